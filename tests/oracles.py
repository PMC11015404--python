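"""Independent test oracles (kept free of the implementation paths they check)."""

import numpy as np

from nodulewalk.rw_segment import BACKGROUND, FOREGROUND, EdgeWeights


def heat_step_oracle(image: np.ndarray, lam: float, n_iter: int) -> np.ndarray:
    """Independent linear heat-equation stencil (c = 1, replicate borders)."""
    out = image.astype(np.float64).copy()
    for _ in range(n_iter):
        padded = np.pad(out, 1, mode="edge")
        lap = (padded[:-2, 1:-1] + padded[2:, 1:-1]
               + padded[1:-1, :-2] + padded[1:-1, 2:] - 4 * out)
        out = out + lam * lap
    return out


def _neighbor_table(weights: EdgeWeights):
    """Per-node neighbour indices and edge weights (N, S, W, E order);
    absent neighbours get weight 0."""
    R, C = weights.shape
    n = R * C
    idx = np.arange(n).reshape(R, C)
    nbr = np.zeros((n, 4), dtype=np.int64)
    w = np.zeros((n, 4), dtype=np.float64)
    # north
    nbr[idx[1:, :].ravel(), 0] = idx[:-1, :].ravel()
    w[idx[1:, :].ravel(), 0] = weights.vertical.ravel()
    # south
    nbr[idx[:-1, :].ravel(), 1] = idx[1:, :].ravel()
    w[idx[:-1, :].ravel(), 1] = weights.vertical.ravel()
    # west
    nbr[idx[:, 1:].ravel(), 2] = idx[:, :-1].ravel()
    w[idx[:, 1:].ravel(), 2] = weights.horizontal.ravel()
    # east
    nbr[idx[:, :-1].ravel(), 3] = idx[:, 1:].ravel()
    w[idx[:, :-1].ravel(), 3] = weights.horizontal.ravel()
    return nbr, w


def mc_absorption(
    weights: EdgeWeights,
    seeds: np.ndarray,
    walks_per_pixel: int,
    rng: np.random.Generator,
    max_steps: int = 1_000_000,
) -> np.ndarray:
    """Monte-Carlo estimate of the foreground-absorption probability.

    From every unseeded pixel, ``walks_per_pixel`` random walks step to a
    4-neighbour with probability proportional to the edge weight until a
    seed is reached; the estimate is the fraction absorbed at foreground
    seeds.  Returns a field shaped like the image (exact 1/0 on seeds).
    """
    R, C = weights.shape
    nbr, w = _neighbor_table(weights)
    cum = np.cumsum(w, axis=1)
    cum /= cum[:, -1:]

    flat_seeds = seeds.ravel()
    absorbing = flat_seeds != 0
    starts = np.flatnonzero(~absorbing)

    pos = np.repeat(starts, walks_per_pixel)
    origin = pos.copy()
    fg_hits = np.zeros(R * C, dtype=np.int64)

    for _ in range(max_steps):
        if pos.size == 0:
            break
        u = rng.random(pos.size)
        k = (u[:, None] > cum[pos]).sum(axis=1)
        pos = nbr[pos, k]
        done = absorbing[pos]
        if done.any():
            hit_fg = flat_seeds[pos[done]] == FOREGROUND
            np.add.at(fg_hits, origin[done][hit_fg], 1)
            pos = pos[~done]
            origin = origin[~done]
    assert pos.size == 0, "some walks never reached a seed"

    p = np.zeros(R * C, dtype=np.float64)
    p[starts] = fg_hits[starts] / walks_per_pixel
    p[flat_seeds == FOREGROUND] = 1.0
    p[flat_seeds == BACKGROUND] = 0.0
    return p.reshape(R, C)


def harmonic_residual(p: np.ndarray, weights: EdgeWeights, seeds: np.ndarray) -> float:
    """Max deviation of unseeded pixels from the weighted neighbour average."""
    nbr, w = _neighbor_table(weights)
    flat = p.ravel()
    avg = (w * flat[nbr]).sum(axis=1) / w.sum(axis=1)
    unseeded = seeds.ravel() == 0
    return float(np.abs(flat - avg)[unseeded].max())
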