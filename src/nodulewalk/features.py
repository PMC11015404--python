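"""Per-nodule feature bank: 13 shape + 7 GLCM texture + 8 intensity features.

Shape features are geometric descriptors of the binary segmentation mask
(area, solidity, ellipse moments, Euler number, ...).  Texture features
are Haralick-style statistics of the grey-level co-occurrence matrix
(GLCM) restricted to the segmented region.  Intensity features are moment
statistics of the region on the approximation (LL) subband of a
single-level 2-D discrete wavelet transform, which acts as a denoised,
half-resolution view of the nodule interior.

The concatenated, stably-named 28-vector (:data:`FEATURE_NAMES`) is the
classifier input.  Vector- valued descriptors (centroid, extrema) are
reduced to single scalars — the mean of their coordinates — so the vector
has exactly one number per named feature.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pywt
from skimage import measure

from .errors import (
    ContractError,
    DegenerateRegionError,
    EmptyRegionError,
    FormatError,
)

SHAPE_FEATURE_NAMES = (
    "area", "solidity", "centroid", "perimeter", "convex_area", "orientation",
    "eccentricity", "minor_axis_length", "equiv_diameter", "major_axis_length",
    "euler_number", "extrema", "extent",
)
GLCM_FEATURE_NAMES = (
    "contrast", "dissimilarity", "entropy", "cluster_shade", "energy",
    "cluster_prominence", "homogeneity",
)
INTENSITY_FEATURE_NAMES = (
    "mean", "idm", "std_dev", "smoothness", "skewness", "rms", "kurtosis",
    "variance",
)
#: Stable order of the full 28-entry feature vector.
FEATURE_NAMES: tuple[str, ...] = (
    SHAPE_FEATURE_NAMES + GLCM_FEATURE_NAMES + INTENSITY_FEATURE_NAMES
)

#: GLCM offsets for directions 0, 45, 90 and 135 degrees at unit distance.
_GLCM_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def _as_mask(mask) -> np.ndarray:
    """Accept a bare boolean array or a SegmentationMask-like object."""
    inner = getattr(mask, "mask", mask)
    arr = np.asarray(inner)
    if arr.ndim != 2:
        raise FormatError(f"expected a 2-D mask, got shape {arr.shape}")
    return arr.astype(bool)


def shape_features(mask) -> dict[str, float]:
    """13 geometric descriptors of a binary region.

    Area and convex area are pixel counts; solidity is their exact ratio.
    Orientation (degrees in (-90, 90]), eccentricity and the axis lengths
    come from the ellipse with the same second central moments as the
    region.  The Euler number uses 8-connectivity (1 for a single
    hole-free blob).  Centroid is the mean of the centroid's row and
    column; extrema is the mean coordinate of the region's 8 extremal
    boundary points (top-left, top-right, right-top, right-bottom,
    bottom-right, bottom-left, left-bottom, left-top).
    """
    m = _as_mask(mask)
    if not m.any():
        raise EmptyRegionError("shape features of an empty mask are undefined")
    props = measure.regionprops(m.astype(np.uint8))[0]

    area = float(props.area)
    convex_area = float(props.area_convex)
    rr, cc = np.nonzero(m)
    # MATLAB-style extrema: extreme rows/cols of the pixel footprint.
    top = rr.min(); bottom = rr.max(); left = cc.min(); right = cc.max()
    pts = np.array([
        (top, cc[rr == top].min()), (top, cc[rr == top].max()),
        (rr[cc == right].min(), right), (rr[cc == right].max(), right),
        (bottom, cc[rr == bottom].max()), (bottom, cc[rr == bottom].min()),
        (rr[cc == left].max(), left), (rr[cc == left].min(), left),
    ], dtype=np.float64)

    return {
        "area": area,
        "solidity": area / convex_area,
        "centroid": float(np.mean(props.centroid)),
        "perimeter": float(props.perimeter),
        "convex_area": convex_area,
        "orientation": float(np.degrees(props.orientation)),
        "eccentricity": float(props.eccentricity),
        "minor_axis_length": float(props.axis_minor_length),
        "equiv_diameter": float(np.sqrt(4.0 * area / np.pi)),
        "major_axis_length": float(props.axis_major_length),
        "euler_number": float(measure.euler_number(m, connectivity=2)),
        "extrema": float(pts.mean()),
        "extent": float(props.extent),
    }


def glcm(
    image: np.ndarray,
    mask,
    levels: int = 8,
    distance: int = 1,
    directions: tuple[tuple[int, int], ...] = _GLCM_DIRECTIONS,
) -> np.ndarray:
    """Symmetric, direction-averaged co-occurrence matrix of a masked region.

    Region intensities are quantised to ``levels`` equal-width bins over
    the region's min-max range (a constant region maps to bin 0).  Pairs
    are counted at offset ``distance`` along each direction, in both
    orderings, and only when both pixels are inside the mask; the counts
    are normalised to sum to 1.
    """
    img = np.asarray(image, dtype=np.float64)
    m = _as_mask(mask)
    if img.shape != m.shape:
        raise FormatError(f"image {img.shape} and mask {m.shape} shapes differ")
    if not m.any():
        raise EmptyRegionError("GLCM of an empty region is undefined")
    if levels < 2:
        raise ContractError(f"need levels >= 2, got {levels}")

    vals = img[m]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.floor((img - lo) / (hi - lo) * levels).astype(np.int64)
        q = np.clip(q, 0, levels - 1)
    else:
        q = np.zeros(img.shape, dtype=np.int64)

    counts = np.zeros((levels, levels), dtype=np.float64)
    rows, cols = img.shape
    for dr_, dc_ in directions:
        dr, dc = dr_ * distance, dc_ * distance
        r0, r1 = max(0, -dr), min(rows, rows - dr)
        c0, c1 = max(0, -dc), min(cols, cols - dc)
        src_m = m[r0:r1, c0:c1]
        dst_m = m[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = src_m & dst_m
        a = q[r0:r1, c0:c1][valid]
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc][valid]
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)

    total = counts.sum()
    if total < 4:  # fewer than 2 unordered pairs
        raise DegenerateRegionError(
            "region has fewer than 2 in-mask co-occurrence pairs"
        )
    return counts / total


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """The seven Haralick-style statistics of a normalised GLCM.

    contrast         = sum (i-j)^2 P(i,j)
    dissimilarity    = sum |i-j| P(i,j)
    entropy          = -sum P log P  (natural log, over P > 0)
    energy           = sum P^2
    homogeneity      = sum P / (1 + (i-j)^2)
    cluster shade    = sum (i + j - mu_i - mu_j)^3 P
    cluster prominence = sum (i + j - mu_i - mu_j)^4 P
    """
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise FormatError(f"GLCM must be square, got shape {P.shape}")
    if np.any(P < 0):
        raise ContractError("GLCM entries must be non-negative")
    if abs(P.sum() - 1.0) > 1e-6:
        raise ContractError(f"GLCM must be normalised to sum 1, got {P.sum()}")

    n = P.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    diff = i - j
    mu_i = float((i * P).sum())
    mu_j = float((j * P).sum())
    shift = i + j - mu_i - mu_j
    pos = P > 0
    return {
        "contrast": float((diff**2 * P).sum()),
        "dissimilarity": float((np.abs(diff) * P).sum()),
        "entropy": float(-(P[pos] * np.log(P[pos])).sum()),
        "cluster_shade": float((shift**3 * P).sum()),
        "energy": float((P**2).sum()),
        "cluster_prominence": float((shift**4 * P).sum()),
        "homogeneity": float((P / (1.0 + diff**2)).sum()),
    }


def dwt_approx(
    image: np.ndarray, mask, wavelet: str = "haar"
) -> tuple[np.ndarray, np.ndarray]:
    """Approximation (LL) subband of the region's bounding box.

    Applies one level of the orthonormal 2-D DWT with symmetric padding to
    the bounding-box crop and returns the LL subband together with the
    mask downsampled to subband resolution (a subband pixel is in-mask iff
    at least one of its 2x2 source pixels is).  Under the orthonormal Haar
    convention a constant region of value v maps to a constant 2v.
    """
    img = np.asarray(image, dtype=np.float64)
    m = _as_mask(mask)
    if img.shape != m.shape:
        raise FormatError(f"image {img.shape} and mask {m.shape} shapes differ")
    if not m.any():
        raise EmptyRegionError("wavelet subband of an empty region is undefined")
    rr, cc = np.nonzero(m)
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    if (r1 - r0) < 2 or (c1 - c0) < 2:
        raise DegenerateRegionError("region bounding box must be at least 2x2")
    region = img[r0:r1, c0:c1]
    sub_mask_src = m[r0:r1, c0:c1]

    ll, _ = pywt.dwt2(region, wavelet, mode="symmetric")

    h, w = sub_mask_src.shape
    padded = np.zeros((h + h % 2, w + w % 2), dtype=bool)
    padded[:h, :w] = sub_mask_src
    sub_mask = (
        padded.reshape(padded.shape[0] // 2, 2, padded.shape[1] // 2, 2)
        .any(axis=(1, 3))
    )
    if sub_mask.shape != ll.shape:  # pragma: no cover - haar always matches
        raise ContractError(
            f"subband {ll.shape} and downsampled mask {sub_mask.shape} disagree"
        )
    return ll, sub_mask


def intensity_features(
    subband: np.ndarray,
    subband_mask,
    glcm_levels: int = 8,
    glcm_distance: int = 1,
) -> dict[str, float]:
    """Eight moment statistics of the in-mask subband intensities.

    Standard deviation and variance are population statistics; skewness
    and kurtosis are the standardised 3rd/4th central moments (kurtosis is
    non-excess, so a Gaussian gives 3).  smoothness = 1 - 1/(1 + variance)
    is 0 for a constant region.  IDM (inverse difference moment) is the
    homogeneity statistic of a GLCM built on the subband region itself.
    A zero-variance region reports skewness and kurtosis as 0 with a
    degeneracy warning.
    """
    sb = np.asarray(subband, dtype=np.float64)
    m = _as_mask(subband_mask)
    if sb.shape != m.shape:
        raise FormatError(f"subband {sb.shape} and mask {m.shape} shapes differ")
    vals = sb[m]
    if vals.size < 2:
        raise DegenerateRegionError("need at least 2 in-mask subband pixels")

    mean = float(vals.mean())
    variance = float(vals.var())
    std_dev = float(np.sqrt(variance))
    rms = float(np.sqrt(np.mean(vals**2)))
    if variance > 0:
        z = (vals - mean) / std_dev
        skewness = float(np.mean(z**3))
        kurtosis = float(np.mean(z**4))
    else:
        warnings.warn("zero-variance region: skewness/kurtosis reported as 0",
                      stacklevel=2)
        skewness = 0.0
        kurtosis = 0.0
    try:
        P = glcm(sb, m, levels=glcm_levels, distance=glcm_distance)
        idm = glcm_features(P)["homogeneity"]
    except DegenerateRegionError:
        idm = float("nan")
    return {
        "mean": mean,
        "idm": idm,
        "std_dev": std_dev,
        "smoothness": 1.0 - 1.0 / (1.0 + variance),
        "skewness": skewness,
        "rms": rms,
        "kurtosis": kurtosis,
        "variance": variance,
    }


def extract_features(
    image: np.ndarray,
    mask,
    glcm_levels: int = 8,
    glcm_distance: int = 1,
    wavelet: str = "haar",
    intensity_on_subband: bool = True,
) -> pd.Series:
    """Full 28-entry feature vector of one segmented nodule.

    Concatenates the shape block (mask only), the GLCM texture block
    (image restricted to the mask) and the intensity block (LL wavelet
    subband of the region by default; set ``intensity_on_subband=False``
    to compute it on the raw region instead).  Returns a pandas Series
    indexed by :data:`FEATURE_NAMES`.
    """
    m = _as_mask(mask)
    values: dict[str, float] = {}
    values.update(shape_features(m))
    values.update(glcm_features(glcm(image, m, levels=glcm_levels,
                                     distance=glcm_distance)))
    if intensity_on_subband:
        ll, sub_mask = dwt_approx(image, m, wavelet=wavelet)
        values.update(intensity_features(ll, sub_mask, glcm_levels=glcm_levels,
                                         glcm_distance=glcm_distance))
    else:
        values.update(intensity_features(np.asarray(image, dtype=np.float64), m,
                                         glcm_levels=glcm_levels,
                                         glcm_distance=glcm_distance))
    vec = pd.Series([values[name] for name in FEATURE_NAMES],
                    index=list(FEATURE_NAMES), dtype=np.float64)
    return vec


def extract_feature_table(samples, masks=None, **kwargs) -> pd.DataFrame:
    """Feature vectors for a batch of (image, mask, label) samples.

    ``samples`` is an iterable of PhantomSample-like objects (attributes
    ``image``, ``mask``, ``label``); pass ``masks`` to override the masks
    (e.g. with segmentation outputs).  Rows keep the iteration order; the
    result has the 28 feature columns plus a ``label`` column.
    """
    rows = []
    labels = []
    for i, sample in enumerate(samples):
        mask = masks[i] if masks is not None else sample.mask
        rows.append(extract_features(sample.image, mask, **kwargs))
        labels.append(sample.label)
    table = pd.DataFrame(rows).reset_index(drop=True)
    table["label"] = labels
    return table
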