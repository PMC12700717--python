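"""Texture radiomics of 2-D ultrasound regions of interest.

Implements the three-group feature inventory extracted from a grayscale
image plus a binary ROI mask:

* Group 1 — six global first-order-histogram features of the in-mask
  intensities (Mean, Variance, Skewness, Kurtosis, Entropy, Energy).
* Group 2 — forty higher-order texture features derived from four count
  structures built on the gray-level-quantized ROI: the co-occurrence
  matrix (GLCM, 9 features), run-length matrix (GLRLM, 13), size-zone
  matrix (GLSZM, 13) and neighborhood gray-tone difference vector
  (NGTDM, 5, Amadasun–King formulation).
* Group 3 — the same 46 features recomputed on each of seven wavelet
  sub-bands (ch1/cv1/cd1 at level 1; ca2/ch2/cv2/cd2 at level 2) of a
  two-level separable discrete wavelet transform, 7 x 46 = 322 features.

The full vector therefore has 6 + 40 + 322 = 368 named entries.

All matrix builders are mask-aware: pixel pairs, runs, zones and
neighborhoods that touch out-of-mask pixels are excluded or broken,
never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

__all__ = [
    "FeatureName",
    "QuantizedROI",
    "quantize",
    "global_features",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "ngtdm_vector",
    "ngtdm_features",
    "wavelet_decompose",
    "extract_all",
    "feature_inventory",
    "select_peak_frame",
]

GLOBAL_FEATURES = ("Mean", "Variance", "Skewness", "Kurtosis", "Entropy", "Energy")
GLCM_FEATURES = (
    "Energy", "Contrast", "Correlation", "Homogeneity", "Entropy",
    "Variance", "SumAverage", "Dissimilarity", "MaxProbability",
)
GLRLM_FEATURES = (
    "SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
    "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV",
)
GLSZM_FEATURES = (
    "SZE", "LZE", "GLN", "ZSN", "ZP", "LGZE", "HGZE",
    "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLV", "ZSV",
)
NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

#: Wavelet sub-bands, level-1 details then the level-2 quartet.
SUBBANDS = ("ch1", "cv1", "cd1", "ca2", "ch2", "cv2", "cd2")

_FAMILY_MEMBERS = {
    "Global": GLOBAL_FEATURES,
    "GLCM": GLCM_FEATURES,
    "GLRLM": GLRLM_FEATURES,
    "GLSZM": GLSZM_FEATURES,
    "NGTDM": NGTDM_FEATURES,
}

#: Default GLCM offsets: distance 1 at 0/45/90/135 degrees (symmetric).
DEFAULT_OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))
#: Default GLRLM directions (counts summed over directions).
DEFAULT_DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))

#: Sentinel for Coarseness when every neighborhood difference vanishes.
COARSENESS_CAP = 1.0e6


@dataclass(frozen=True)
class FeatureName:
    """Canonical identity of one radiomic feature.

    Rendered as ``<subband>-<family>-<feature>`` with an ASCII hyphen;
    the sub-band prefix is omitted for features of the undecomposed
    (native) image, e.g. ``Global-Mean`` vs ``cv2-GLSZM-LZHGE``.
    """

    subband: str  # "native" or one of SUBBANDS
    family: str
    feature: str

    def render(self) -> str:
        if self.subband == "native":
            return f"{self.family}-{self.feature}"
        return f"{self.subband}-{self.family}-{self.feature}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "FeatureName":
        parts = text.split("-")
        if len(parts) == 2:
            subband, (family, feature) = "native", parts
        elif len(parts) == 3:
            subband, family, feature = parts
        else:
            raise ValueError(f"cannot parse feature name {text!r}")
        if subband != "native" and subband not in SUBBANDS:
            raise ValueError(f"unknown sub-band in {text!r}")
        if family not in _FAMILY_MEMBERS:
            raise ValueError(f"unknown family in {text!r}")
        if feature not in _FAMILY_MEMBERS[family]:
            raise ValueError(f"unknown feature in {text!r}")
        return cls(subband, family, feature)


def feature_inventory() -> list[FeatureName]:
    """The ordered 368-entry feature inventory (native block, then sub-bands)."""
    names: list[FeatureName] = []
    for subband in ("native",) + SUBBANDS:
        for family, members in _FAMILY_MEMBERS.items():
            names.extend(FeatureName(subband, family, m) for m in members)
    return names


@dataclass
class QuantizedROI:
    """Gray-level-quantized ROI: integer levels 1..ng inside the mask, 0 outside."""

    levels: np.ndarray  # int array, 0 marks out-of-mask
    mask: np.ndarray  # bool array
    ng: int

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _check_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty ROI mask")
    return mask


def quantize(image: np.ndarray, mask: np.ndarray, ng: int = 32) -> QuantizedROI:
    """Equal-width quantization of in-mask intensities to levels 1..ng.

    Bins span the in-mask [min, max] range; a constant region maps every
    pixel to level 1.
    """
    if ng < 2:
        raise ValueError("ng must be >= 2")
    mask = _check_mask(image, mask)
    image = np.asarray(image, dtype=float)
    vals = image[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(image.shape, dtype=np.int32)
    if hi > lo:
        lv = np.floor((image - lo) / (hi - lo) * ng).astype(np.int32) + 1
        np.clip(lv, 1, ng, out=lv)
        levels[mask] = lv[mask]
    else:
        levels[mask] = 1
    return QuantizedROI(levels=levels, mask=mask, ng=int(ng))


# ---------------------------------------------------------------------------
# Group 1: global first-order features
# ---------------------------------------------------------------------------

def global_features(image: np.ndarray, mask: np.ndarray, ng: int = 32) -> dict[str, float]:
    """Population moments plus histogram Entropy/Energy of in-mask intensities.

    Skewness and Kurtosis of a constant region are defined as 0; Entropy and
    Energy come from the ``ng``-bin equal-width histogram of in-mask values
    (base-2 logarithm).
    """
    mask = _check_mask(image, mask)
    vals = np.asarray(image, dtype=float)[mask]
    mean = float(vals.mean())
    var = float(vals.var())  # population variance
    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.mean((vals - mean) ** 3) / sd**3)
        kurt = float(np.mean((vals - mean) ** 4) / var**2)
    else:
        skew = 0.0
        kurt = 0.0
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        counts, _ = np.histogram(vals, bins=ng, range=(lo, hi))
    else:
        counts = np.array([vals.size])
    p = counts[counts > 0] / vals.size
    entropy = float(-(p * np.log2(p)).sum())
    energy = float((p**2).sum())
    return {
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Entropy": entropy,
        "Energy": energy,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(q: QuantizedROI, offsets=DEFAULT_OFFSETS) -> np.ndarray:
    """Symmetric gray-level co-occurrence counts aggregated over offsets.

    A pair contributes only when both pixels lie inside the mask; each
    offset is counted symmetrically (both orderings).
    """
    if not offsets:
        raise ValueError("offsets must be nonempty")
    ng = q.ng
    counts = np.zeros((ng, ng), dtype=np.int64)
    lv = q.levels
    h, w = lv.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = lv[r0:r1, c0:c1]
        b = lv[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = (a > 0) & (b > 0)
        ia, ib = a[ok] - 1, b[ok] - 1
        np.add.at(counts, (ia, ib), 1)
        np.add.at(counts, (ib, ia), 1)
    return counts


def glcm_features(q: QuantizedROI, offsets=DEFAULT_OFFSETS) -> dict[str, float]:
    """Haralick-style features of the normalized aggregated co-occurrence matrix."""
    if q.n_pixels < 2:
        raise ValueError("GLCM needs at least 2 in-mask pixels")
    counts = glcm_matrix(q, offsets)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs for the given offsets")
    p = counts / total
    ng = q.ng
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu_i = (ii * p).sum()
    mu_j = (jj * p).sum()
    var_i = ((ii - mu_i) ** 2 * p).sum()
    var_j = ((jj - mu_j) ** 2 * p).sum()
    if var_i > 0 and var_j > 0:
        correlation = float(((ii - mu_i) * (jj - mu_j) * p).sum() / np.sqrt(var_i * var_j))
    else:
        correlation = 0.0  # degenerate: zero variance
    nz = p[p > 0]
    # sum distribution p_{x+y}(k), k = 2..2*ng
    psum = np.zeros(2 * ng + 1)
    np.add.at(psum, (ii + jj).astype(int).ravel(), p.ravel())
    k = np.arange(2 * ng + 1, dtype=float)
    return {
        "Energy": float((p**2).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": correlation,
        "Homogeneity": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Entropy": float(-(nz * np.log2(nz)).sum()),
        "Variance": float(((ii - mu_i) ** 2 * p).sum()),
        "SumAverage": float((k * psum).sum()),
        "Dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "MaxProbability": float(p.max()),
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _direction_lines(lv: np.ndarray, direction: tuple[int, int]) -> list[np.ndarray]:
    """1-D scan lines of the level image along a direction (0 = out of mask)."""
    h, w = lv.shape
    dr, dc = direction
    if (dr, dc) == (0, 1):
        return [lv[r] for r in range(h)]
    if (dr, dc) == (1, 0):
        return [lv[:, c] for c in range(w)]
    if (dr, dc) == (1, 1):
        return [np.diagonal(lv, offset=o) for o in range(-(h - 1), w)]
    if (dr, dc) == (1, -1):
        f = np.fliplr(lv)
        return [np.diagonal(f, offset=o) for o in range(-(h - 1), w)]
    raise ValueError(f"unsupported direction {direction}")


def _run_lengths(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal runs of identical nonzero values: (levels, lengths)."""
    if seq.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.r_[0, change + 1]
    ends = np.r_[change, seq.size - 1]
    levels = seq[starts]
    keep = levels > 0
    return levels[keep].astype(np.int64), (ends - starts + 1)[keep].astype(np.int64)


def glrlm_matrix(q: QuantizedROI, directions=DEFAULT_DIRECTIONS) -> np.ndarray:
    """Run-length counts (levels x run length) summed over directions.

    Runs are maximal colinear segments of equal level lying entirely inside
    the mask; out-of-mask pixels break runs.
    """
    pieces = []
    for d in directions:
        for line in _direction_lines(q.levels, d):
            pieces.append(np.asarray(line))
            pieces.append(np.zeros(1, dtype=q.levels.dtype))  # line separator
    joined = np.concatenate(pieces)
    levels, lengths = _run_lengths(joined)
    rmax = int(lengths.max()) if lengths.size else 1
    counts = np.zeros((q.ng, rmax), dtype=np.int64)
    np.add.at(counts, (levels - 1, lengths - 1), 1)
    return counts


def glrlm_features(q: QuantizedROI, directions=DEFAULT_DIRECTIONS) -> dict[str, float]:
    """Standard run-length features of the normalized run-length matrix.

    RP is normalized by ``n_pixels * n_directions`` so it stays in (0, 1]
    when counts are aggregated over several directions.
    """
    counts = glrlm_matrix(q, directions)
    nr = counts.sum()
    if nr == 0:
        raise ValueError("no runs found")
    p = counts / nr
    ng, rmax = counts.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, rmax + 1, dtype=float)[None, :]
    p_i = p.sum(axis=1)
    p_j = p.sum(axis=0)
    mu_i = float((np.arange(1, ng + 1) * p_i).sum())
    mu_j = float((np.arange(1, rmax + 1) * p_j).sum())
    return {
        "SRE": float((p / j**2).sum()),
        "LRE": float((p * j**2).sum()),
        "GLN": float(nr * (p_i**2).sum()),
        "RLN": float(nr * (p_j**2).sum()),
        "RP": float(nr / (q.n_pixels * len(directions))),
        "LGRE": float((p / i**2).sum()),
        "HGRE": float((p * i**2).sum()),
        "SRLGE": float((p / (i**2 * j**2)).sum()),
        "SRHGE": float((p * i**2 / j**2).sum()),
        "LRLGE": float((p * j**2 / i**2).sum()),
        "LRHGE": float((p * i**2 * j**2).sum()),
        "GLV": float(((np.arange(1, ng + 1) - mu_i) ** 2 * p_i).sum()),
        "RLV": float(((np.arange(1, rmax + 1) - mu_j) ** 2 * p_j).sum()),
    }


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

_EIGHT = np.ones((3, 3), dtype=int)


def glszm_matrix(q: QuantizedROI) -> np.ndarray:
    """Size-zone counts (levels x zone size); zones are 8-connected components."""
    zone_levels: list[int] = []
    zone_sizes: list[int] = []
    for level in range(1, q.ng + 1):
        sel = q.levels == level
        if not sel.any():
            continue
        lab, n = ndimage.label(sel, structure=_EIGHT)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zone_levels.extend([level] * n)
        zone_sizes.extend(sizes.tolist())
    if not zone_sizes:
        raise ValueError("no zones found")
    zmax = max(zone_sizes)
    counts = np.zeros((q.ng, zmax), dtype=np.int64)
    np.add.at(counts, (np.array(zone_levels) - 1, np.array(zone_sizes) - 1), 1)
    return counts


def glszm_features(q: QuantizedROI) -> dict[str, float]:
    counts = glszm_matrix(q)
    nz = counts.sum()
    p = counts / nz
    ng, zmax = counts.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    z = np.arange(1, zmax + 1, dtype=float)[None, :]
    p_i = p.sum(axis=1)
    p_z = p.sum(axis=0)
    mu_i = float((np.arange(1, ng + 1) * p_i).sum())
    mu_z = float((np.arange(1, zmax + 1) * p_z).sum())
    return {
        "SZE": float((p / z**2).sum()),
        "LZE": float((p * z**2).sum()),
        "GLN": float(nz * (p_i**2).sum()),
        "ZSN": float(nz * (p_z**2).sum()),
        "ZP": float(nz / q.n_pixels),
        "LGZE": float((p / i**2).sum()),
        "HGZE": float((p * i**2).sum()),
        "SZLGE": float((p / (i**2 * z**2)).sum()),
        "SZHGE": float((p * i**2 / z**2).sum()),
        "LZLGE": float((p * z**2 / i**2).sum()),
        "LZHGE": float((p * z**2 * i**2).sum()),
        "GLV": float(((np.arange(1, ng + 1) - mu_i) ** 2 * p_i).sum()),
        "ZSV": float(((np.arange(1, zmax + 1) - mu_z) ** 2 * p_z).sum()),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_vector(q: QuantizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level (n_i, s_i) of the neighborhood gray-tone difference vector.

    s_i sums, over in-mask pixels of level i that have at least one in-mask
    8-neighbor, the absolute difference between the level and the mean level
    of the in-mask 8-neighbors.  Returns (n, s, N_valid).
    """
    lv = q.levels.astype(float)
    m = q.mask.astype(float)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    neigh_sum = ndimage.convolve(lv * m, kernel, mode="constant", cval=0.0)
    neigh_cnt = ndimage.convolve(m, kernel, mode="constant", cval=0.0)
    valid = q.mask & (neigh_cnt > 0)
    n = np.zeros(q.ng)
    s = np.zeros(q.ng)
    levels_v = q.levels[valid]
    diffs = np.abs(levels_v - neigh_sum[valid] / neigh_cnt[valid])
    np.add.at(n, levels_v - 1, 1)
    np.add.at(s, levels_v - 1, diffs)
    return n, s, int(valid.sum())


def ngtdm_features(q: QuantizedROI) -> dict[str, float]:
    """Amadasun–King coarseness/contrast/busyness/complexity/strength."""
    n, s, n_valid = ngtdm_vector(q)
    if n_valid == 0:
        raise ValueError("no pixel has an in-mask neighbor")
    p = n / n_valid
    levels = np.arange(1, q.ng + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())
    ps = float((p * s).sum())
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP
    s_sum = float(s.sum())

    ii = levels[present][:, None]
    jj = levels[present][None, :]
    pi = p[present][:, None]
    pj = p[present][None, :]
    si = s[present][:, None]
    sj = s[present][None, :]

    if ngp > 1:
        contrast = float((pi * pj * (ii - jj) ** 2).sum() / (ngp * (ngp - 1)) * (s_sum / n_valid))
    else:
        contrast = 0.0
    denom_b = float(np.abs(ii * pi - jj * pj).sum())
    busyness = ps / denom_b if denom_b > 0 else 0.0
    complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (n_valid * (pi + pj))).sum())
    strength = float(((pi + pj) * (ii - jj) ** 2).sum() / s_sum) if s_sum > 0 else 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": contrast,
        "Busyness": float(busyness),
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# Wavelet decomposition
# ---------------------------------------------------------------------------

def _decimate_mask(mask: np.ndarray) -> np.ndarray:
    """2x2 decimation; a cell survives only if all four parents are in-mask."""
    h, w = mask.shape
    return mask.reshape(h // 2, 2, w // 2, 2).all(axis=(1, 3))


def wavelet_decompose(
    image: np.ndarray, mask: np.ndarray, wavelet: str = "haar"
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Two-level separable DWT (periodic extension) with decimated masks.

    Returns the seven retained sub-bands ``ch1, cv1, cd1, ca2, ch2, cv2, cd2``
    as (coefficients, mask) pairs.  ``ch``/``cv`` are the horizontal/vertical
    detail images (responding to horizontal/vertical structure), ``cd`` the
    diagonal detail, ``ca2`` the twice-decimated approximation.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if h % 4 or w % 4:
        raise ValueError("image dimensions must be divisible by 4 for two levels")
    mask = np.asarray(mask).astype(bool)
    ca1, (ch1, cv1, cd1) = pywt.dwt2(image, wavelet, mode="periodization")
    ca2, (ch2, cv2, cd2) = pywt.dwt2(ca1, wavelet, mode="periodization")
    m1 = _decimate_mask(mask)
    m2 = _decimate_mask(m1)
    return {
        "ch1": (ch1, m1),
        "cv1": (cv1, m1),
        "cd1": (cd1, m1),
        "ca2": (ca2, m2),
        "ch2": (ch2, m2),
        "cv2": (cv2, m2),
        "cd2": (cd2, m2),
    }


# ---------------------------------------------------------------------------
# Full inventory
# ---------------------------------------------------------------------------

def _band_features(image, mask, ng) -> dict[str, dict[str, float]]:
    q = quantize(image, mask, ng)
    return {
        "Global": global_features(image, mask, ng),
        "GLCM": glcm_features(q),
        "GLRLM": glrlm_features(q),
        "GLSZM": glszm_features(q),
        "NGTDM": ngtdm_features(q),
    }


def _sentinel_features() -> dict[str, dict[str, float]]:
    return {fam: {m: 0.0 for m in members} for fam, members in _FAMILY_MEMBERS.items()}


def extract_all(
    image: np.ndarray,
    mask: np.ndarray,
    ng: int = 32,
    wavelet: str = "haar",
) -> dict[str, float]:
    """Extract the full 368-feature vector for one image + ROI mask.

    Native Group-1/Group-2 features come first, then the 46-feature block
    for each of the seven wavelet sub-bands.  A sub-band whose decimated
    mask is empty yields sentinel zeros with a warning.
    """
    mask = _check_mask(image, mask)
    blocks: dict[str, dict[str, dict[str, float]]] = {
        "native": _band_features(image, mask, ng)
    }
    for name, (band, bmask) in wavelet_decompose(image, mask, wavelet).items():
        if bmask.any():
            blocks[name] = _band_features(band, bmask, ng)
        else:
            warnings.warn(
                f"sub-band {name}: decimated mask is empty; emitting sentinel zeros",
                stacklevel=2,
            )
            blocks[name] = _sentinel_features()
    out: dict[str, float] = {}
    for fn in feature_inventory():
        out[fn.render()] = blocks[fn.subband][fn.family][fn.feature]
    return out


def select_peak_frame(frames: np.ndarray, mask: np.ndarray) -> int:
    """Index of the frame with maximal mean in-mask intensity (CEUS peak)."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        return 0
    mask = np.asarray(mask).astype(bool)
    means = frames[:, mask].mean(axis=1)
    return int(np.argmax(means))
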