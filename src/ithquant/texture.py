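"""Co-occurrence matrices and texture statistics over patch-level label maps.

The heterogeneity features are Haralick-style statistics of a normalized,
symmetric co-occurrence matrix (CM) accumulated over the eight unit-offset
neighbour directions of a patch grid.  Counts are accumulated over all eight
directions and divided by two, so each unordered neighbour pair contributes
once per orientation; the matrix is then normalized to sum to one.

Unlike intensity GLCMs on raw images, these CMs are built on *patch-level*
maps (binarized layer presence or ordinal grade levels) and must skip patches
flagged invalid (non-tissue or DCIS), which is why the accumulation is done
here rather than through ``skimage.feature.graycomatrix``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "CoocMatrix",
    "TextureFeatureSet",
    "UndefinedCMError",
    "build_cm",
    "texture_stats",
    "colocalization",
    "TEXTURE_STATISTICS",
]

#: Names of the scalar statistics derived from one co-occurrence matrix,
#: in catalogue order.
TEXTURE_STATISTICS = (
    "contrast",
    "dissimilarity",
    "homogeneity",
    "heterogeneity",
    "correlation",
    "uniformity",
    "energy",
    "entropy",
)

# Four positive unit offsets; with their negations they make the eight
# neighbour directions (E, SE, S, SW and reverses).
_POSITIVE_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


class UndefinedCMError(ValueError):
    """Raised when a map has no valid neighbouring patch pair."""


@dataclasses.dataclass(frozen=True)
class CoocMatrix:
    """Normalized symmetric co-occurrence probability matrix.

    Attributes
    ----------
    p : ndarray of shape (L, L)
        Probabilities p(i, j); non-negative, symmetric, summing to 1.
    levels : ndarray of shape (L,)
        Ordered numeric level labels indexing the rows/columns of ``p``.
    distance : int
        Neighbour offset in patches.
    directions : int
        Number of directions accumulated (8).
    """

    p: np.ndarray
    levels: np.ndarray
    distance: int = 1
    directions: int = 8

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("co-occurrence matrix must be square")
        if np.any(p < 0):
            raise ValueError("co-occurrence probabilities must be non-negative")
        if not math.isclose(float(p.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("co-occurrence matrix must sum to 1")


@dataclasses.dataclass(frozen=True)
class TextureFeatureSet:
    """Scalar texture statistics of one co-occurrence matrix."""

    contrast: float
    dissimilarity: float
    homogeneity: float
    heterogeneity: float
    correlation: float
    uniformity: float
    energy: float
    entropy: float
    #: False when the map is constant (sigma_i * sigma_j == 0) and the
    #: correlation is reported as 0 by convention.
    correlation_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in TEXTURE_STATISTICS}


def build_cm(
    level_map: np.ndarray,
    valid: np.ndarray | None = None,
    distance: int = 1,
    directions: int = 8,
) -> CoocMatrix:
    """Build the normalized symmetric co-occurrence matrix of a patch map.

    Parameters
    ----------
    level_map : 2D integer array
        Per-patch levels (e.g. 0/1 presence, or grade 1-3).
    valid : 2D boolean array, optional
        Patches to include; invalid patches contribute to no pair.
    distance : int
        Offset between paired patches, in patches.
    directions : int
        Only the canonical 8-direction accumulation is supported.

    Raises
    ------
    UndefinedCMError
        If no valid pair of neighbouring patches exists.
    """
    level_map = np.asarray(level_map)
    if level_map.ndim != 2:
        raise ValueError("level map must be 2D")
    if directions != 8:
        raise ValueError("only 8-direction accumulation is supported")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if valid is None:
        valid = np.ones(level_map.shape, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
        if valid.shape != level_map.shape:
            raise ValueError("valid mask shape must match level map")

    levels = np.unique(level_map[valid]) if valid.any() else np.array([], dtype=int)
    if levels.size == 0:
        raise UndefinedCMError("no valid patch in map")

    counts = np.zeros((levels.size, levels.size), dtype=float)
    H, W = level_map.shape
    for dy, dx in _POSITIVE_OFFSETS:
        dy, dx = dy * distance, dx * distance
        src = (slice(max(0, -dy), H - max(0, dy)),
               slice(max(0, -dx), W - max(0, dx)))
        dst = (slice(max(0, dy), H - max(0, -dy)),
               slice(max(0, dx), W - max(0, -dx)))
        a, b = level_map[src], level_map[dst]
        pair_ok = valid[src] & valid[dst]
        if not pair_ok.any():
            continue
        ia = np.searchsorted(levels, a[pair_ok])
        ib = np.searchsorted(levels, b[pair_ok])
        # each positive offset paired with its negation: add both orderings,
        # i.e. the full 8-direction count before the divide-by-2
        np.add.at(counts, (ia, ib), 1.0)
        np.add.at(counts, (ib, ia), 1.0)

    counts /= 2.0  # each unordered pair once per orientation
    total = counts.sum()
    if total == 0:
        raise UndefinedCMError("no valid neighbouring patch pair")
    return CoocMatrix(p=counts / total, levels=levels.astype(float),
                      distance=distance, directions=directions)


def texture_stats(cm: CoocMatrix) -> TextureFeatureSet:
    """Compute the texture statistics of a co-occurrence matrix.

    contrast      = sum p(i,j) (i-j)^2
    dissimilarity = sum p(i,j) |i-j|
    homogeneity   = sum p(i,j) / (1 + (i-j)^2)
    heterogeneity = 1 - homogeneity
    correlation   = sum p(i,j)(i-mu_i)(j-mu_j) / (sigma_i sigma_j)
                    (0 and flagged when sigma_i sigma_j == 0)
    uniformity    = sum p(i,j)^2
    energy        = sqrt(uniformity)
    entropy       = -sum_{p>0} p log2 p   (bits)
    """
    p = np.asarray(cm.p, dtype=float)
    i = cm.levels[:, None]
    j = cm.levels[None, :]
    diff = i - j

    contrast = float((p * diff**2).sum())
    dissimilarity = float((p * np.abs(diff)).sum())
    homogeneity = float((p / (1.0 + diff**2)).sum())
    heterogeneity = 1.0 - homogeneity
    uniformity = float((p**2).sum())
    energy = math.sqrt(uniformity)
    pos = p[p > 0]
    entropy = float(-(pos * np.log2(pos)).sum())

    mu_i = float((p.sum(axis=1) * cm.levels).sum())
    mu_j = float((p.sum(axis=0) * cm.levels).sum())
    var_i = float((p.sum(axis=1) * (cm.levels - mu_i) ** 2).sum())
    var_j = float((p.sum(axis=0) * (cm.levels - mu_j) ** 2).sum())
    denom = math.sqrt(var_i * var_j)
    if denom > 0:
        correlation = float((p * (i - mu_i) * (j - mu_j)).sum() / denom)
        corr_ok = True
    else:
        correlation = 0.0
        corr_ok = False

    return TextureFeatureSet(
        contrast=contrast,
        dissimilarity=dissimilarity,
        homogeneity=homogeneity,
        heterogeneity=heterogeneity,
        correlation=correlation,
        uniformity=uniformity,
        energy=energy,
        entropy=entropy,
        correlation_defined=corr_ok,
    )


def colocalization(fracs_a: np.ndarray, fracs_b: np.ndarray) -> float:
    """Colocalization of two per-patch fraction layers.

    Defined as ``sum_k min(a_k, b_k) / sum_k max(a_k, b_k)``: 0 iff the
    supports are disjoint, 1 iff the layers carry identical fractions
    everywhere.  When both layers are empty the statistic is undefined and
    reported as 0 (callers flag it missing).
    """
    a = np.asarray(fracs_a, dtype=float).ravel()
    b = np.asarray(fracs_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(
            f"fraction vectors differ in length ({a.size} vs {b.size})"
        )
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    denom = np.maximum(a, b).sum()
    if denom == 0:
        return 0.0
    return float(np.minimum(a, b).sum() / denom)
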