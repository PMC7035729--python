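"""Texture descriptors and Fisher-discriminant-ratio ranking.

The headline descriptor concatenates the rotation-invariant-uniform LBP
histogram (20 bins) of each of the seven level-1 wavelet detail subbands,
in subband order, giving 7 x 20 = 140 features per volume.  The plain
single-method descriptors (LBP variants on the raw volume, or the raw
detail coefficients) are provided as comparison baselines.

Feature relevance for a two-class problem is scored per feature by the
Fisher discriminant ratio

    FDR = (m1 - m2)^2 / (s1^2 + s2^2)

with per-class means m and standard deviations s; larger is more
discriminative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volio import Volume3D
from .dwt3d import decompose_level1, DETAIL_LABELS
from .lbp3d import LBPConfig, lbp_histogram, variant_n_bins

__all__ = [
    "FeatureVector",
    "FeatureMatrix",
    "FDRRanking",
    "extract_dwt_lbp20",
    "extract_single",
    "fdr_score",
    "rank_by_fdr",
    "COMBINED_LENGTH",
]

COMBINED_LENGTH = 7 * 20  # seven detail subbands x 20 riu bins


@dataclass
class FeatureVector:
    values: np.ndarray
    layout: list[tuple[str, int]]  # (subband or variant label, bin index)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if len(self.layout) != self.values.size:
            raise ValueError(
                f"layout length {len(self.layout)} != value count {self.values.size}"
            )

    def __len__(self) -> int:
        return self.values.size


@dataclass
class FeatureMatrix:
    """Per-volume feature rows with class labels; row order is data order."""

    values: np.ndarray
    labels: list[str]
    layout: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.values.shape[0]} rows vs {len(self.labels)} labels"
            )
        if self.layout is not None and len(self.layout) != self.values.shape[1]:
            raise ValueError("layout length does not match feature count")

    @classmethod
    def from_vectors(cls, vectors: Sequence[FeatureVector],
                     labels: Sequence[str]) -> "FeatureMatrix":
        if not vectors:
            raise ValueError("no feature vectors")
        layout = vectors[0].layout
        for v in vectors[1:]:
            if v.layout != layout:
                raise ValueError("feature vectors have inconsistent layouts")
        return cls(values=np.vstack([v.values for v in vectors]),
                   labels=list(labels), layout=list(layout))

    def class_split(self) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
        labs = list(dict.fromkeys(self.labels))
        if len(labs) != 2:
            raise ValueError(f"exactly two classes required, found {labs}")
        lab_arr = np.asarray(self.labels)
        return (self.values[lab_arr == labs[0]],
                self.values[lab_arr == labs[1]],
                (labs[0], labs[1]))


@dataclass
class FDRRanking:
    scores: np.ndarray         # per-feature FDR (may contain +inf sentinels)
    order: np.ndarray          # feature indices, descending score


def extract_dwt_lbp20(vol: Volume3D, wavelet_name: str = "db2",
                      extension_mode: str = "symmetric",
                      normalize: bool = True) -> FeatureVector:
    """Combined descriptor: riu-LBP histograms of the 7 detail subbands.

    The volume is decomposed once (level 1, db2 by default); each detail
    subband is coded with the 18-neighbour riu LBP and histogrammed into 20
    bins; histograms are concatenated in the fixed subband order, giving a
    140-value vector.  With normalisation on, each 20-bin block sums to 1.
    """
    sb = decompose_level1(vol, wavelet_name, extension_mode)
    cfg = LBPConfig(variant="riu", normalize=normalize)
    values = []
    layout = []
    for lab, det in zip(sb.orientation_labels, sb.details):
        h = lbp_histogram(det, cfg)
        values.append(h.bins)
        layout.extend((lab, b) for b in range(h.bins.size))
    return FeatureVector(values=np.concatenate(values), layout=layout)


def extract_single(vol: Volume3D, method: str, *,
                   wavelet_name: str = "db2", extension_mode: str = "symmetric",
                   normalize: bool = True) -> FeatureVector:
    """Baseline descriptors on the raw volume.

    ``lbp_full`` / ``lbp_uniform`` / ``lbp_riu``: one LBP histogram of the
    named variant (262,144 / 309 / 20 values).  ``dwt_raw``: the raw detail
    coefficients of the level-1 transform, flattened subband by subband.
    """
    lbp_methods = {"lbp_full": "full", "lbp_uniform": "uniform", "lbp_riu": "riu"}
    if method in lbp_methods:
        cfg = LBPConfig(variant=lbp_methods[method], normalize=normalize)
        h = lbp_histogram(vol, cfg)
        layout = [(cfg.variant, b) for b in range(h.bins.size)]
        return FeatureVector(values=h.bins, layout=layout)
    if method == "dwt_raw":
        sb = decompose_level1(vol, wavelet_name, extension_mode)
        values = []
        layout = []
        for lab, det in zip(sb.orientation_labels, sb.details):
            flat = det.data.ravel()
            values.append(flat)
            layout.extend((lab, i) for i in range(flat.size))
        return FeatureVector(values=np.concatenate(values), layout=layout)
    raise ValueError(
        f"unknown method {method!r}; choose lbp_full, lbp_uniform, lbp_riu or dwt_raw"
    )


def fdr_score(class1_values: np.ndarray, class2_values: np.ndarray) -> float:
    """Fisher discriminant ratio of one feature between two classes.

    Uses sample standard deviations (n-1 denominator).  If both classes are
    constant, the score is 0 for equal means and +inf otherwise (the feature
    separates the training data perfectly).
    """
    x1 = np.asarray(class1_values, dtype=np.float64)
    x2 = np.asarray(class2_values, dtype=np.float64)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each class needs at least 2 samples for an FDR score")
    m1, m2 = x1.mean(), x2.mean()
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    denom = v1 + v2
    if denom == 0.0:
        return 0.0 if m1 == m2 else math.inf
    return float((m1 - m2) ** 2 / denom)


def rank_by_fdr(matrix: FeatureMatrix) -> FDRRanking:
    """Score every feature and order indices by descending FDR.

    Ties (including all-zero scores) break by ascending feature index so the
    ranking is deterministic across platforms.
    """
    x1, x2, _ = matrix.class_split()
    if x1.shape[0] < 2 or x2.shape[0] < 2:
        raise ValueError("each class needs at least 2 rows")
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1, v2 = x1.var(axis=0, ddof=1), x2.var(axis=0, ddof=1)
    denom = v1 + v2
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = (m1 - m2) ** 2 / denom
    zero_den = denom == 0.0
    scores[zero_den & (m1 == m2)] = 0.0
    scores[zero_den & (m1 != m2)] = np.inf
    order = np.argsort(-scores, kind="stable")
    return FDRRanking(scores=scores, order=order)
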