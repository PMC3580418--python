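"""The two published prognostic classifiers: a three-gene linear risk score
and a six-gene nearest-cluster-center rule.

Both operate on marker expression normalized housekeeping-first: each array is
normalized to its housekeeping genes (subtracting the mean log2 level, or
dividing by the geometric mean in natural scale), then each marker gene is
median-centred across patients.  The three-gene score dichotomizes each
marker at the cohort median (strictly above = 1) and computes

    RiskScore = 4 * m1 + 3 * m2 - 3 * m3

on the indicators; a score <= 2 predicts good prognosis.  The six-gene rule
compares the Euclidean distance of a patient's normalized six-gene vector to
two training cluster centers; when the distance ratio falls inside the
ambiguity band (default [0.9, 1.11], inclusive) the patient is left
unclassified and ignored downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, ScheduleSpec

GOOD = "good"
POOR = "poor"
UNCLASSIFIED = "unclassified"
CALL_LABELS = (GOOD, POOR, UNCLASSIFIED)

THREE_GENE_WEIGHTS = (4.0, 3.0, -3.0)
THREE_GENE_THRESHOLD = 2.0


@dataclass
class ClusterCenters:
    """Training cluster centers for the six-gene classifier."""

    center_good: np.ndarray
    center_poor: np.ndarray
    ambiguity_band: tuple[float, float] = (0.9, 1.11)
    train_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        self.center_good = np.asarray(self.center_good, dtype=float)
        self.center_poor = np.asarray(self.center_poor, dtype=float)
        if self.center_good.shape != self.center_poor.shape:
            raise ValueError("cluster centers must have equal length")
        if np.allclose(self.center_good, self.center_poor):
            raise ValueError("cluster centers must be distinct")
        lo, hi = self.ambiguity_band
        if not lo < 1 < hi:
            raise ValueError("ambiguity band must straddle 1")

    def in_scale(self, scale: str) -> tuple[np.ndarray, np.ndarray]:
        """Centers are stored in log2-normalized scale; natural-scale
        schedules compare against their elementwise exp2."""
        if scale == "log2":
            return self.center_good, self.center_poor
        return np.exp2(self.center_good), np.exp2(self.center_poor)


def normalize_markers(expr: ExpressionMatrix, marker_genes, housekeeping_genes
                      ) -> ExpressionMatrix:
    """Housekeeping-then-median normalization of marker genes.

    In log2 scale: subtract per array the mean housekeeping log2 level, then
    subtract each marker's across-patient median.  In natural scale: divide by
    the geometric mean of the housekeeping values, then by the gene median.
    """
    V = expr.values
    missing = [g for g in list(marker_genes) + list(housekeeping_genes)
               if g not in V.index]
    if missing:
        raise KeyError(f"gene(s) absent from expression matrix: {missing}")
    markers = V.loc[list(marker_genes)]
    hk = V.loc[list(housekeeping_genes)]
    if expr.scale == "log2":
        M = markers.sub(hk.mean(axis=0), axis=1)
        M = M.sub(M.median(axis=1), axis=0)
    else:
        if (hk.to_numpy() <= 0).any():
            raise ValueError("housekeeping values must be positive in natural scale")
        geo = np.exp(np.log(hk).mean(axis=0))
        M = markers.div(geo, axis=1)
        M = M.div(M.median(axis=1), axis=0)
    from dataclasses import replace
    return replace(expr, values=M)


def three_gene_classify(markers: ExpressionMatrix | pd.DataFrame,
                        weights=THREE_GENE_WEIGHTS,
                        threshold: float = THREE_GENE_THRESHOLD,
                        schedule: ScheduleSpec | None = None) -> pd.DataFrame:
    """Risk-score calls from a (3 x patients) normalized marker matrix.

    The rows must be ordered to match ``weights``.  Indicators are 1 iff the
    value is strictly above the median of the patients in this matrix (the
    classification cohort: one site under separate handling, everyone under
    combined); values exactly at the median count as below.  Calls are
    ``good`` iff the score is <= ``threshold``, else ``poor`` -- the
    three-gene marker never leaves a patient unclassified.
    """
    M = markers.values if isinstance(markers, ExpressionMatrix) else markers
    if M.shape[0] != len(weights):
        raise ValueError(f"expected {len(weights)} marker rows, got {M.shape[0]}")
    indicators = M.gt(M.median(axis=1), axis=0).to_numpy().astype(float)
    scores = np.asarray(weights) @ indicators
    sid = _sid(markers, schedule)
    return pd.DataFrame({
        "patient_id": list(M.columns),
        "call": np.where(scores <= threshold, GOOD, POOR),
        "risk_score": scores,
        "schedule_id": sid,
    })


def six_gene_classify(markers: ExpressionMatrix | pd.DataFrame,
                      centers: ClusterCenters,
                      scale: str | None = None,
                      schedule: ScheduleSpec | None = None) -> pd.DataFrame:
    """Nearest-cluster-center calls from a (6 x patients) normalized matrix.

    The distance ratio ``r = d_good / d_poor`` assigns the patient to the
    nearer center's label unless ``r`` falls inside the closed ambiguity band,
    in which case the patient is unclassified.  A patient exactly on both
    centers (both distances zero) is unclassified.
    """
    if isinstance(markers, ExpressionMatrix):
        scale = markers.scale
        M = markers.values
    else:
        M = markers
        scale = scale or "log2"
    cg, cp = centers.in_scale(scale)
    if M.shape[0] != cg.shape[0]:
        raise ValueError(f"expected {cg.shape[0]} marker rows, got {M.shape[0]}")
    X = M.to_numpy(dtype=float)
    d_good = np.linalg.norm(X - cg[:, None], axis=0)
    d_poor = np.linalg.norm(X - cp[:, None], axis=0)
    lo, hi = centers.ambiguity_band
    calls = np.empty(X.shape[1], dtype=object)
    ratios = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        if d_good[j] == 0 and d_poor[j] == 0:
            calls[j] = UNCLASSIFIED
            ratios[j] = np.nan
            continue
        r = np.inf if d_poor[j] == 0 else d_good[j] / d_poor[j]
        ratios[j] = r
        if lo <= r <= hi:
            calls[j] = UNCLASSIFIED
        else:
            calls[j] = GOOD if r < lo else POOR
    sid = _sid(markers, schedule)
    return pd.DataFrame({
        "patient_id": list(M.columns),
        "call": calls,
        "risk_score": ratios,
        "schedule_id": sid,
    })


def _sid(markers, schedule):
    if schedule is not None:
        return schedule.schedule_id
    if isinstance(markers, ExpressionMatrix) and markers.schedule is not None:
        return markers.schedule.schedule_id
    return ""


def classify_three_gene(expr_list: list[ExpressionMatrix], marker_genes_3,
                        housekeeping_genes) -> pd.DataFrame:
    """Normalize, dichotomize and score per matrix (per site under separate
    handling), then pool the calls across sites."""
    parts = [three_gene_classify(normalize_markers(em, marker_genes_3,
                                                   housekeeping_genes))
             for em in expr_list]
    return pd.concat(parts, ignore_index=True)


def classify_six_gene(expr_list: list[ExpressionMatrix], marker_genes_6,
                      housekeeping_genes, centers: ClusterCenters) -> pd.DataFrame:
    """Per-site housekeeping/median normalization followed by the fixed-center
    distance rule, pooled across sites."""
    parts = [six_gene_classify(normalize_markers(em, marker_genes_6,
                                                 housekeeping_genes), centers)
             for em in expr_list]
    return pd.concat(parts, ignore_index=True)
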