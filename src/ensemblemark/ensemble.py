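"""Treating the 24 pre-processing schedules as an ensemble classifier.

Each patient is a vector of per-schedule calls.  Patients classified
identically by every schedule (and never left unclassified) are *robust*;
everyone else is *ambiguous* and retains, for downstream evaluation, the call
of the reference schedule (the original study's protocol: RMA, default
annotation, separate handling).  A generalized majority-vote mode with an
agreement threshold tau in (0.5, 1] is provided; tau = 1 reproduces strict
unanimity.

The module also implements the univariate sensitivity screen: every feature
is median-dichotomized under every schedule, fitted with an unadjusted Cox
model, and summarized by how many schedules call it significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifiers import CALL_LABELS, UNCLASSIFIED
from .survival import BinaryCoxEngine, NonIdentifiableError, binary_metrics, cox_fit


@dataclass
class ClassificationEnsemble:
    """Patients x schedules matrix of calls with a designated reference column."""

    calls: pd.DataFrame  # index patient_id, columns schedule_id
    reference_schedule: str

    def __post_init__(self):
        if self.reference_schedule not in self.calls.columns:
            raise ValueError(
                f"reference schedule {self.reference_schedule!r} not among columns")
        bad = set(self.calls.to_numpy().ravel()) - set(CALL_LABELS)
        if bad:
            raise ValueError(f"unknown call labels: {sorted(bad)}")

    @property
    def n_schedules(self) -> int:
        return self.calls.shape[1]


@dataclass
class RobustnessPartition:
    """Unanimous (robust) vs discordant (ambiguous) patients."""

    robust_ids: list[str]
    ambiguous_ids: list[str]
    concordance: pd.Series  # fraction of schedules agreeing with the majority
    majority: pd.Series  # the majority call per patient
    tau: float = 1.0

    def __post_init__(self):
        overlap = set(self.robust_ids) & set(self.ambiguous_ids)
        if overlap:
            raise ValueError(f"patients in both partitions: {sorted(overlap)[:5]}")


def build_ensemble(call_tables: dict[str, pd.DataFrame],
                   reference_schedule: str) -> ClassificationEnsemble:
    """Assemble per-schedule call tables into one patients x schedules matrix.

    Schedule columns are ordered canonically (sorted schedule id); every
    patient must be present in every table.
    """
    columns = {}
    patients = None
    for sid in sorted(call_tables):
        table = call_tables[sid]
        s = table.set_index("patient_id")["call"]
        if s.index.duplicated().any():
            dup = s.index[s.index.duplicated()][0]
            raise ValueError(f"duplicate patient {dup!r} in schedule {sid}")
        if patients is None:
            patients = set(s.index)
        elif set(s.index) != patients:
            missing = patients.symmetric_difference(s.index)
            raise ValueError(
                f"schedule {sid} misses/adds patients: {sorted(missing)[:5]}")
        columns[sid] = s
    matrix = pd.DataFrame(columns)
    matrix = matrix.loc[sorted(matrix.index)]
    return ClassificationEnsemble(calls=matrix, reference_schedule=reference_schedule)


def _majority_and_concordance(calls: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    counts = {lab: (calls == lab).sum(axis=1) for lab in CALL_LABELS}
    counts = pd.DataFrame(counts)
    majority = counts.idxmax(axis=1)  # ties break in CALL_LABELS order
    concordance = counts.max(axis=1) / calls.shape[1]
    return majority, concordance


def partition_unanimous(ens: ClassificationEnsemble, tau: float = 1.0
                        ) -> RobustnessPartition:
    """Partition patients into robust vs ambiguous.

    With ``tau = 1`` a patient is robust iff all schedules agree and none is
    unclassified (an unclassifiable schedule is itself discordant evidence).
    With ``tau < 1`` a patient is robust iff at least a fraction tau of
    schedules agree on a good/poor majority call.
    """
    if not 0.5 < tau <= 1.0:
        raise ValueError("tau must be in (0.5, 1.0]")
    majority, concordance = _majority_and_concordance(ens.calls)
    robust = (concordance >= tau) & (majority != UNCLASSIFIED)
    if tau == 1.0:
        robust &= concordance == 1.0
    ids = ens.calls.index
    return RobustnessPartition(
        robust_ids=list(ids[robust]),
        ambiguous_ids=list(ids[~robust]),
        concordance=concordance,
        majority=majority,
        tau=tau,
    )


def evaluate_partition(part: RobustnessPartition, ens: ClassificationEnsemble,
                       clinical: pd.DataFrame, adjust_stage: bool = True,
                       horizon: float = 60.0) -> dict:
    """Paired survival + binary evaluation of the robust and ambiguous subsets.

    The robust subset is evaluated with its unanimous (majority) calls; the
    ambiguous subset with the reference schedule's calls, excluding patients
    the reference schedule left unclassified (their count is reported).
    Non-identifiable fits are reported as such rather than raised.
    """
    from .survival import truncate_survival

    out = {}
    truncated = truncate_survival(clinical, horizon)
    specs = {
        "robust": pd.DataFrame({
            "patient_id": part.robust_ids,
            "call": part.majority.loc[part.robust_ids].to_numpy(),
        }),
        "ambiguous": pd.DataFrame({
            "patient_id": part.ambiguous_ids,
            "call": ens.calls.loc[part.ambiguous_ids,
                                  ens.reference_schedule].to_numpy(),
        }),
    }
    for name, calls in specs.items():
        n_unclassified_ref = int((calls["call"] == UNCLASSIFIED).sum())
        calls = calls[calls["call"] != UNCLASSIFIED]
        entry = {"n": len(calls), "n_unclassified_reference": n_unclassified_ref,
                 "fit": None, "metrics": None, "note": ""}
        if len(calls) == 0:
            entry["note"] = "empty subset"
        else:
            try:
                entry["fit"] = cox_fit(calls, truncated, adjust_stage=adjust_stage)
            except NonIdentifiableError as exc:
                entry["note"] = str(exc)
            entry["metrics"] = binary_metrics(calls, clinical, horizon)
        out[name] = entry
    return out


def univariate_screen(matrices_by_schedule: dict[str, list], clinical: pd.DataFrame,
                      alpha: float = 0.05) -> dict:
    """Median-dichotomized unadjusted Cox screen of every feature x schedule.

    For each feature and schedule the cohort is split at the within-matrix
    median (per site under separate handling, pooled afterwards) and the
    binary group effect is fitted with the Efron partial likelihood.  Raw
    p-values are thresholded at ``alpha`` with no multiplicity correction;
    constant (non-dichotomizable) features are recorded as non-testable.

    Returns a dict with ``pvalues`` and ``hrs`` (features x schedules),
    ``n_significant`` per feature, and the cohort-level fractions
    ``frac_significant_all`` and ``frac_significant_any``.
    """
    clin = clinical.set_index("patient_id")
    engine = BinaryCoxEngine(clin["time_months"], clin["event"])
    features = None
    pcols, hcols = {}, {}
    for sid in sorted(matrices_by_schedule):
        mats = matrices_by_schedule[sid]
        indic = pd.concat(
            [em.values.gt(em.values.median(axis=1), axis=0) for em in mats], axis=1)
        indic = indic.reindex(columns=clin.index)
        if indic.isna().any().any():
            raise ValueError(f"schedule {sid} does not cover all patients")
        if features is None:
            features = list(indic.index)
        pvals = np.full(len(features), np.nan)
        hrs = np.full(len(features), np.nan)
        X = indic.loc[features].to_numpy(dtype=float)
        for i in range(len(features)):
            res = engine.fit(X[i])
            if res is not None:
                pvals[i] = res["p"]
                hrs[i] = res["hr"]
        pcols[sid] = pvals
        hcols[sid] = hrs
    pvalues = pd.DataFrame(pcols, index=features)
    hrs = pd.DataFrame(hcols, index=features)
    sig = pvalues <= alpha  # NaN (non-testable) counts as not significant
    n_sig = sig.sum(axis=1)
    n_sched = pvalues.shape[1]
    return {
        "pvalues": pvalues,
        "hrs": hrs,
        "n_significant": n_sig,
        "frac_significant_all": float((n_sig == n_sched).mean()),
        "frac_significant_any": float((n_sig >= 1).mean()),
        "alpha": alpha,
        "non_testable": list(pvalues.index[pvalues.isna().all(axis=1)]),
    }
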