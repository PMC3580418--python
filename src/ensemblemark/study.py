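"""End-to-end driver reproducing the full study design on a synthetic cohort.

``run_study`` wires every stage together: simulate a probe-level multi-site
cohort, pre-process it under the 24 schedules, classify every patient with
the three-gene and/or six-gene marker per schedule, evaluate each schedule's
calls (overall stage-adjusted plus per-stage subgroups), compute Schoenfeld
power curves from the realized event counts, and finally partition patients
by cross-schedule unanimity and evaluate the robust and ambiguous subsets.
All outputs land under one run directory with a JSON manifest (seed, schedule
ids, file hashes, warnings) and the whole run is deterministic under a fixed
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as emio
from .classifiers import classify_six_gene, classify_three_gene
from .cohort import STAGES, CohortSpec, generate_cluster_centers, generate_cohort
from .ensemble import build_ensemble, evaluate_partition, partition_unanimous
from .power import power_curves
from .preprocess import (compute_schedule_matrices, enumerate_schedules,
                         reference_schedule)
from .survival import (NonIdentifiableError, binary_metrics, cox_fit,
                       truncate_survival)

logger = logging.getLogger("ensemblemark")

MARKERS = ("three", "six")


@dataclass
class RunConfig:
    """Configuration of one end-to-end study run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    marker: str = "both"  # "three" | "six" | "both"
    schedules: str | list[str] = "all"
    out_dir: str = "run"
    seed: int | None = None
    subgroups: tuple[str, ...] = STAGES
    horizon: float = 60.0

    def __post_init__(self):
        if self.marker not in MARKERS + ("both",):
            raise ValueError(f"marker must be one of {MARKERS + ('both',)}")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        unknown = set(self.subgroups) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage subgroup(s): {sorted(unknown)}")

    @property
    def markers(self) -> tuple[str, ...]:
        return MARKERS if self.marker == "both" else (self.marker,)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _fit_row(fit, metrics) -> dict:
    row = {"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_wald": np.nan,
           "n": np.nan, "events": np.nan, "sensitivity": np.nan,
           "specificity": np.nan, "accuracy": np.nan}
    if fit is not None:
        row.update(hr=fit.hr, ci_low=fit.ci_low, ci_high=fit.ci_high,
                   p_wald=fit.p_wald, n=fit.n_patients, events=fit.n_events)
    if metrics is not None:
        row.update(
            sensitivity=np.nan if metrics.sensitivity is None else metrics.sensitivity,
            specificity=np.nan if metrics.specificity is None else metrics.specificity,
            accuracy=np.nan if metrics.accuracy is None else metrics.accuracy)
    return row


def _evaluate_calls(calls: pd.DataFrame, clinical: pd.DataFrame,
                    truncated: pd.DataFrame, subgroups, notes: list[str],
                    label: str) -> list[dict]:
    rows = []
    try:
        fit = cox_fit(calls, truncated, adjust_stage=True)
    except NonIdentifiableError as exc:
        fit = None
        notes.append(f"{label}/all: {exc}")
    rows.append({"subgroup": "all",
                 **_fit_row(fit, binary_metrics(calls, clinical))})
    for st in subgroups:
        clin_st = truncated[truncated["stage"] == st]
        calls_st = calls[calls["patient_id"].isin(clin_st["patient_id"])]
        try:
            # subgroup fits are unadjusted within stage
            fit = cox_fit(calls_st, clin_st, adjust_stage=False)
        except (NonIdentifiableError, ValueError) as exc:
            fit = None
            notes.append(f"{label}/{st}: {exc}")
        met = (binary_metrics(calls_st, clinical[clinical["stage"] == st])
               if len(calls_st) else None)
        rows.append({"subgroup": st, **_fit_row(fit, met)})
    return rows


def run_study(config: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest (also written to disk)."""
    t0 = _time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = config.cohort
    if config.seed is not None:
        spec = replace(spec, seed=config.seed)

    manifest: dict = {"seed": spec.seed, "marker": config.marker,
                      "horizon": config.horizon, "warnings": [],
                      "timings_s": {}, "outputs": {}}
    caught: list[str] = []

    def record(path: Path):
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    # -- simulate -----------------------------------------------------------
    logger.info("simulating cohort (seed=%d)", spec.seed)
    cohort, clinical = generate_cohort(spec)
    emio.write_cohort(cohort, clinical, out / "cohort")
    for p in sorted((out / "cohort").iterdir()):
        record(p)
    truncated = truncate_survival(clinical, config.horizon)
    manifest["timings_s"]["simulate"] = round(_time.time() - t0, 3)

    centers = None
    if "six" in config.markers:
        centers = generate_cluster_centers(cohort, clinical)
        emio.write_centers(centers, out / "cohort" / "centers.json")
        record(out / "cohort" / "centers.json")

    # -- preprocess ---------------------------------------------------------
    t1 = _time.time()
    schedules = enumerate_schedules()
    if config.schedules != "all":
        wanted = set(config.schedules)
        schedules = [s for s in schedules if s.schedule_id in wanted]
        missing = wanted - {s.schedule_id for s in schedules}
        if missing:
            raise ValueError(f"unknown schedule id(s): {sorted(missing)}")
    required = (tuple(spec.marker_genes_3) + tuple(spec.marker_genes_6)
                + tuple(spec.housekeeping_genes))
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        matrices = compute_schedule_matrices(cohort, clinical, schedules, required)
    caught.extend(str(w.message) for w in wlist)
    expr_dir = out / "expression"
    expr_dir.mkdir(exist_ok=True)
    for sid, mats in matrices.items():
        for em in mats:
            suffix = "" if em.site in (None, "combined") else f".{em.site}"
            path = expr_dir / f"{sid}{suffix}.tsv"
            emio.write_expression_matrix(em, path)
            record(path)
    manifest["schedules"] = list(matrices)
    manifest["timings_s"]["preprocess"] = round(_time.time() - t1, 3)

    # -- classify + evaluate ------------------------------------------------
    results_dir = out / "results"
    results_dir.mkdir(exist_ok=True)
    ref_id = reference_schedule().schedule_id
    for marker in config.markers:
        t2 = _time.time()
        calls_dir = out / "calls" / marker
        calls_dir.mkdir(parents=True, exist_ok=True)
        call_tables: dict[str, pd.DataFrame] = {}
        rows = []
        for sid, mats in matrices.items():
            if marker == "three":
                calls = classify_three_gene(mats, spec.marker_genes_3,
                                            spec.housekeeping_genes)
            else:
                calls = classify_six_gene(mats, spec.marker_genes_6,
                                          spec.housekeeping_genes, centers)
            call_tables[sid] = calls
            path = calls_dir / f"{sid}.csv"
            emio.write_calls(calls, path)
            record(path)
            for row in _evaluate_calls(calls, clinical, truncated,
                                       config.subgroups, caught,
                                       f"{marker}/{sid}"):
                rows.append({"schedule_id": sid, **row})
        results = pd.DataFrame(rows)
        results_path = results_dir / f"schedule_results_{marker}.csv"
        results.to_csv(results_path, index=False, float_format="%.6g")
        record(results_path)

        # -- ensemble partition --------------------------------------------
        ens_dir = out / "ensemble"
        ens_dir.mkdir(exist_ok=True)
        ens = build_ensemble(call_tables, reference_schedule=ref_id)
        part = partition_unanimous(ens)
        ens.calls.to_csv(ens_dir / f"{marker}_matrix.csv", index_label="patient_id")
        record(ens_dir / f"{marker}_matrix.csv")
        pd.DataFrame({
            "patient_id": ens.calls.index,
            "robust_flag": [int(p in set(part.robust_ids)) for p in ens.calls.index],
            "concordance": part.concordance.to_numpy(),
            "majority_call": part.majority.to_numpy(),
        }).to_csv(ens_dir / f"{marker}_partition.csv", index=False,
                  float_format="%.6g")
        record(ens_dir / f"{marker}_partition.csv")
        paired = evaluate_partition(part, ens, clinical, horizon=config.horizon)
        paired_rows = []
        for subset, entry in paired.items():
            paired_rows.append({
                "subset": subset, "n": entry["n"],
                "n_unclassified_reference": entry["n_unclassified_reference"],
                "note": entry["note"],
                **_fit_row(entry["fit"], entry["metrics"])})
        pd.DataFrame(paired_rows).to_csv(ens_dir / f"{marker}_paired.csv",
                                         index=False, float_format="%.6g")
        record(ens_dir / f"{marker}_paired.csv")
        manifest[f"partition_{marker}"] = {
            "n_robust": len(part.robust_ids),
            "n_ambiguous": len(part.ambiguous_ids)}
        manifest["timings_s"][f"classify_{marker}"] = round(_time.time() - t2, 3)

    # -- power curves from realized event counts ----------------------------
    t3 = _time.time()
    events = {"all": int(truncated["event"].sum())}
    for st in config.subgroups:
        events[st] = int(truncated.loc[truncated["stage"] == st, "event"].sum())
    curves = power_curves({k: v for k, v in events.items() if v >= 1})
    curve_rows = []
    for c in curves:
        for h, p in zip(c.hr, c.power):
            curve_rows.append({"cohort": c.label, "ne": c.ne, "hr": h, "power": p})
    power_path = results_dir / "power_curves.csv"
    pd.DataFrame(curve_rows).to_csv(power_path, index=False, float_format="%.6g")
    record(power_path)
    manifest["power_hr_at_0.8"] = {c.label: c.hr_at_threshold for c in curves}
    manifest["timings_s"]["power"] = round(_time.time() - t3, 3)

    manifest["warnings"] = caught
    manifest["n_partition_evaluations"] = 2 * len(config.markers)
    manifest["config"] = {"marker": config.marker, "horizon": config.horizon,
                          "subgroups": list(config.subgroups),
                          "cohort": asdict(spec)}
    from importlib.metadata import PackageNotFoundError, version
    try:
        manifest["version"] = version("ensemblemark")
    except PackageNotFoundError:
        manifest["version"] = "unknown"
    manifest["timings_s"]["total"] = round(_time.time() - t0, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("study complete in %.1fs -> %s", _time.time() - t0, out)
    return manifest
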