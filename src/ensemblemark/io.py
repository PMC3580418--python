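"""Plain-text I/O for cohorts, expression matrices, clinical tables and calls.

All formats are human-inspectable: tab-delimited matrices (probes or genes as
rows, arrays as columns) with ``# key: value`` header comments, CSV tables,
and JSON sidecars/manifests.  Readers validate structure and report the
offending id or line on failure; write -> read round-trips are lossless on
ids/labels and to 1e-12 on values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import CALL_LABELS, ClusterCenters
from .cohort import STAGES, CohortSpec, ProbeLevelCohort
from .preprocess import ExpressionMatrix, ScheduleSpec


class ParseError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def write_expression_matrix(em: ExpressionMatrix, path, sidecar: bool = True) -> None:
    path = Path(path)
    header = {
        "scale": em.scale,
        "level": em.level,
        "site": em.site or "",
        "schedule_id": em.schedule.schedule_id if em.schedule else "",
    }
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        em.values.to_csv(fh, sep="\t", index_label="feature_id",
                         float_format="%.12g")
    if sidecar and em.schedule is not None:
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(em.schedule.to_dict(), fh, indent=1)


def read_expression_matrix(path) -> ExpressionMatrix:
    path = Path(path)
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
            pos = fh.tell()
        values = pd.read_csv(fh, sep="\t", index_col="feature_id")
    schedule = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        schedule = ScheduleSpec.from_dict(json.loads(sidecar.read_text()))
    elif header.get("schedule_id"):
        schedule = ScheduleSpec.from_id(header["schedule_id"])
    return ExpressionMatrix(values=values, scale=header.get("scale", "log2"),
                            schedule=schedule, level=header.get("level", "gene"),
                            site=header.get("site") or None)


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

_CLINICAL_REQUIRED = ("patient_id", "site", "stage", "time_months", "event")


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False, float_format="%.12g")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"clinical table missing column(s): {missing}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise ParseError(f"duplicate patient_id {dup.iloc[0]!r} in clinical table")
    for col, caster in (("time_months", float), ("event", int)):
        parsed = []
        for i, raw in enumerate(df[col]):
            try:
                parsed.append(caster(raw))
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric value {raw!r} in column {col!r} at line {i + 2}")
        df[col] = parsed
    bad_stage = set(df["stage"]) - set(STAGES)
    if bad_stage:
        raise ParseError(f"unknown stage label(s): {sorted(bad_stage)}")
    if (df["time_months"] < 0).any():
        raise ParseError("negative survival time in clinical table")
    if not df["event"].isin((0, 1)).all():
        raise ParseError("event indicator must be 0 or 1")
    if "high_noise" in df.columns:
        df["high_noise"] = df["high_noise"].astype(int)
    return df


# ---------------------------------------------------------------------------
# call tables
# ---------------------------------------------------------------------------

def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, index=False, float_format="%.12g")


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", "call") if c not in df.columns]
    if missing:
        raise ParseError(f"calls table missing column(s): {missing}")
    bad = set(df["call"]) - set(CALL_LABELS)
    if bad:
        raise ParseError(f"unknown call label(s): {sorted(bad)}")
    key = (df[["patient_id", "schedule_id"]] if "schedule_id" in df.columns
           else df[["patient_id"]])
    dup = df["patient_id"][key.duplicated()]
    if len(dup):
        raise ParseError(f"duplicate patient_id {dup.iloc[0]!r} in calls table")
    return df


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def write_cohort(cohort: ProbeLevelCohort, clinical: pd.DataFrame, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for site, matrix in cohort.intensities.items():
        matrix.to_csv(out / f"intensities_{site}.tsv", sep="\t",
                      index_label="probe_id", float_format="%.12g")
    cohort.probe_info.to_csv(out / "probe_map.tsv", sep="\t",
                             index_label="probe_id", float_format="%.12g")
    cohort.annotation_default.to_csv(out / "annotation_default.tsv", sep="\t",
                                     index=False)
    cohort.annotation_alternative.to_csv(out / "annotation_alternative.tsv",
                                         sep="\t", index=False)
    write_clinical(clinical, out / "clinical.csv")
    if cohort.spec is not None:
        from dataclasses import asdict
        with open(out / "cohort_spec.json", "w") as fh:
            json.dump(asdict(cohort.spec), fh, indent=1)


def read_cohort(in_dir) -> tuple[ProbeLevelCohort, pd.DataFrame]:
    src = Path(in_dir)
    intensities = {}
    for path in sorted(src.glob("intensities_*.tsv")):
        site = path.stem.removeprefix("intensities_")
        intensities[site] = pd.read_csv(path, sep="\t", index_col="probe_id")
    if not intensities:
        raise ParseError(f"no intensities_*.tsv files under {src}")
    probe_info = pd.read_csv(src / "probe_map.tsv", sep="\t", index_col="probe_id")
    ann_def = pd.read_csv(src / "annotation_default.tsv", sep="\t", dtype=str)
    ann_alt = pd.read_csv(src / "annotation_alternative.tsv", sep="\t", dtype=str)
    clinical = read_clinical(src / "clinical.csv")
    spec = None
    spec_path = src / "cohort_spec.json"
    if spec_path.exists():
        spec = CohortSpec.from_dict(json.loads(spec_path.read_text()))
    return ProbeLevelCohort(
        intensities=intensities, probe_info=probe_info,
        annotation_default=ann_def, annotation_alternative=ann_alt,
        spec=spec), clinical


# ---------------------------------------------------------------------------
# cluster centers
# ---------------------------------------------------------------------------

def write_centers(centers: ClusterCenters, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "center_good": list(centers.center_good),
            "center_poor": list(centers.center_poor),
            "ambiguity_band": list(centers.ambiguity_band),
            "train_ids": list(centers.train_ids) if centers.train_ids else None,
        }, fh, indent=1)


def read_centers(path) -> ClusterCenters:
    d = json.loads(Path(path).read_text())
    return ClusterCenters(
        center_good=np.asarray(d["center_good"], dtype=float),
        center_poor=np.asarray(d["center_poor"], dtype=float),
        ambiguity_band=tuple(d.get("ambiguity_band", (0.9, 1.11))),
        train_ids=tuple(d["train_ids"]) if d.get("train_ids") else None)
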