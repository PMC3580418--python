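"""Synthetic multi-site probe-level microarray cohorts with survival outcomes.

This module generates desk-scale stand-ins for a multi-institution lung-cancer
expression cohort: per-site matrices of strictly positive probe intensities
(probes grouped into ProbeSets, with per-probe affinity and GC content), a
clinical table (stage, overall-survival time, censoring indicator) and a
planted two-group prognostic structure on designated marker genes whose true
hazard ratio is configurable.  Everything downstream -- pre-processing
schedules, the two marker classifiers, survival evaluation and the ensemble
robustness analysis -- is testable against the known simulation truth.

Survival model
--------------
Event times are exponential.  A patient in latent group *poor* has hazard
``lambda0 * stage_hr[stage] * planted_hr`` while a *good* patient has hazard
``lambda0 * stage_hr[stage]``; latent group is independent of stage, so the
stage-adjusted Cox hazard ratio between latent groups equals ``planted_hr``
exactly.  Censoring is independent exponential with the per-patient rate tuned
so that the probability of censoring equals ``censor_rate``.

Measurement model
-----------------
For gene g, patient j at site s the log2 signal is::

    s_gj = base_g + effect_g * 1[j poor] + batch_{s,g} + N(0, noise_sd_j)

and a probe p of that gene's ProbeSet reads::

    intensity = 2 ** (s_gj + affinity_p + N(0, probe_noise_sd))
                + background_scale * (0.5 + gc_p) * 2 ** N(0, 0.3)

i.e. a strictly positive optical background that increases with the probe's GC
fraction, giving GC-aware background correction genuine signal to exploit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

STAGES = ("IA", "IB", "II", "III")

GOOD = "good"
POOR = "poor"


class CohortSpecError(ValueError):
    """Raised when a cohort specification violates an invariant."""


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic multi-site cohort.

    Defaults mirror a 442-patient four-site validation cohort: per-site sizes
    (111, 111, 110, 110) and a stage mix of roughly 26% IA, 37% IB, 21% II and
    16% III, with ~53% of patients experiencing an event.
    """

    n_sites: int = 4
    patients_per_site: tuple[int, ...] = (111, 111, 110, 110)
    stage_fractions: tuple[float, float, float, float] = (0.26, 0.37, 0.21, 0.16)
    n_genes: int = 200
    n_probes_per_probeset: int = 11

    # marker / housekeeping gene identities (placeholders standing for the
    # published three-gene and six-gene signatures and for ACTB/BAT1/B2M/TBP)
    marker_genes_3: tuple[str, str, str] = ("G0000", "G0001", "G0002")
    marker_genes_6: tuple[str, ...] = (
        "G0003", "G0004", "G0005", "G0006", "G0007", "G0008")
    housekeeping_genes: tuple[str, ...] = ("G0009", "G0010", "G0011", "G0012")
    marker_signs_3: tuple[int, int, int] = (1, 1, -1)
    marker_signs_6: tuple[int, ...] = (1, 1, 1, -1, -1, -1)
    effect_log2: float = 1.0

    planted_hr: float = 2.0
    stage_hazard_ratios: tuple[float, float, float, float] = (1.0, 1.4, 2.0, 2.8)
    baseline_median_survival: float = 60.0  # months, good-prognosis stage IA
    censor_rate: float = 0.47

    batch_shift_sd: float = 0.3
    biological_sd: float = 0.5  # patient-level expression variation, log2
    noise_sd: float = 0.5  # per-probe measurement noise, log2
    high_noise_fraction: float = 0.0
    high_noise_sd: float = 2.5
    background_scale: float = 30.0

    second_probeset_fraction: float = 0.5
    alt_drop_fraction: float = 0.1
    alt_reassign_fraction: float = 0.1

    seed: int = 0

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_sites < 1:
            raise CohortSpecError("n_sites must be >= 1")
        if len(self.patients_per_site) != self.n_sites:
            raise CohortSpecError(
                "patients_per_site must have one entry per site "
                f"(n_sites={self.n_sites}, got {len(self.patients_per_site)})")
        if any(n < 1 for n in self.patients_per_site):
            raise CohortSpecError("patients_per_site entries must be >= 1")
        if len(self.stage_fractions) != len(STAGES):
            raise CohortSpecError("stage_fractions must have four entries")
        if any(f < 0 for f in self.stage_fractions):
            raise CohortSpecError("stage_fractions must be non-negative")
        if abs(sum(self.stage_fractions) - 1.0) > 1e-9:
            raise CohortSpecError("stage_fractions must sum to 1")
        if self.planted_hr <= 0:
            raise CohortSpecError("planted_hr must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise CohortSpecError("censor_rate must be in [0, 1)")
        if self.n_probes_per_probeset < 1:
            raise CohortSpecError("n_probes_per_probeset must be >= 1")
        if len(self.marker_genes_3) != 3 or len(self.marker_signs_3) != 3:
            raise CohortSpecError("marker_genes_3 / marker_signs_3 must have length 3")
        if len(self.marker_genes_6) != 6 or len(self.marker_signs_6) != 6:
            raise CohortSpecError("marker_genes_6 / marker_signs_6 must have length 6")
        if len(self.housekeeping_genes) != 4:
            raise CohortSpecError("housekeeping_genes must have length 4")
        special = (tuple(self.marker_genes_3) + tuple(self.marker_genes_6)
                   + tuple(self.housekeeping_genes))
        if len(set(special)) != len(special):
            raise CohortSpecError(
                "marker_genes_3, marker_genes_6 and housekeeping_genes must be disjoint")
        known = {_gene_id(i) for i in range(self.n_genes)}
        missing = [g for g in special if g not in known]
        if missing:
            raise CohortSpecError(
                f"marker/housekeeping gene ids not in gene universe (n_genes="
                f"{self.n_genes}): {missing}")
        for name in ("noise_sd", "high_noise_sd", "biological_sd",
                     "batch_shift_sd", "effect_log2"):
            if getattr(self, name) < 0:
                raise CohortSpecError(f"{name} must be >= 0")
        if not 0 <= self.high_noise_fraction <= 1:
            raise CohortSpecError("high_noise_fraction must be in [0, 1]")
        if not 0 <= self.alt_drop_fraction < 1:
            raise CohortSpecError("alt_drop_fraction must be in [0, 1)")
        if not 0 <= self.alt_reassign_fraction < 1:
            raise CohortSpecError("alt_reassign_fraction must be in [0, 1)")
        if self.baseline_median_survival <= 0:
            raise CohortSpecError("baseline_median_survival must be > 0")

    @property
    def gene_ids(self) -> list[str]:
        return [_gene_id(i) for i in range(self.n_genes)]

    @property
    def special_genes(self) -> tuple[str, ...]:
        return (tuple(self.marker_genes_3) + tuple(self.marker_genes_6)
                + tuple(self.housekeeping_genes))

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        valid = {f.name for f in fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise CohortSpecError(f"unknown cohort spec fields: {sorted(unknown)}")
        coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        spec = cls(**coerced)
        spec.validate()
        return spec


@dataclass
class ProbeLevelCohort:
    """Per-site probe-intensity matrices plus probe and ProbeSet annotation.

    ``intensities`` maps site label to a (probes x arrays) DataFrame on the
    natural intensity scale.  ``probe_info`` is indexed by probe id with
    columns ``probeset_id``, ``gc_fraction`` and ``affinity`` (log2 units).
    Each annotation is a ProbeSet -> gene map (columns ``probeset_id``,
    ``gene_id``); the alternative annotation is a perturbed remapping in which
    a fraction of ProbeSets are dropped or reassigned, emulating updated
    Entrez-based ProbeSet definitions.
    """

    intensities: dict[str, pd.DataFrame]
    probe_info: pd.DataFrame
    annotation_default: pd.DataFrame
    annotation_alternative: pd.DataFrame
    spec: CohortSpec | None = None
    truth: pd.DataFrame | None = None  # gene x patient true log2 signal

    @property
    def sites(self) -> list[str]:
        return list(self.intensities)

    @property
    def patient_ids(self) -> list[str]:
        return list(itertools.chain.from_iterable(
            m.columns for m in self.intensities.values()))

    def annotation(self, name: str) -> pd.DataFrame:
        if name == "default":
            return self.annotation_default
        if name == "alternative":
            return self.annotation_alternative
        raise ValueError(f"unknown annotation {name!r} (use 'default' or 'alternative')")


def _allocate_stages(n: int, fractions: tuple[float, ...],
                     rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of n patients over stages, shuffled."""
    raw = np.asarray(fractions) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    stages = np.repeat(np.asarray(STAGES), counts)
    return stages[rng.permutation(n)]


def generate_cohort(spec: CohortSpec) -> tuple[ProbeLevelCohort, pd.DataFrame]:
    """Generate a probe-level cohort and its clinical table.

    Deterministic under a fixed ``spec.seed``: the same spec always yields
    bit-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    gene_ids = spec.gene_ids
    n_genes = spec.n_genes
    base = rng.uniform(5.0, 11.0, n_genes)
    # marker and housekeeping genes sit in the upper intensity range: signature
    # genes must be measurable above optical background, and housekeeping genes
    # are canonically highly expressed
    special_idx = [gene_ids.index(g) for g in spec.special_genes]
    base[special_idx] = rng.uniform(8.0, 11.0, len(special_idx))

    # one ProbeSet per gene, plus a second one for a random subset of genes
    has_second = rng.random(n_genes) < spec.second_probeset_fraction
    probeset_gene: list[tuple[str, int]] = []
    for i, gid in enumerate(gene_ids):
        probeset_gene.append((f"{gid}_a", i))
        if has_second[i]:
            probeset_gene.append((f"{gid}_b", i))

    k = spec.n_probes_per_probeset
    probe_rows = []
    probe_gene_idx = []
    for psid, gi in probeset_gene:
        gc = rng.uniform(0.25, 0.75, k)
        affinity = rng.normal(0.0, 0.7, k)
        for p in range(k):
            probe_rows.append((f"{psid}_p{p:02d}", psid, gc[p], affinity[p]))
            probe_gene_idx.append(gi)
    probe_info = pd.DataFrame(
        probe_rows, columns=["probe_id", "probeset_id", "gc_fraction", "affinity"]
    ).set_index("probe_id")
    probe_gene_idx = np.asarray(probe_gene_idx)

    # planted prognostic effect on marker genes (log2 shift in the poor group)
    effect = np.zeros(n_genes)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for g, s in zip(spec.marker_genes_3, spec.marker_signs_3):
        effect[gene_pos[g]] = s * spec.effect_log2
    for g, s in zip(spec.marker_genes_6, spec.marker_signs_6):
        effect[gene_pos[g]] = s * spec.effect_log2

    batch = rng.normal(0.0, spec.batch_shift_sd, (spec.n_sites, n_genes))
    lambda0 = np.log(2.0) / spec.baseline_median_survival
    stage_hr = dict(zip(STAGES, spec.stage_hazard_ratios))

    intensities: dict[str, pd.DataFrame] = {}
    clin_frames = []
    truth_frames = []
    gc = probe_info["gc_fraction"].to_numpy()
    affinity = probe_info["affinity"].to_numpy()

    for s in range(spec.n_sites):
        site = f"site{s + 1:02d}"
        n_s = spec.patients_per_site[s]
        pids = [f"{site}-p{j + 1:03d}" for j in range(n_s)]

        poor = rng.random(n_s) < 0.5
        stages = _allocate_stages(n_s, spec.stage_fractions, rng)
        high = rng.random(n_s) < spec.high_noise_fraction

        lam = lambda0 * np.array([stage_hr[st] for st in stages])
        lam = lam * np.where(poor, spec.planted_hr, 1.0)
        t_event = rng.exponential(1.0 / lam)
        if spec.censor_rate > 0:
            mu = lam * spec.censor_rate / (1.0 - spec.censor_rate)
            t_cens = rng.exponential(1.0 / mu)
        else:
            t_cens = np.full(n_s, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)

        clin_frames.append(pd.DataFrame({
            "patient_id": pids,
            "site": site,
            "stage": stages,
            "time_months": time,
            "event": event,
            "latent_group": np.where(poor, POOR, GOOD),
            "high_noise": high.astype(int),
        }))

        # the patient's true expression: baseline + planted effect + batch +
        # biological variation; per-probe measurement noise (noise_sd, or
        # high_noise_sd for flagged patients) is added on top per probe, so
        # summarization algorithms see -- and weight -- it differently
        signal = (base[:, None] + batch[s][:, None]
                  + np.outer(effect, poor.astype(float))
                  + rng.normal(0.0, spec.biological_sd, (n_genes, n_s)))
        truth_frames.append(pd.DataFrame(signal, index=gene_ids, columns=pids))

        sd_j = np.where(high, spec.high_noise_sd, spec.noise_sd)
        probe_log2 = (signal[probe_gene_idx] + affinity[:, None]
                      + rng.normal(0.0, 1.0, (len(probe_info), n_s)) * sd_j[None, :])
        background = (spec.background_scale * (0.5 + gc)[:, None]
                      * np.exp2(rng.normal(0.0, 0.3, (len(probe_info), n_s))))
        intensities[site] = pd.DataFrame(
            np.exp2(probe_log2) + background, index=probe_info.index, columns=pids)

    clinical = pd.concat(clin_frames, ignore_index=True)
    truth = pd.concat(truth_frames, axis=1)

    annotation_default, annotation_alternative = _build_annotations(
        spec, probeset_gene, rng)

    cohort = ProbeLevelCohort(
        intensities=intensities,
        probe_info=probe_info,
        annotation_default=annotation_default,
        annotation_alternative=annotation_alternative,
        spec=spec,
        truth=truth,
    )
    return cohort, clinical


def _build_annotations(spec: CohortSpec, probeset_gene: list[tuple[str, int]],
                       rng: np.random.Generator
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Default and perturbed-alternative ProbeSet -> gene maps.

    The default map designates each gene's primary ProbeSet.  The alternative
    map designates the secondary ProbeSet where one exists, then drops a
    fraction of genes and swaps (reassigns) the ProbeSets of another fraction,
    never touching marker or housekeeping genes so both annotations keep the
    classifiers runnable.
    """
    gene_ids = spec.gene_ids
    primary = {gene_ids[gi]: psid for psid, gi in probeset_gene
               if psid.endswith("_a")}
    secondary = {gene_ids[gi]: psid for psid, gi in probeset_gene
                 if psid.endswith("_b")}

    default = pd.DataFrame({
        "probeset_id": [primary[g] for g in gene_ids],
        "gene_id": gene_ids,
    })

    alt_map = {g: secondary.get(g, primary[g]) for g in gene_ids}
    protected = set(spec.special_genes)
    eligible = np.array([g for g in gene_ids if g not in protected])

    n_drop = int(round(spec.alt_drop_fraction * spec.n_genes))
    n_drop = min(n_drop, len(eligible))
    dropped = set(rng.choice(eligible, size=n_drop, replace=False)) if n_drop else set()

    remaining = np.array([g for g in eligible if g not in dropped])
    n_re = int(round(spec.alt_reassign_fraction * spec.n_genes)) // 2 * 2
    n_re = min(n_re, len(remaining) // 2 * 2)
    if n_re:
        chosen = rng.choice(remaining, size=n_re, replace=False)
        for a, b in zip(chosen[0::2], chosen[1::2]):
            alt_map[a], alt_map[b] = alt_map[b], alt_map[a]

    kept = [g for g in gene_ids if g not in dropped]
    alternative = pd.DataFrame({
        "probeset_id": [alt_map[g] for g in kept],
        "gene_id": kept,
    })
    return default, alternative


def generate_cluster_centers(cohort: ProbeLevelCohort, clinical: pd.DataFrame,
                             marker_genes_6: tuple[str, ...] | None = None,
                             housekeeping_genes: tuple[str, ...] | None = None,
                             train_ids: list[str] | None = None,
                             train_fraction: float = 0.5,
                             seed: int | None = None):
    """Per-group mean normalized six-gene vectors from a training split.

    Emulates the published six-gene classifier's training cluster centers: the
    reference pre-processing schedule is applied to the cohort, marker values
    are normalized within the training split only (so centers depend on no
    other patients), and the per-latent-group means are returned as a
    :class:`~ensemblemark.classifiers.ClusterCenters` in log2-normalized scale.
    """
    from .classifiers import ClusterCenters, normalize_markers
    from .preprocess import apply_schedule, reference_schedule

    if marker_genes_6 is None or housekeeping_genes is None:
        if cohort.spec is None:
            raise ValueError("marker_genes_6/housekeeping_genes required when "
                             "the cohort carries no spec")
        marker_genes_6 = marker_genes_6 or cohort.spec.marker_genes_6
        housekeeping_genes = housekeeping_genes or cohort.spec.housekeeping_genes

    clin = clinical.set_index("patient_id")
    if train_ids is None:
        base_seed = cohort.spec.seed if cohort.spec is not None else 0
        rng = np.random.default_rng((seed if seed is not None else base_seed) + 1)
        train_ids = []
        for grp in (GOOD, POOR):
            ids = clin.index[clin["latent_group"] == grp].to_numpy()
            n_train = max(2, int(round(train_fraction * len(ids))))
            if len(ids) < 2:
                raise ValueError(f"latent group {grp!r} has fewer than 2 patients")
            train_ids.extend(rng.choice(ids, size=min(n_train, len(ids)),
                                        replace=False))
    train_ids = list(train_ids)
    for grp in (GOOD, POOR):
        if not any(clin.loc[pid, "latent_group"] == grp for pid in train_ids):
            raise ValueError(f"training split contains no {grp!r} patients")

    mats = apply_schedule(cohort, clinical, reference_schedule(),
                          required_genes=tuple(marker_genes_6) + tuple(housekeeping_genes))
    vectors = []
    for em in mats:
        cols = [c for c in em.values.columns if c in train_ids]
        if not cols:
            continue
        sub = replace_values(em, em.values[cols])
        vectors.append(normalize_markers(sub, marker_genes_6, housekeeping_genes).values)
    pooled = pd.concat(vectors, axis=1)

    groups = clin.loc[pooled.columns, "latent_group"]
    center_good = pooled.loc[:, (groups == GOOD).to_numpy()].mean(axis=1).to_numpy()
    center_poor = pooled.loc[:, (groups == POOR).to_numpy()].mean(axis=1).to_numpy()
    return ClusterCenters(center_good=center_good, center_poor=center_poor,
                          train_ids=tuple(train_ids))


def replace_values(em, values: pd.DataFrame):
    """Copy an ExpressionMatrix with new values but identical metadata."""
    return replace(em, values=values)
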