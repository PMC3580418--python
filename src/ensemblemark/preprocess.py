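"""Pre-processing schedules: four summarization algorithms x log x annotation x handling.

A *schedule* is a complete recipe turning probe-level intensities into a
gene x patient expression matrix: a summarization algorithm (RMA, GCRMA, MAS5
or the Li-Wong model-based expression index, MBEI), whether the output is
log2-transformed (forced for RMA/GCRMA, optional for MAS5/MBEI), which
ProbeSet -> gene annotation defines the ProbeSets, and whether the per-site
batches are pre-processed separately or merged first.  The full factorial is
6 algorithm/log variants x 2 annotations x 2 handling modes = 24 schedules.

The algorithm internals are deliberately simplified relative to the vendor
implementations (documented in docs/methods.md): RMA background subtracts the
per-array mode of the dim-probe distribution instead of fitting a
normal+exponential convolution; GCRMA estimates probe background by linear
regression of log2 intensity on GC fraction among the dimmest quartile; MAS5
is PM-only (no ideal-mismatch); MBEI omits the Li-Wong outlier rejection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

ALGORITHMS = ("GCRMA", "MAS5", "MBEI", "RMA")
ANNOTATIONS = ("alternative", "default")
HANDLINGS = ("combined", "separate")
LOG2_ONLY = ("RMA", "GCRMA")

MAS5_SCALE_TARGET = 500.0  # vendor-convention trimmed-mean target


class ScheduleError(ValueError):
    """Raised for invalid schedule specifications."""


@dataclass(frozen=True)
class ScheduleSpec:
    """One of the 24 pre-processing recipes.

    ``pseudo_count`` is added to raw intensities before MBEI fitting; the
    published re-analysis variant this emulates used MBEI with pseudo-count
    addition and combined handling.
    """

    algorithm: str
    log2_output: bool
    annotation: str = "default"
    handling: str = "separate"
    pseudo_count: float = 0.0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ScheduleError(f"unknown algorithm {self.algorithm!r}")
        if self.annotation not in ANNOTATIONS:
            raise ScheduleError(f"unknown annotation {self.annotation!r}")
        if self.handling not in HANDLINGS:
            raise ScheduleError(f"unknown handling {self.handling!r}")
        if self.algorithm in LOG2_ONLY and not self.log2_output:
            raise ScheduleError(f"{self.algorithm} output is always log2")
        if self.pseudo_count < 0:
            raise ScheduleError("pseudo_count must be >= 0")
        if self.pseudo_count and self.algorithm != "MBEI":
            raise ScheduleError("pseudo_count only applies to MBEI")

    @property
    def scale(self) -> str:
        return "log2" if self.log2_output else "natural"

    @property
    def schedule_id(self) -> str:
        sid = f"{self.algorithm}-{self.scale}-{self.annotation}-{self.handling}"
        if self.pseudo_count:
            sid += f"-pc{self.pseudo_count:g}"
        return sid

    def to_dict(self) -> dict:
        return {"algorithm": self.algorithm, "log2_output": self.log2_output,
                "annotation": self.annotation, "handling": self.handling,
                "pseudo_count": self.pseudo_count}

    @classmethod
    def from_dict(cls, d: dict) -> "ScheduleSpec":
        return cls(**d)

    @classmethod
    def from_id(cls, sid: str) -> "ScheduleSpec":
        parts = sid.split("-")
        if len(parts) not in (4, 5):
            raise ScheduleError(f"malformed schedule id {sid!r}")
        pc = float(parts[4][2:]) if len(parts) == 5 else 0.0
        return cls(algorithm=parts[0], log2_output=parts[1] == "log2",
                   annotation=parts[2], handling=parts[3], pseudo_count=pc)


def enumerate_schedules() -> list[ScheduleSpec]:
    """All 24 schedules in canonical (algorithm, scale, annotation, handling) order."""
    out = []
    for alg in ALGORITHMS:
        scales = [True] if alg in LOG2_ONLY else [True, False]
        for log2_output in scales:
            for annotation in ANNOTATIONS:
                for handling in HANDLINGS:
                    out.append(ScheduleSpec(alg, log2_output, annotation, handling))
    out.sort(key=lambda s: (s.algorithm, s.scale, s.annotation, s.handling))
    return out


def reference_schedule() -> ScheduleSpec:
    """The original study protocol: RMA, default annotation, separate handling."""
    return ScheduleSpec("RMA", True, "default", "separate")


@dataclass
class ExpressionMatrix:
    """A feature x patient expression matrix with its provenance.

    ``level`` is ``"probeset"`` straight out of a summarizer or ``"gene"``
    after annotation mapping; ``site`` tags per-site matrices produced under
    separate handling (``"combined"`` otherwise).
    """

    values: pd.DataFrame
    scale: str  # "log2" | "natural"
    schedule: ScheduleSpec | None = None
    level: str = "probeset"
    site: str | None = None

    def __post_init__(self):
        if self.scale not in ("log2", "natural"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.scale == "natural" and (self.values.to_numpy() <= 0).any():
            raise ValueError("natural-scale expression must be strictly positive")


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def quantile_normalize(values):
    """Quantile normalization across arrays (columns).

    Every column's sorted values are replaced by the across-column mean of
    order statistics; ranks are preserved within each column and tied values
    receive the mean of their candidate values.
    """
    is_df = isinstance(values, pd.DataFrame)
    X = values.to_numpy(dtype=float) if is_df else np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("quantile_normalize expects a 2-D (features x arrays) input")
    order = np.argsort(X, axis=0, kind="stable")
    sorted_x = np.take_along_axis(X, order, axis=0)
    means = sorted_x.mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = np.empty(X.shape[0])
        col[order[:, j]] = means
        _, inv, counts = np.unique(X[:, j], return_inverse=True, return_counts=True)
        sums = np.bincount(inv, weights=col)
        out[:, j] = (sums / counts)[inv]
    if is_df:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


@dataclass
class MedianPolishResult:
    overall: float
    row: np.ndarray
    col: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int

    @property
    def fitted_col(self) -> np.ndarray:
        """Per-array summarized value: overall effect + column effect."""
        return self.overall + self.col


def median_polish(X, max_iter: int = 10, tol: float = 1e-8) -> MedianPolishResult:
    """Tukey median polish of a 2-D table, row sweep first.

    Convergence when the total absolute residual changes by less than ``tol``
    (relatively) between sweeps; ties in medians use the standard midpoint
    convention of :func:`numpy.median`.
    """
    z = np.array(X, dtype=float)
    if z.ndim != 2:
        raise ValueError("median_polish expects a 2-D input")
    nr, nc = z.shape
    t = 0.0
    r = np.zeros(nr)
    c = np.zeros(nc)
    oldsum = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        r += rdelta
        delta = np.median(c)
        c -= delta
        t += delta
        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        c += cdelta
        delta = np.median(r)
        r -= delta
        t += delta
        newsum = np.abs(z).sum()
        if newsum == 0 or abs(newsum - oldsum) < tol * max(newsum, 1.0):
            converged = True
            break
        oldsum = newsum
    return MedianPolishResult(t, r, c, z, converged, it)


def tukey_biweight(values, c: float = 5.0, eps: float = 1e-4) -> float:
    """One-step Tukey biweight location about the median with MAD scaling."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("tukey_biweight requires at least one value")
    if not np.isfinite(x).all():
        raise ValueError("tukey_biweight requires finite values")
    return float(_biweight_columns(x[:, None], c=c, eps=eps)[0])


def _biweight_columns(X: np.ndarray, c: float = 5.0, eps: float = 1e-4) -> np.ndarray:
    """Column-wise one-step Tukey biweight of a (probes x arrays) block."""
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    s = c * mad + eps
    u = (X - med) / s
    w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
    return (w * X).sum(axis=0) / w.sum(axis=0)


def li_wong_fit(X, max_iter: int = 100, tol: float = 1e-6):
    """Multiplicative Li-Wong model intensity[i,j] ~ phi[i] * theta[j] by ALS.

    The identifiability constraint is sum(phi^2) = number of probes; theta is
    the per-array expression index.  Returns ``(theta, phi, objectives,
    converged)`` where ``objectives`` is the squared-error trace (one entry
    per completed iteration, non-increasing).
    """
    X = np.asarray(X, dtype=float)
    n_probes, n_arrays = X.shape
    theta = X.mean(axis=0)
    if not np.any(theta):
        theta = np.ones(n_arrays)
    objectives = []
    converged = False
    phi = np.ones(n_probes)
    for _ in range(max_iter):
        phi = X @ theta / (theta @ theta)
        denom = phi @ phi
        if denom == 0:
            break
        theta_new = X.T @ phi / denom
        s = np.sqrt((phi @ phi) / n_probes)
        phi = phi / s
        theta_scaled = theta_new * s
        objectives.append(float(((X - np.outer(phi, theta_scaled)) ** 2).sum()))
        rel = np.linalg.norm(theta_scaled - theta) / max(np.linalg.norm(theta), 1e-12)
        theta = theta_scaled
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn("Li-Wong ALS did not converge; returning last iterate",
                      RuntimeWarning, stacklevel=2)
    return theta, phi, np.asarray(objectives), converged


# ---------------------------------------------------------------------------
# background correction
# ---------------------------------------------------------------------------

def _dim_mode(col: np.ndarray) -> float:
    """Mode of the dim-probe distribution (values below the 25th percentile)."""
    q25 = np.percentile(col, 25.0)
    dim = col[col <= q25]
    if dim.size < 2 or dim.min() == dim.max():
        return float(dim.min()) if dim.size else 0.0
    counts, edges = np.histogram(dim, bins=50)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def _rma_background(V: np.ndarray) -> np.ndarray:
    out = np.empty_like(V)
    for j in range(V.shape[1]):
        col = V[:, j]
        bg = _dim_mode(col)
        floor = 0.5 * col[col > 0].min()
        out[:, j] = np.maximum(col - bg, floor)
    return out


def _gcrma_background(V: np.ndarray, gc: np.ndarray) -> np.ndarray:
    if gc is None or np.isnan(gc).any():
        raise ValueError("per-probe GC fractions are required for GCRMA; "
                         "use RMA when GC content is unavailable")
    out = np.empty_like(V)
    for j in range(V.shape[1]):
        col = V[:, j]
        q25 = np.percentile(col, 25.0)
        dim = col <= q25
        slope, intercept = np.polyfit(gc[dim], np.log2(col[dim]), 1)
        pred = np.exp2(intercept + slope * gc)
        floor = 0.5 * col[col > 0].min()
        out[:, j] = np.maximum(col - pred, floor)
    return out


# ---------------------------------------------------------------------------
# summarization
# ---------------------------------------------------------------------------

def _combined(cohort, sites):
    sites = list(cohort.intensities) if sites is None else list(sites)
    mats = [cohort.intensities[s] for s in sites]
    return pd.concat(mats, axis=1), sites


def _probeset_index_groups(cohort, annotation: str) -> dict[str, np.ndarray]:
    """Row indices of each annotated ProbeSet's probes; omits (and logs)
    ProbeSets carrying zero probes under the chosen annotation."""
    wanted = set(cohort.annotation(annotation)["probeset_id"])
    groups = {}
    codes = cohort.probe_info["probeset_id"]
    positions = pd.Series(np.arange(len(codes)), index=codes.to_numpy())
    for psid, idx in positions.groupby(level=0):
        if psid in wanted:
            groups[psid] = idx.to_numpy()
    missing = wanted - set(groups)
    if missing:
        warnings.warn(
            f"{len(missing)} ProbeSet(s) with zero probes omitted: "
            f"{sorted(missing)[:5]}...", RuntimeWarning, stacklevel=2)
    return dict(sorted(groups.items()))


def rma_summarize(cohort, annotation: str = "default", sites=None) -> ExpressionMatrix:
    """RMA: background shift, quantile normalization, log2, median polish."""
    X, _ = _combined(cohort, sites)
    groups = _probeset_index_groups(cohort, annotation)
    L = np.log2(quantile_normalize(_rma_background(X.to_numpy(dtype=float))))
    return _polish_probesets(L, groups, X.columns)


def gcrma_summarize(cohort, annotation: str = "default", sites=None) -> ExpressionMatrix:
    """As RMA but with a GC-dependent per-probe background estimate."""
    X, _ = _combined(cohort, sites)
    groups = _probeset_index_groups(cohort, annotation)
    gc = cohort.probe_info["gc_fraction"].to_numpy(dtype=float)
    L = np.log2(quantile_normalize(_gcrma_background(X.to_numpy(dtype=float), gc)))
    return _polish_probesets(L, groups, X.columns)


def _polish_probesets(L: np.ndarray, groups: dict[str, np.ndarray],
                      columns) -> ExpressionMatrix:
    rows = np.empty((len(groups), L.shape[1]))
    for i, (psid, idx) in enumerate(groups.items()):
        sub = L[idx]
        rows[i] = sub[0] if len(idx) == 1 else median_polish(sub).fitted_col
    values = pd.DataFrame(rows, index=list(groups), columns=columns)
    return ExpressionMatrix(values, scale="log2", level="probeset")


def mas5_summarize(cohort, annotation: str = "default", log2_output: bool = False,
                   sites=None, scale_target: float = MAS5_SCALE_TARGET
                   ) -> ExpressionMatrix:
    """MAS5-style signal: per-ProbeSet Tukey biweight of log2 probe intensities,
    then per-array 2%-trimmed-mean scaling to a fixed target."""
    X, _ = _combined(cohort, sites)
    groups = _probeset_index_groups(cohort, annotation)
    L = np.log2(X.to_numpy(dtype=float))
    rows = np.empty((len(groups), L.shape[1]))
    for i, (psid, idx) in enumerate(groups.items()):
        rows[i] = _biweight_columns(L[idx])
    S = np.exp2(rows)
    trimmed = stats.trim_mean(S, 0.02, axis=0)
    S = S * (scale_target / trimmed)[None, :]
    values = pd.DataFrame(np.log2(S) if log2_output else S,
                          index=list(groups), columns=X.columns)
    return ExpressionMatrix(values, scale="log2" if log2_output else "natural",
                            level="probeset")


def mbei_summarize(cohort, annotation: str = "default", log2_output: bool = False,
                   pseudo_count: float = 0.0, sites=None) -> ExpressionMatrix:
    """Li-Wong model-based expression index with optional pseudo-count addition.

    Arrays are first median-scaled to a common median, then each ProbeSet is
    fitted with the multiplicative model by alternating least squares.
    """
    X, _ = _combined(cohort, sites)
    groups = _probeset_index_groups(cohort, annotation)
    V = X.to_numpy(dtype=float) + pseudo_count
    if (V <= 0).any():
        raise ValueError("intensities must be positive after pseudo-count addition")
    med = np.median(V, axis=0)
    V = V * (np.median(med) / med)[None, :]
    rows = np.empty((len(groups), V.shape[1]))
    for i, (psid, idx) in enumerate(groups.items()):
        theta, _, _, _ = li_wong_fit(V[idx])
        rows[i] = theta
    if log2_output:
        n_clip = int((rows <= 0).sum())
        if n_clip:
            warnings.warn(f"{n_clip} non-positive MBEI index value(s) clipped "
                          "before log2", RuntimeWarning, stacklevel=2)
        rows = np.log2(np.maximum(rows, 1e-8))
    values = pd.DataFrame(rows, index=list(groups), columns=X.columns)
    return ExpressionMatrix(values, scale="log2" if log2_output else "natural",
                            level="probeset")


_SUMMARIZERS = {"RMA": rma_summarize, "GCRMA": gcrma_summarize}


def _summarize(cohort, schedule: ScheduleSpec, sites=None) -> ExpressionMatrix:
    if schedule.algorithm in _SUMMARIZERS:
        return _SUMMARIZERS[schedule.algorithm](cohort, schedule.annotation, sites)
    if schedule.algorithm == "MAS5":
        return mas5_summarize(cohort, schedule.annotation, schedule.log2_output, sites)
    return mbei_summarize(cohort, schedule.annotation, schedule.log2_output,
                          schedule.pseudo_count, sites)


# ---------------------------------------------------------------------------
# schedule application
# ---------------------------------------------------------------------------

def _designated_probesets(annotation_df: pd.DataFrame) -> pd.Series:
    """gene_id -> designated ProbeSet (lexicographically first if several)."""
    ann = annotation_df.sort_values(["gene_id", "probeset_id"], kind="stable")
    ann = ann.drop_duplicates("gene_id", keep="first")
    return ann.set_index("gene_id")["probeset_id"]


def to_gene_level(em: ExpressionMatrix, annotation_df: pd.DataFrame) -> ExpressionMatrix:
    """Map a probeset-level matrix to gene level via designated ProbeSets."""
    desig = _designated_probesets(annotation_df)
    present = desig[desig.isin(em.values.index)]
    values = em.values.loc[present.to_numpy()]
    values.index = present.index
    return replace(em, values=values, level="gene")


def apply_schedule(cohort, clinical: pd.DataFrame | None, schedule: ScheduleSpec,
                   required_genes: tuple[str, ...] | None = None
                   ) -> list[ExpressionMatrix]:
    """Run one schedule, returning gene-level matrices.

    Combined handling merges all sites before one pass of the algorithm and
    yields a single matrix; separate handling runs the algorithm per site and
    yields one matrix per site, tagged for downstream per-site classification.
    """
    ann = cohort.annotation(schedule.annotation)
    site_groups = ([[s] for s in cohort.sites] if schedule.handling == "separate"
                   else [list(cohort.sites)])
    out = []
    for sites in site_groups:
        em = _summarize(cohort, schedule, sites)
        em = to_gene_level(em, ann)
        em.schedule = schedule
        em.site = sites[0] if len(sites) == 1 else "combined"
        if required_genes:
            missing = [g for g in required_genes if g not in em.values.index]
            if missing:
                raise ScheduleError(
                    f"gene(s) {missing} absent under schedule {schedule.schedule_id}")
        if clinical is not None:
            known = set(clinical["patient_id"])
            unknown = [c for c in em.values.columns if c not in known]
            if unknown:
                raise ValueError(f"expression columns not in clinical table: "
                                 f"{unknown[:5]}")
        out.append(em)
    return out


def compute_schedule_matrices(cohort, clinical, schedules=None,
                              required_genes=None
                              ) -> dict[str, list[ExpressionMatrix]]:
    """Apply many schedules, reusing natural-scale MAS5/MBEI computations for
    their log2 variants (the log2 output is the elementwise log2)."""
    schedules = enumerate_schedules() if schedules is None else list(schedules)
    cache: dict[tuple, list[ExpressionMatrix]] = {}
    out: dict[str, list[ExpressionMatrix]] = {}
    for sched in schedules:
        key = (sched.algorithm, sched.annotation, sched.handling, sched.pseudo_count)
        if key not in cache:
            base = sched if sched.algorithm in LOG2_ONLY else replace(
                sched, log2_output=False)
            cache[key] = apply_schedule(cohort, clinical, base, required_genes)
        mats = cache[key]
        if sched.log2_output and sched.algorithm not in LOG2_ONLY:
            mats = [replace(em, values=np.log2(np.maximum(em.values, 1e-8)),
                            scale="log2", schedule=sched) for em in mats]
        else:
            mats = [replace(em, schedule=sched) for em in mats]
        out[sched.schedule_id] = mats
    return out
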