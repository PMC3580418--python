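"""Survival evaluation of prognostic calls.

Provides five-year truncation of overall survival, stage-adjusted Cox
proportional-hazards fits with Wald tests (lifelines, Efron tie handling),
Kaplan-Meier curves, the dichotomous five-year classification metrics, and a
fast Newton solver for the binary-covariate Efron partial likelihood used by
the schedule-wise univariate screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .classifiers import GOOD, POOR, UNCLASSIFIED
from .cohort import STAGES

DEFAULT_HORIZON = 60.0  # months


class NonIdentifiableError(ValueError):
    """Raised when the group effect is not identifiable (monotone likelihood)."""


@dataclass
class SurvivalFitResult:
    """A hazard ratio (poor vs good) with its Wald confidence interval."""

    hr: float
    ci_low: float
    ci_high: float
    p_wald: float
    n_patients: int
    n_events: int
    stage_adjusted: bool

    def __post_init__(self):
        if not self.ci_low <= self.hr <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")


@dataclass
class BinaryMetrics:
    """Five-year dichotomous classification counts and derived rates.

    Patients censored before the horizon are excluded (and counted); patients
    the classifier left unclassified are counted separately.  Rates with a
    zero denominator are ``None`` rather than a silent 0/0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded_censored: int
    n_unclassified: int = 0

    @property
    def sensitivity(self):
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self):
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def accuracy(self):
        d = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / d if d else None


def truncate_survival(clinical: pd.DataFrame, horizon: float = DEFAULT_HORIZON
                      ) -> pd.DataFrame:
    """Truncate overall survival at the horizon (default 5 years = 60 months).

    Events after the horizon are recoded as censored at the horizon; all times
    are capped at the horizon.
    """
    if (clinical["time_months"] < 0).any():
        raise ValueError("survival times must be >= 0")
    out = clinical.copy()
    late = out["time_months"] > horizon
    out.loc[late, "event"] = 0
    out.loc[late, "time_months"] = horizon
    return out


def _merge_calls(calls: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    merged = calls.merge(clinical, on="patient_id", how="inner", validate="1:1")
    if len(merged) != len(calls):
        missing = set(calls["patient_id"]) - set(clinical["patient_id"])
        raise ValueError(f"calls and clinical tables misaligned: {sorted(missing)[:5]}")
    return merged


def cox_fit(calls: pd.DataFrame, clinical: pd.DataFrame,
            adjust_stage: bool = True) -> SurvivalFitResult:
    """Cox proportional-hazards fit of the poor-vs-good group effect.

    Partial-likelihood maximization with Efron tie handling; unclassified
    patients are excluded.  With ``adjust_stage`` the tumor stage enters as
    indicator covariates (IA reference).  HR = exp(coef), 95% CI =
    exp(coef +- 1.96 SE), p from the Wald z statistic.
    """
    df = _merge_calls(calls, clinical)
    df = df[df["call"] != UNCLASSIFIED]
    for grp in (GOOD, POOR):
        sub = df[df["call"] == grp]
        if len(sub) == 0:
            raise NonIdentifiableError(f"no patients in group {grp!r}")
        if sub["event"].sum() == 0:
            raise NonIdentifiableError(
                f"group {grp!r} has no events: monotone likelihood, "
                "hazard ratio not identifiable")
    model = pd.DataFrame({
        "time": df["time_months"].to_numpy(dtype=float),
        "event": df["event"].to_numpy(dtype=int),
        "group": (df["call"] == POOR).to_numpy(dtype=float),
    })
    if adjust_stage and "stage" in df.columns:
        for st in STAGES[1:]:
            col = (df["stage"] == st).to_numpy(dtype=float)
            if 0 < col.sum() < len(col):
                model[f"stage_{st}"] = col
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(model, duration_col="time", event_col="event",
                    fit_options={"precision": 1e-9})
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise NonIdentifiableError(
            f"Cox partial likelihood not identifiable: {exc}") from exc
    row = cph.summary.loc["group"]
    return SurvivalFitResult(
        hr=float(np.exp(row["coef"])),
        ci_low=float(np.exp(row["coef"] - 1.959963984540054 * row["se(coef)"])),
        ci_high=float(np.exp(row["coef"] + 1.959963984540054 * row["se(coef)"])),
        p_wald=float(row["p"]),
        n_patients=len(model),
        n_events=int(model["event"].sum()),
        stage_adjusted=adjust_stage,
    )


def km_curve(calls: pd.DataFrame, clinical: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimates per call group.

    Returns, per non-empty group, a DataFrame with ``time`` and ``survival``
    columns (step function values; starts at 1, non-increasing).  Empty groups
    are omitted with a warning.
    """
    df = _merge_calls(calls, clinical)
    out = {}
    for grp in (GOOD, POOR):
        sub = df[df["call"] == grp]
        if len(sub) == 0:
            warnings.warn(f"group {grp!r} empty; curve omitted", RuntimeWarning,
                          stacklevel=2)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_months"], sub["event"])
        sf = kmf.survival_function_
        out[grp] = pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                                 "survival": sf.iloc[:, 0].to_numpy()})
    return out


def plot_km(curves: dict[str, pd.DataFrame], path: str, title: str = "") -> None:
    """Write a basic Kaplan-Meier step plot to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {GOOD: "tab:blue", POOR: "tab:red"}
    for grp, curve in curves.items():
        ax.step(curve["time"], curve["survival"], where="post", label=grp,
                color=colors.get(grp))
    ax.set_xlabel("months")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def binary_metrics(calls: pd.DataFrame, clinical: pd.DataFrame,
                   horizon: float = DEFAULT_HORIZON) -> BinaryMetrics:
    """Five-year TP/FP/TN/FN counts from *raw* (untruncated) survival.

    A poor-call patient who died within the horizon is a TP, one who survived
    beyond it an FP; a good-call patient alive at the horizon is a TN, one who
    died within it an FN.  "Alive at the horizon" requires follow-up >= the
    horizon (censoring exactly at the horizon counts as alive); patients
    censored earlier are excluded and counted.
    """
    df = _merge_calls(calls, clinical)
    tp = fp = tn = fn = excluded = unclassified = 0
    for _, row in df.iterrows():
        if row["call"] == UNCLASSIFIED:
            unclassified += 1
            continue
        died = row["event"] == 1 and row["time_months"] <= horizon
        alive = row["time_months"] >= horizon and not died
        if not died and not alive:
            excluded += 1
            continue
        if row["call"] == POOR:
            tp, fp = tp + died, fp + alive
        else:
            fn, tn = fn + died, tn + alive
    return BinaryMetrics(tp=tp, fp=fp, tn=tn, fn=fn,
                         n_excluded_censored=excluded,
                         n_unclassified=unclassified)


# ---------------------------------------------------------------------------
# fast binary-covariate Cox engine (Efron ties)
# ---------------------------------------------------------------------------

class BinaryCoxEngine:
    """Newton solver for the Efron partial likelihood with one binary covariate.

    The survival data are fixed at construction; :meth:`fit` is then cheap per
    covariate vector, which is what the 24-schedule univariate screen needs.
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        self.n = len(time)
        self.order = np.argsort(time, kind="stable")
        t_s = time[self.order]
        e_s = event[self.order]
        ev_pos = np.flatnonzero(e_s == 1)
        ev_times = t_s[ev_pos]
        uniq, first_idx = np.unique(ev_times, return_index=True)
        self.group_start = np.searchsorted(t_s, uniq, side="left")
        self.n_at_risk = self.n - self.group_start
        self.d = np.diff(np.append(first_idx, len(ev_pos)))
        self.ev_pos = ev_pos
        self.ev_group = np.repeat(np.arange(len(uniq)), self.d)
        # flattened (group, l) pairs for the Efron correction
        self.pair_group = np.repeat(np.arange(len(uniq)), self.d)
        self.pair_frac = np.concatenate(
            [np.arange(dk) / dk for dk in self.d]) if len(self.d) else np.array([])
        self.n_groups = len(uniq)

    def fit(self, x, max_iter: int = 50, tol: float = 1e-10) -> dict | None:
        """Fit exp(beta * x); returns None for degenerate inputs (constant
        covariate or a level with no events, i.e. monotone likelihood)."""
        x = np.asarray(x, dtype=float)
        xs = x[self.order]
        if xs.min() == xs.max() or self.n_groups == 0:
            return None
        suffix1 = np.cumsum(xs[::-1])[::-1]
        n1R = suffix1[self.group_start]
        n0R = self.n_at_risk - n1R
        d1 = np.bincount(self.ev_group, weights=xs[self.ev_pos],
                         minlength=self.n_groups)
        d0 = self.d - d1
        s_total = d1.sum()
        if s_total == 0 or d0.sum() == 0:
            return None
        g = self.pair_group
        frac = self.pair_frac
        beta = 0.0
        info = np.nan
        for _ in range(max_iter):
            e = np.exp(beta)
            T = n0R[g] + n1R[g] * e - frac * (d0[g] + d1[g] * e)
            A = (n1R[g] - frac * d1[g]) * e
            score = s_total - (A / T).sum()
            info = (A * (T - A) / T ** 2).sum()
            if info <= 0:
                return None
            step = np.clip(score / info, -1.0, 1.0)
            beta += step
            if abs(beta) > 15:
                return None
            if abs(step) < tol:
                break
        se = 1.0 / np.sqrt(info)
        z = beta / se
        return {"beta": beta, "se": se, "hr": float(np.exp(beta)),
                "p": float(2.0 * stats.norm.sf(abs(z)))}


def univariate_cox(time, event, x) -> dict | None:
    """One-off binary-covariate Cox fit (see :class:`BinaryCoxEngine`)."""
    return BinaryCoxEngine(time, event).fit(x)
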