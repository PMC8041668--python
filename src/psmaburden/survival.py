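"""Survival prognostication workflow for whole-body burden biomarkers.

Covariates enter regressions on the log2 scale, so every hazard ratio is
per *doubling* of the raw biomarker.  The stage covers: Spearman
correlations and Mann-Whitney U tests, univariate and multivariate Cox
proportional-hazards regression (Breslow ties by default, Efron via
``ties=``), stepwise backward elimination by likelihood-ratio test
(removal at p >= 0.10, no re-entry), Kaplan-Meier estimation with
Greenwood variance and pointwise log-log confidence intervals, the
log-rank test (2-group and k-group), quantile stratification, and the
maximally selected ("ideal") log-rank cutoff finder.

Data are exchanged as pandas DataFrames with columns ``time_months``
(positive), ``event`` (1 = death observed, 0 = censored) and one column
per covariate on the raw scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "FitError",
    "TransformError",
    "CoxFit",
    "StepwiseResult",
    "KMEstimate",
    "LogRankResult",
    "CutoffResult",
    "log2_covariates",
    "fit_cox",
    "stepwise_backward_lr",
    "km_estimate",
    "logrank_test",
    "quantile_stratify",
    "find_ideal_cutoff",
    "spearman_correlation",
    "mann_whitney_u",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class FitError(RuntimeError):
    """Cox model could not be estimated (collinearity, monotone likelihood)."""


class TransformError(ValueError):
    """Covariate transform undefined (non-positive value under log2)."""


# ---------------------------------------------------------------------------
# covariate transform
# ---------------------------------------------------------------------------

def log2_covariates(table: pd.DataFrame, names: list[str]) -> pd.DataFrame:
    """Add ``<name>_log2`` columns; raw values must be strictly positive.

    Missing values propagate (complete-case handling happens in the fit).
    """
    out = table.copy()
    for name in names:
        if name not in out.columns:
            raise KeyError(f"covariate {name!r} not in table")
        values = out[name].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isnan(values) & (values <= 0))
        if bad.size:
            i = int(bad[0])
            pid = out["patient_id"].iloc[i] if "patient_id" in out.columns else f"row {i}"
            raise TransformError(
                f"covariate {name!r} must be positive for log2; "
                f"got {values[i]} for patient {pid}"
            )
        out[f"{name}_log2"] = np.log2(values)
    return out


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxFit:
    """Cox model estimates: per-covariate coefficient, HR, 95% CI, Wald p.

    ``coefficients`` is indexed by covariate name with columns
    ``coef, se, hr, ci_low, ci_high, p``; coefficients are per log2 unit
    when the covariate is log2-transformed, so ``hr = exp(coef)`` is the
    hazard ratio per doubling.
    """

    coefficients: pd.DataFrame
    log_likelihood: float
    log_likelihood_null: float
    n: int
    n_events: int
    ties: str = "breslow"

    @property
    def covariate_names(self) -> list[str]:
        return list(self.coefficients.index)

    def hazard_ratio(self, name: str) -> float:
        return float(self.coefficients.loc[name, "hr"])


def _design(table: pd.DataFrame, covariate_names: list[str]) -> pd.DataFrame:
    missing = [c for c in list(covariate_names) + ["time_months", "event"] if c not in table.columns]
    if missing:
        raise KeyError(f"missing column(s): {missing}")
    cols = ["time_months", "event"] + list(covariate_names)
    sub = table[cols].dropna()
    return sub


def fit_cox(table: pd.DataFrame, covariate_names: list[str], ties: str = "breslow") -> CoxFit:
    """Maximum partial-likelihood Cox fit (complete-case).

    Requires at least 2 events.  Collinear covariates and monotone
    likelihoods raise :class:`FitError`.
    """
    covariate_names = list(covariate_names)
    if not covariate_names:
        raise ValueError("at least one covariate required")
    sub = _design(table, covariate_names)
    time = sub["time_months"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=float)
    n_events = int(event.sum())
    if n_events < 2:
        raise FitError(f"need >= 2 events, got {n_events}")
    X = sub[covariate_names].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < len(covariate_names):
        raise FitError(f"collinear covariates among {covariate_names}")
    model = sm.PHReg(time, X, status=event, ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=False)
        except Exception as exc:  # pragma: no cover - numerical pathologies
            raise FitError(f"Cox fit failed: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))) or np.any(np.abs(params) > 50):
        raise FitError("Cox fit did not converge (monotone likelihood?)")
    z = params / bse
    p = 2 * stats.norm.sf(np.abs(z))
    coeffs = pd.DataFrame(
        {
            "coef": params,
            "se": bse,
            "hr": np.exp(params),
            "ci_low": np.exp(params - Z_95 * bse),
            "ci_high": np.exp(params + Z_95 * bse),
            "p": p,
        },
        index=pd.Index(covariate_names, name="covariate"),
    )
    return CoxFit(
        coefficients=coeffs,
        log_likelihood=float(model.loglike(params)),
        log_likelihood_null=float(model.loglike(np.zeros_like(params))),
        n=len(sub),
        n_events=n_events,
        ties=ties,
    )


@dataclass(frozen=True)
class StepwiseResult:
    """Final model of backward elimination plus the ordered removal trace."""

    final: CoxFit
    removal_trace: tuple[tuple[str, float], ...]  # (covariate, LR removal p)


def _empty_fit(table: pd.DataFrame, all_names: list[str], ties: str) -> CoxFit:
    sub = _design(table, all_names)
    time = sub["time_months"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=float)
    X = sub[all_names].to_numpy(dtype=float)
    model = sm.PHReg(time, X, status=event, ties=ties)
    ll0 = float(model.loglike(np.zeros(len(all_names))))
    coeffs = pd.DataFrame(
        columns=["coef", "se", "hr", "ci_low", "ci_high", "p"],
        index=pd.Index([], name="covariate"), dtype=float,
    )
    return CoxFit(coefficients=coeffs, log_likelihood=ll0, log_likelihood_null=ll0,
                  n=len(sub), n_events=int(event.sum()), ties=ties)


def stepwise_backward_lr(
    table: pd.DataFrame,
    covariate_names: list[str],
    removal_alpha: float = 0.10,
    ties: str = "breslow",
) -> StepwiseResult:
    """Backward elimination by likelihood-ratio test, no re-entry.

    Starting from the full model, the covariate whose single-term removal
    has the largest LR p-value is dropped while that p >= ``removal_alpha``;
    elimination may empty the model.  Rows are restricted to complete cases
    of the *initial* covariate set so nested likelihoods are comparable.
    """
    current = list(covariate_names)
    complete = _design(table, current)  # freeze complete cases of full set
    trace: list[tuple[str, float]] = []
    while current:
        fit = fit_cox(complete, current, ties=ties)
        removal_p: dict[str, float] = {}
        for name in current:
            rest = [c for c in current if c != name]
            if rest:
                ll_reduced = fit_cox(complete, rest, ties=ties).log_likelihood
            else:
                ll_reduced = fit.log_likelihood_null
            lr = 2.0 * (fit.log_likelihood - ll_reduced)
            removal_p[name] = float(stats.chi2.sf(max(lr, 0.0), df=1))
        worst = max(removal_p, key=removal_p.get)
        if removal_p[worst] >= removal_alpha:
            trace.append((worst, removal_p[worst]))
            current.remove(worst)
        else:
            return StepwiseResult(final=fit, removal_trace=tuple(trace))
    return StepwiseResult(final=_empty_fit(table, list(covariate_names), ties), removal_trace=tuple(trace))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate with Greenwood log-log confidence intervals.

    ``median`` and its CI bounds are ``inf`` when the corresponding curve
    never reaches 0.5 ("NR", not reached).
    """

    times: np.ndarray          # distinct event times
    survival: np.ndarray       # S(t) just after each event time
    ci_low: np.ndarray
    ci_high: np.ndarray
    at_risk: np.ndarray
    n_deaths: np.ndarray
    n: int
    median: float
    median_ci: tuple[float, float]

    @property
    def median_is_reached(self) -> bool:
        return np.isfinite(self.median)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_at_risk": self.at_risk,
                "n_deaths": self.n_deaths,
            }
        )


def _extract(table_or_time, event=None) -> tuple[np.ndarray, np.ndarray]:
    if event is None:
        time = np.asarray(table_or_time["time_months"], dtype=float)
        event = np.asarray(table_or_time["event"], dtype=float)
    else:
        time = np.asarray(table_or_time, dtype=float)
        event = np.asarray(event, dtype=float)
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    return time, event


def km_estimate(table_or_time, event=None) -> KMEstimate:
    """Kaplan-Meier product-limit estimator.

    Pointwise 95% CIs are computed on the log(-log S) scale
    (``S ** exp(±z·se)`` with the Greenwood standard error), the
    convention behind the "log-log option" of standard survival software.
    Median CI bounds come from the crossings of the CI curves with 0.5.
    """
    time, event = _extract(table_or_time, event)
    n = len(time)
    if n == 0:
        raise ValueError("need at least one record")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]

    event_times = np.unique(time[event == 1])
    at_risk = np.empty(len(event_times), dtype=int)
    deaths = np.empty(len(event_times), dtype=int)
    for j, t in enumerate(event_times):
        at_risk[j] = int(np.sum(time >= t))
        deaths[j] = int(np.sum((time == t) & (event == 1)))

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - deaths / at_risk
        surv = np.cumprod(frac)
        # Greenwood cumulative sum for the log-log variance
        gw = np.cumsum(np.where(at_risk > deaths, deaths / (at_risk * (at_risk - deaths)), np.inf))
        log_s = np.log(surv, out=np.full_like(surv, -np.inf), where=surv > 0)
        se_loglog = np.sqrt(gw) / np.abs(log_s)
        lo = surv ** np.exp(Z_95 * se_loglog)
        hi = surv ** np.exp(-Z_95 * se_loglog)
    # degenerate points: S == 1 (no variance info) or S == 0
    lo = np.where(surv >= 1.0, 1.0, np.where(surv <= 0.0, 0.0, lo))
    hi = np.where(surv >= 1.0, 1.0, np.where(surv <= 0.0, 0.0, hi))

    def _crossing(curve: np.ndarray) -> float:
        below = np.flatnonzero(curve <= 0.5)
        return float(event_times[below[0]]) if below.size else float("inf")

    return KMEstimate(
        times=event_times,
        survival=surv,
        ci_low=lo,
        ci_high=hi,
        at_risk=at_risk,
        n_deaths=deaths,
        n=n,
        median=_crossing(surv),
        median_ci=(_crossing(lo), _crossing(hi)),
    )


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


def logrank_test(*groups) -> LogRankResult:
    """Log-rank comparison of k >= 2 survival curves.

    Each group is a DataFrame with ``time_months``/``event`` columns or a
    ``(time, event)`` pair of arrays.  Uses the standard
    observed-vs-expected statistic with the hypergeometric covariance;
    supports the 2-group and global k-group forms.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not (
        len(groups[0]) == 2 and np.ndim(groups[0][0]) == 1 and np.isscalar(np.asarray(groups[0][0]).flat[0])
    ):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    parsed = []
    for g in groups:
        if isinstance(g, tuple) and len(g) == 2:
            parsed.append(_extract(g[0], g[1]))
        else:
            parsed.append(_extract(g))
    k = len(parsed)
    all_time = np.concatenate([t for t, _ in parsed])
    all_event = np.concatenate([e for _, e in parsed])
    if all_event.sum() < 1:
        raise ValueError("no events in any group")
    group_idx = np.concatenate([np.full(len(t), i) for i, (t, _) in enumerate(parsed)])

    event_times = np.unique(all_time[all_event == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = all_time >= t
        n_j = at_risk.sum()
        d_j = int(np.sum((all_time == t) & (all_event == 1)))
        n_ij = np.array([(at_risk & (group_idx == i)).sum() for i in range(k)], dtype=float)
        d_ij = np.array(
            [np.sum((all_time == t) & (all_event == 1) & (group_idx == i)) for i in range(k)],
            dtype=float,
        )
        observed += d_ij
        expected += d_j * n_ij / n_j
        if n_j > 1:
            c = d_j * (n_j - d_j) / (n_j - 1.0)
            p_i = n_ij / n_j
            V += c * (np.diag(p_i) - np.outer(p_i, p_i))

    diff = (observed - expected)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        chi2 = float(diff @ np.linalg.solve(Vsub, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(Vsub) @ diff)
    chi2 = max(chi2, 0.0)
    df = k - 1
    return LogRankResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


# ---------------------------------------------------------------------------
# stratification and cutoff finding
# ---------------------------------------------------------------------------

_SCHEMES = {
    "quartiles": ([0.25, 0.5, 0.75], ["Q1", "Q2", "Q3", "Q4"]),
    "quintiles": ([0.2, 0.4, 0.6, 0.8], ["Q1", "Q2", "Q3", "Q4", "Q5"]),
    "quintile_1_24_5": ([0.2, 0.4, 0.6, 0.8], ["Q1", "Q2-4", "Q2-4", "Q2-4", "Q5"]),
}


def quantile_stratify(values, scheme: str = "quartiles") -> np.ndarray:
    """Group labels by empirical quantile cut points.

    A value equal to a cut point goes to the lower stratum (inclusive-left),
    so boundary ties always stay together.  The ``quintile_1_24_5`` scheme
    pools quintiles 2-4 into one stratum.  Degenerate inputs (all values
    identical) yield a single group with a warning, never an error.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(_SCHEMES)}")
    probs, labels = _SCHEMES[scheme]
    values = np.asarray(values, dtype=float)
    if len(values) < len(probs) + 1:
        raise ValueError(f"need >= {len(probs) + 1} values for scheme {scheme!r}")
    cuts = np.quantile(values, probs)
    idx = np.searchsorted(cuts, values, side="left")  # count of cut points < value
    out = np.asarray(labels, dtype=object)[idx]
    if len(np.unique(out)) == 1:
        warnings.warn("degenerate stratification: all values in a single stratum", stacklevel=2)
    return out


@dataclass(frozen=True)
class CutoffResult:
    """Maximally selected log-rank cutoff for one covariate.

    The reported p-value is the *unadjusted* minimum over all admissible
    cutoffs and is therefore anti-conservative (maximally selected);
    ``p_bonferroni`` applies a Bonferroni factor over the number of
    candidates evaluated.
    """

    covariate: str
    cutoff: float
    n_above: int
    n_below: int
    chi2: float
    p: float
    n_candidates: int
    p_bonferroni: float
    median_above: float
    median_above_ci: tuple[float, float]
    median_below: float
    median_below_ci: tuple[float, float]
    maximally_selected: bool = True


def find_ideal_cutoff(
    table: pd.DataFrame,
    covariate: str,
    min_group_fraction: float = 0.10,
) -> CutoffResult:
    """Exhaustive maximally selected log-rank cutoff.

    Candidate cutoffs are the midpoints between consecutive distinct sorted
    covariate values; a candidate is admissible when both resulting groups
    (above: value > cutoff, below: value <= cutoff) hold at least
    ``min_group_fraction`` of the patients.  The admissible cutoff with the
    smallest two-group log-rank p is returned.
    """
    sub = table[["time_months", "event", covariate]].dropna()
    values = sub[covariate].to_numpy(dtype=float)
    time = sub["time_months"].to_numpy(dtype=float)
    event = sub["event"].to_numpy(dtype=float)
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError(f"covariate {covariate!r} needs >= 2 distinct values")
    n = len(values)
    min_size = min_group_fraction * n
    candidates = (distinct[:-1] + distinct[1:]) / 2.0

    best: tuple[float, float, float] | None = None  # (p, chi2, cutoff)
    n_admissible = 0
    for cut in candidates:
        above = values > cut
        n_above = int(above.sum())
        if n_above < min_size or (n - n_above) < min_size:
            continue
        n_admissible += 1
        res = logrank_test((time[above], event[above]), (time[~above], event[~above]))
        if best is None or res.p < best[0]:
            best = (res.p, res.chi2, float(cut))
    if best is None:
        raise ValueError(
            f"no admissible cutoff for {covariate!r} at min_group_fraction={min_group_fraction}"
        )
    p, chi2, cutoff = best
    above = values > cutoff
    km_above = km_estimate(time[above], event[above])
    km_below = km_estimate(time[~above], event[~above])
    return CutoffResult(
        covariate=covariate,
        cutoff=cutoff,
        n_above=int(above.sum()),
        n_below=int((~above).sum()),
        chi2=chi2,
        p=p,
        n_candidates=n_admissible,
        p_bonferroni=min(1.0, p * n_admissible),
        median_above=km_above.median,
        median_above_ci=km_above.median_ci,
        median_below=km_below.median,
        median_below_ci=km_below.median_ci,
    )


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties; t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (exact for small tie-free samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
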