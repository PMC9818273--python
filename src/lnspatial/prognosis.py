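"""Survival screening, the combined prognostic index, and risk groups.

The screening cascade mirrors common prognostic-factor discovery practice:

1. each spatial factor is screened by univariate Cox regression on
   disease-free survival (Wald p < alpha retains the factor);
2. each retained factor is tested for independence from N stage in a
   bivariate Cox model (factor + ordinal N stage); the factor is kept only
   when its adjusted p stays below alpha;
3. the independent factors and ordinal N stage enter one joint Cox model
   whose linear predictor is the per-patient prognostic index;
4. the discovery cohort's index tertiles define thresholds splitting
   patients into low (G1), intermediate (G2) and high (G3) risk groups;
   the same thresholds are applied unchanged to any validation cohort.

Cox models use the Efron tie correction (lifelines); the concordance index
is Harrell's C with 0.5 credit for tied predictions, oriented so that a
higher index predicting earlier failure counts as concordant.  Confidence
intervals for C come from percentile bootstrap over patients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index

logger = logging.getLogger("lnspatial")

__all__ = [
    "CoxFit",
    "RiskStratification",
    "fit_cox",
    "screen_univariate",
    "test_independence",
    "build_index",
    "concordance",
    "bootstrap_compare",
    "tertile_thresholds",
    "assign_groups",
    "stratify",
    "km_analysis",
    "GROUP_LABELS",
]

GROUP_LABELS = ("G1", "G2", "G3")  # G1 = lowest index = low risk


@dataclass(frozen=True)
class CoxFit:
    """Multivariate proportional-hazards fit summary."""

    covariates: list[str]
    beta: np.ndarray
    hr: np.ndarray
    ci95: np.ndarray  # (n, 2) on the HR scale
    p: np.ndarray
    loglik: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "HR": self.hr,
                "HR_ci_low": self.ci95[:, 0],
                "HR_ci_high": self.ci95[:, 1],
                "p": self.p,
            },
            index=pd.Index(self.covariates, name="covariate"),
        )

    def linear_predictor(self, covariates: pd.DataFrame) -> pd.Series:
        """Prognostic index: beta . x per row (uncentred)."""
        X = covariates[self.covariates].to_numpy(dtype=float)
        return pd.Series(X @ self.beta, index=covariates.index, name="index")


@dataclass(frozen=True)
class RiskStratification:
    """Discovery tertile thresholds and per-patient group labels."""

    thresholds: tuple[float, float]
    labels: pd.Series  # values in GROUP_LABELS

    def group_sizes(self) -> dict[str, int]:
        counts = self.labels.value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUP_LABELS}


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------


def _prepare(df: pd.DataFrame, covariates: list[str], duration_col: str, event_col: str) -> pd.DataFrame:
    data = df[covariates + [duration_col, event_col]].astype(float)
    if not np.all(np.isfinite(data.to_numpy())):
        raise ValueError("non-finite values in the survival table")
    if data[event_col].sum() < 1:
        raise ValueError("no observed events: cannot fit a Cox model")
    for c in covariates:
        if data[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    return data


def fit_cox(
    df: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time",
    event_col: str = "event",
) -> CoxFit:
    """Efron-tie-corrected Cox proportional-hazards fit.

    ``df`` holds one row per patient with the covariate columns plus
    duration (months) and event indicator.  Raises on zero events,
    constant covariates, or non-convergence.
    """
    data = _prepare(df, list(covariates), duration_col, event_col)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as err:
        raise ConvergenceError(
            f"Cox fit on {covariates} failed to converge: {err}"
        ) from err
    s = cph.summary.loc[list(covariates)]
    return CoxFit(
        covariates=list(covariates),
        beta=s["coef"].to_numpy(),
        hr=s["exp(coef)"].to_numpy(),
        ci95=s[["exp(coef) lower 95%", "exp(coef) upper 95%"]].to_numpy(),
        p=s["p"].to_numpy(),
        loglik=float(cph.log_likelihood_),
    )


# ---------------------------------------------------------------------------
# screening cascade
# ---------------------------------------------------------------------------


def screen_univariate(
    factors: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    duration_col: str = "time",
    event_col: str = "event",
) -> list[str]:
    """Factors whose univariate Cox Wald p-value is below ``alpha``.

    ``factors`` is patient x factor; ``clinical`` supplies duration and
    event on the same patients (aligned on index).
    """
    if factors.shape[1] == 0:
        raise ValueError("empty factor table")
    merged = factors.join(clinical[[duration_col, event_col]], how="inner")
    retained = []
    for col in factors.columns:
        try:
            fit = fit_cox(merged, [col], duration_col, event_col)
        except (ValueError, ConvergenceError) as err:
            logger.warning("univariate screen: skipping %s (%s)", col, err)
            continue
        if fit.p[0] < alpha:
            retained.append(col)
    return retained


def test_independence(
    factor: str,
    factors: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    n_stage_col: str = "n_stage",
    duration_col: str = "time",
    event_col: str = "event",
) -> bool:
    """Keep the factor only if it stays significant after adjusting for
    ordinal N stage in a bivariate Cox model.

    A factor collinear with N stage (or a non-converging fit) is dropped:
    it carries no independent prognostic information.
    """
    merged = factors[[factor]].join(
        clinical[[n_stage_col, duration_col, event_col]], how="inner"
    )
    x = merged[factor].to_numpy(dtype=float)
    n = merged[n_stage_col].to_numpy(dtype=float)
    # exact linear dependence on N stage -> no independent contribution
    if np.ptp(n) > 0:
        resid = x - np.polyval(np.polyfit(n, x, 1), n)
        if np.allclose(resid, 0, atol=1e-10 * max(1.0, float(np.abs(x).max()))):
            logger.info("independence test: %s is collinear with N stage; dropped", factor)
            return False
    try:
        fit = fit_cox(merged, [factor, n_stage_col], duration_col, event_col)
    except (ValueError, ConvergenceError) as err:
        logger.warning("independence test: dropping %s (%s)", factor, err)
        return False
    return bool(fit.p[0] < alpha)


def build_index(
    factors: pd.DataFrame,
    clinical: pd.DataFrame,
    retained: list[str],
    n_stage_col: str = "n_stage",
    duration_col: str = "time",
    event_col: str = "event",
) -> tuple[CoxFit, pd.Series]:
    """Joint Cox fit on the retained factors plus ordinal N stage; the
    prognostic index is the fitted linear predictor per patient."""
    if len(retained) == 0:
        raise ValueError("no retained factors: cannot build a combined index")
    merged = factors[retained].join(
        clinical[[n_stage_col, duration_col, event_col]], how="inner"
    )
    fit = fit_cox(merged, retained + [n_stage_col], duration_col, event_col)
    index = fit.linear_predictor(merged)
    return fit, index


# ---------------------------------------------------------------------------
# concordance and bootstrap
# ---------------------------------------------------------------------------


def concordance(index: pd.Series | np.ndarray, time, event) -> float:
    """Harrell's C oriented so a higher index predicting earlier failure is
    concordant; tied indices earn 0.5 credit."""
    idx = np.asarray(index, dtype=float)
    return float(concordance_index(np.asarray(time, float), -idx, np.asarray(event, int)))


def bootstrap_compare(
    index_a: pd.Series | np.ndarray,
    index_b: pd.Series | np.ndarray,
    time,
    event,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Percentile-bootstrap comparison of two risk indices on one cohort.

    Draws ``n_boot`` patient-level resamples with replacement, recomputes
    both C-indices on each, and returns percentile 95% CIs plus a
    two-sided p-value for the difference ``C_A - C_B``:
    ``p = 2 * min(frac(delta <= 0), frac(delta >= 0))`` clipped to
    ``[2/n_boot, 1]``.  Resamples without any event are redrawn (counted in
    ``n_degenerate``).
    """
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; confidence intervals will be coarse")
    a = np.asarray(index_a, float)
    b = np.asarray(index_b, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    if a.shape != b.shape:
        raise ValueError("the two indices must cover the same patients")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = a.size
    ca = np.empty(n_boot)
    cb = np.empty(n_boot)
    n_degenerate = 0
    for i in range(n_boot):
        while True:
            sel = rng.integers(0, n, size=n)
            if e[sel].sum() > 0:
                break
            n_degenerate += 1
        ca[i] = concordance(a[sel], t[sel], e[sel])
        cb[i] = concordance(b[sel], t[sel], e[sel])
    if n_degenerate:
        logger.info("bootstrap_compare: %d degenerate resamples redrawn", n_degenerate)
    delta = ca - cb
    p = 2.0 * min(float(np.mean(delta <= 0)), float(np.mean(delta >= 0)))
    p = float(np.clip(p, 2.0 / n_boot, 1.0))
    return {
        "c_a": concordance(a, t, e),
        "c_b": concordance(b, t, e),
        "ci_a": tuple(np.percentile(ca, [2.5, 97.5])),
        "ci_b": tuple(np.percentile(cb, [2.5, 97.5])),
        "p": p,
        "n_boot": n_boot,
        "n_degenerate": n_degenerate,
    }


# ---------------------------------------------------------------------------
# stratification and Kaplan-Meier analysis
# ---------------------------------------------------------------------------


def tertile_thresholds(discovery_index: pd.Series | np.ndarray) -> tuple[float, float]:
    """33 1/3 and 66 2/3 percentiles (linear interpolation) of the
    discovery-cohort index."""
    idx = np.asarray(discovery_index, float)
    if idx.size < 3:
        raise ValueError("need at least 3 discovery patients for tertiles")
    t_low, t_high = np.percentile(idx, [100.0 / 3.0, 200.0 / 3.0])
    return float(t_low), float(t_high)


def assign_groups(index: pd.Series, thresholds: tuple[float, float]) -> pd.Series:
    """G1 where index <= t_low, G2 where <= t_high, else G3 (ties toward the
    lower-risk group)."""
    t_low, t_high = thresholds
    idx = index.to_numpy(dtype=float)
    labels = np.where(idx <= t_low, "G1", np.where(idx <= t_high, "G2", "G3"))
    out = pd.Series(labels, index=index.index, name="risk_group")
    if len(set(out)) == 1:
        warnings.warn("degenerate stratification: every patient in one group")
    return out


def stratify(
    index: pd.Series,
    thresholds: tuple[float, float] | None = None,
    discovery_index: pd.Series | None = None,
) -> RiskStratification:
    """Three-tier risk stratification.

    Thresholds come either from ``thresholds`` (reusing discovery values on
    a validation cohort) or are computed as tertiles of
    ``discovery_index`` (defaulting to ``index`` itself).
    """
    if thresholds is None:
        src = index if discovery_index is None else discovery_index
        thresholds = tertile_thresholds(src)
    return RiskStratification(thresholds=thresholds, labels=assign_groups(index, thresholds))


def km_analysis(
    groups: pd.Series,
    clinical: pd.DataFrame,
    horizon: float = 36.0,
    duration_col: str = "time",
    event_col: str = "event",
) -> dict:
    """Kaplan-Meier estimate, survival rate at a horizon, and pairwise
    hazard ratios for labeled patient groups.

    Returns a dict with ``curves`` (per-group KM step functions),
    ``survival_at_horizon`` (KM value at ``horizon`` months, e.g. a 3-year
    rate at 36), and ``pairwise`` — a DataFrame of univariate-Cox hazard
    ratios with 95% CI and log-rank p for every ordered group pair, the
    earlier (lower-risk) group as reference.
    """
    df = clinical.loc[groups.index, [duration_col, event_col]].copy()
    df["group"] = groups
    present = [g for g in sorted(df["group"].unique())]
    sizes = df["group"].value_counts()
    nonempty = [g for g in present if sizes.get(g, 0) > 0]
    if len(nonempty) < 2:
        raise ValueError("need at least two non-empty groups")

    curves: dict[str, pd.DataFrame] = {}
    survival: dict[str, float] = {}
    for g in nonempty:
        sub = df[df["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col], label=g)
        curves[g] = kmf.survival_function_.reset_index().rename(
            columns={"timeline": "time", g: "survival"}
        )
        survival[g] = float(kmf.survival_function_at_times(horizon).iloc[0])

    rows = []
    for i, ref in enumerate(nonempty):
        for other in nonempty[i + 1 :]:
            sub = df[df["group"].isin([ref, other])].copy()
            sub["indicator"] = (sub["group"] == other).astype(float)
            lr = logrank_test(
                sub.loc[sub["indicator"] == 0, duration_col],
                sub.loc[sub["indicator"] == 1, duration_col],
                event_observed_A=sub.loc[sub["indicator"] == 0, event_col],
                event_observed_B=sub.loc[sub["indicator"] == 1, event_col],
            )
            try:
                fit = fit_cox(sub, ["indicator"], duration_col, event_col)
                hr, (lo, hi), p_wald = fit.hr[0], fit.ci95[0], fit.p[0]
            except (ValueError, ConvergenceError) as err:
                logger.warning("pairwise HR %s vs %s unavailable (%s)", other, ref, err)
                hr = lo = hi = p_wald = np.nan
            rows.append(
                {
                    "reference": ref,
                    "group": other,
                    "HR": hr,
                    "HR_ci_low": lo,
                    "HR_ci_high": hi,
                    "p_wald": p_wald,
                    "p_logrank": lr.p_value,
                    "n_reference": int(sizes[ref]),
                    "n_group": int(sizes[other]),
                }
            )
    return {
        "curves": curves,
        "survival_at_horizon": survival,
        "horizon": horizon,
        "pairwise": pd.DataFrame(rows),
    }
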