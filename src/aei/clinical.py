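"""Association of allelic-imbalance ratios with clinical covariates and
survival.

Tumors are grouped by their cis-regulatory (gamma) imbalance call —
mutant-preferring (gamma_mut), wild-type-preferring (gamma_wt), or
balanced (gamma_balanced) — and the groups are compared on
clinicopathological markers (rank tests, BH-adjusted per study) and on
survival (Kaplan–Meier + log-rank; multivariate Cox with the balanced
group as reference).  Overall survival uses death from any cause as the
endpoint; disease-specific survival uses its own event flag; subjects
alive at last contact are censored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from lifelines import KaplanMeierFitter, CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.exceptions import ConvergenceError, ConvergenceWarning

from aei.inference import SampleProfile

logger = logging.getLogger(__name__)

GAMMA_MUT = "gamma_mut"
GAMMA_WT = "gamma_wt"
GAMMA_BALANCED = "gamma_balanced"

_CALL_TO_CATEGORY = {"mutant": GAMMA_MUT, "wildtype": GAMMA_WT, "balanced": GAMMA_BALANCED}


class ClinicalError(ValueError):
    pass


@dataclass(frozen=True)
class GammaCategory:
    sample_id: str
    category: str


def categorize_gamma(profiles: list[SampleProfile]) -> list[GammaCategory]:
    """Map each profile's gamma call to its survival-analysis category.

    Pure function of the gamma call; profiles without a gamma estimate are
    dropped (logged).
    """
    out = []
    for p in profiles:
        if p.gamma is None:
            logger.info("dropping %s: no gamma estimate", p.sample_id)
            continue
        out.append(GammaCategory(p.sample_id, _CALL_TO_CATEGORY[p.gamma.call]))
    return out


def group_comparison(ratio_maps, covariate) -> dict:
    """Rank test of a ratio's MAP values across covariate levels.

    Two levels: Wilcoxon rank-sum with continuity correction.  More than
    two: Kruskal–Wallis.  Missing covariate values are dropped first.
    Returns {'test', 'statistic', 'p_value', 'levels'}.
    """
    values = np.asarray(ratio_maps, dtype=float)
    cov = pd.Series(list(covariate))
    keep = np.isfinite(values) & cov.notna().to_numpy() & (cov != "missing").to_numpy()
    values, cov = values[keep], cov[keep]
    levels = sorted(pd.unique(cov))
    groups = [values[(cov == lv).to_numpy()] for lv in levels]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ClinicalError("need >= 2 covariate levels with >= 2 samples each")
    if len(groups) == 2:
        stat, p = stats.mannwhitneyu(
            groups[0], groups[1], alternative="two-sided",
            method="asymptotic", use_continuity=True,
        )
        test = "wilcoxon_rank_sum"
    else:
        stat, p = stats.kruskal(*groups)
        test = "kruskal_wallis"
    return {"test": test, "statistic": float(stat), "p_value": float(p), "levels": levels}


def adjust_per_study(results: list[dict], study_labels: list[str], alpha: float = 0.05) -> list[dict]:
    """BH-adjust a batch of group-comparison P values within each study."""
    if len(results) != len(study_labels):
        raise ClinicalError("one study label per result required")
    out = [dict(r) for r in results]
    for study in set(study_labels):
        idx = [i for i, s in enumerate(study_labels) if s == study]
        _, q, _, _ = multipletests([out[i]["p_value"] for i in idx], method="fdr_bh")
        for i, qi in zip(idx, q):
            out[i]["q_value"] = float(qi)
            out[i]["significant"] = bool(qi <= alpha)
            out[i]["study"] = study
    return out


@dataclass
class SurvivalResult:
    """Kaplan–Meier curves per category plus the log-rank comparison."""

    logrank_p: float
    logrank_stat: float
    medians: dict[str, float]            # NaN when the curve never crosses 0.5
    curves: dict[str, pd.DataFrame]      # columns: time, survival
    at_risk: pd.DataFrame                # groups × time grid
    n_per_group: dict[str, int] = field(default_factory=dict)


def km_logrank(times, events, categories) -> SurvivalResult:
    """Product-limit survival per category with a log-rank comparison.

    ``times`` are follow-up times (years), ``events`` 1 for death and 0
    for censoring, ``categories`` group labels per subject.  Medians are
    NaN where the curve never reaches 0.5 (e.g. all censored).
    """
    df = pd.DataFrame({
        "time": np.asarray(times, dtype=float),
        "event": np.asarray(events, dtype=int),
        "group": list(categories),
    }).dropna()
    if (df["time"] < 0).any():
        raise ClinicalError("negative survival time")
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ClinicalError("need >= 2 categories for a log-rank comparison")

    lr = multivariate_logrank_test(df["time"], df["group"], df["event"])

    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float] = {}
    n_per_group: dict[str, int] = {}
    time_grid = np.unique(df["time"].to_numpy())
    at_risk = pd.DataFrame(index=groups, columns=time_grid, dtype=float)
    for g in groups:
        sub = df[df["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        curves[g] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_[str(g)].to_numpy(),
        })
        medians[g] = float(kmf.median_survival_time_)  # inf -> never crosses 0.5
        if np.isinf(medians[g]):
            medians[g] = float("nan")
        n_per_group[g] = int(len(sub))
        for t in time_grid:
            at_risk.loc[g, t] = int((sub["time"].to_numpy() >= t).sum())
    return SurvivalResult(
        logrank_p=float(lr.p_value),
        logrank_stat=float(lr.test_statistic),
        medians=medians,
        curves=curves,
        at_risk=at_risk,
        n_per_group=n_per_group,
    )


def cox_multivariate(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
    category_col: str | None = "gamma_category",
) -> pd.DataFrame:
    """Cox proportional-hazards fit with Wald 95% CIs per covariate.

    Categorical covariates (and the gamma category, reference level
    gamma_balanced) are dummy-coded; numeric covariates enter as-is.
    Returns a DataFrame with columns ``hr``, ``ci_low``, ``ci_high``,
    ``p``.  Separation or non-convergence raises ClinicalError rather
    than returning a silently degenerate fit.
    """
    cols = [duration_col, event_col] + list(covariates)
    if category_col is not None:
        cols.append(category_col)
    data = df[cols].dropna().copy()
    if int(data[event_col].sum()) < 10:
        raise ClinicalError("fewer than 10 events: Cox fit unreliable")

    design = data[[duration_col, event_col]].copy()
    for cov in covariates:
        col = data[cov]
        if col.nunique() <= 1:
            raise ClinicalError(f"constant covariate {cov!r}")
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            design = pd.concat([design, dummies], axis=1)
        else:
            design[cov] = col.astype(float)
    if category_col is not None:
        cat = pd.Categorical(
            data[category_col],
            categories=[GAMMA_BALANCED, GAMMA_MUT, GAMMA_WT],
        )
        dummies = pd.get_dummies(
            pd.Series(cat, index=data.index), prefix="gamma", drop_first=True, dtype=float
        )
        dummies = dummies.loc[:, dummies.sum(axis=0) > 0]
        design = pd.concat([design, dummies], axis=1)

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=ConvergenceWarning)
            cph.fit(design, duration_col=duration_col, event_col=event_col)
    except (ConvergenceError, ConvergenceWarning) as exc:
        raise ClinicalError(f"Cox model did not converge cleanly: {exc}") from exc

    summary = cph.summary
    return pd.DataFrame({
        "hr": summary["exp(coef)"],
        "ci_low": summary["exp(coef) lower 95%"],
        "ci_high": summary["exp(coef) upper 95%"],
        "p": summary["p"],
    })
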