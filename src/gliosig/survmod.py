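"""Risk-score survival stratification and prognostic model battery.

Patients are dichotomised at training-derived risk-score percentiles and
compared by Kaplan-Meier / log-rank; Cox proportional-hazards models (Breslow
ties; fitting delegated to lifelines) quantify the adjusted prognostic value
of the continuous risk score, with nested likelihood-ratio tests between
progressively richer predictor sets and Harrell bootstrap optimism correction
of the concordance index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger("gliosig")

__all__ = [
    "CoxResult",
    "OptimismResult",
    "dichotomise",
    "km_logrank",
    "cox_fit",
    "nested_lrt",
    "harrell_optimism",
    "predictor_set_comparison",
]


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    if (table["time_days"] <= 0).any():
        raise ValueError("survival times must be positive")
    if table["event"].isna().any():
        raise ValueError("missing event flags")
    return table


def dichotomise(scores, training_score_distribution, percentile: int = 50) -> np.ndarray:
    """High-risk mask: score strictly above the stated percentile of the
    training score distribution."""
    train = np.asarray(training_score_distribution, dtype=float)
    if train.size == 0:
        raise ValueError("empty training score distribution")
    threshold = float(np.percentile(train, percentile))
    high = np.asarray(scores, dtype=float) > threshold
    if high.all() or not high.any():
        logger.warning("dichotomise: single risk group at percentile %s", percentile)
    return high


def km_logrank(table: pd.DataFrame, groups) -> dict:
    """Kaplan-Meier curves (Greenwood 95% bands) per group plus the log-rank test."""
    table = _check_table(table)
    groups = pd.Series(np.asarray(groups), index=table.index)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("km_logrank requires >= 2 non-empty groups")
    curves = {}
    for g in uniq:
        sub = table.loc[groups == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_days"], sub["event"], label=str(g))
        ci = kmf.confidence_interval_survival_function_
        curves[g] = pd.DataFrame({
            "time": kmf.survival_function_.index,
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "lower95": ci.iloc[:, 0].to_numpy(),
            "upper95": ci.iloc[:, 1].to_numpy(),
        })
    res = multivariate_logrank_test(table["time_days"], groups, table["event"])
    return {"curves": curves, "chi2": float(res.test_statistic), "p": float(res.p_value)}


@dataclass
class CoxResult:
    summary: pd.DataFrame          # coef, hazard_ratio, ci_lower, ci_upper, p per covariate
    concordance: float
    log_likelihood: float
    aic: float
    covariates: tuple
    n: int
    n_events: int
    ties: str = "breslow"


def cox_fit(table: pd.DataFrame, covariates: Sequence[str], ties: str = "breslow") -> CoxResult:
    """Cox proportional-hazards fit (partial likelihood, Breslow ties) via lifelines."""
    table = _check_table(table)
    if int(table["event"].sum()) < 1:
        raise ValueError("cox_fit requires at least one event")
    covariates = list(covariates)
    for c in covariates:
        if table[c].nunique() < 2:
            raise ValueError(f"degenerate covariate {c!r}")
    df = table[["time_days", "event", *covariates]].astype(float)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time_days", event_col="event")
    except Exception as exc:                      # convergence / separation
        raise RuntimeError(f"Cox fit failed: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "hazard_ratio": s["exp(coef)"],
        "ci_lower": np.exp(s["coef lower 95%"]),
        "ci_upper": np.exp(s["coef upper 95%"]),
        "p": s["p"],
    })
    return CoxResult(
        summary=summary,
        concordance=float(cph.concordance_index_),
        log_likelihood=float(cph.log_likelihood_),
        aic=float(cph.AIC_partial_),
        covariates=tuple(covariates),
        n=int(df.shape[0]),
        n_events=int(df["event"].sum()),
    )


def nested_lrt(full: CoxResult, reduced: CoxResult) -> tuple[float, float]:
    """Likelihood-ratio chi-square 2(LL_full - LL_reduced) with df = covariate gap."""
    if not set(reduced.covariates) <= set(full.covariates):
        raise ValueError("reduced covariates must be a subset of the full model's")
    if (full.n, full.n_events) != (reduced.n, reduced.n_events):
        raise ValueError("models were fitted on different samples")
    df = len(full.covariates) - len(reduced.covariates)
    chi2 = max(2.0 * (full.log_likelihood - reduced.log_likelihood), 0.0)
    if df == 0:
        return float(chi2), 1.0 if chi2 == 0 else float("nan")
    return float(chi2), float(stats.chi2.sf(chi2, df))


@dataclass
class OptimismResult:
    apparent: float
    optimism: np.ndarray
    mean_optimism: float
    sd_optimism: float
    corrected: float
    ci: tuple
    n_boot: int
    n_failed: int
    seed: Optional[int]


def harrell_optimism(
    table: pd.DataFrame,
    covariates: Sequence[str],
    n_boot: int = 200,
    seed: Optional[int] = 42,
) -> OptimismResult:
    """Bootstrap optimism correction of Harrell's concordance index.

    Per iteration the model is refitted on a with-replacement patient resample;
    optimism = C(boot model, boot sample) - C(boot model, original sample);
    corrected = apparent - mean optimism.  Failed refits are skipped and
    counted.
    """
    from lifelines.utils import concordance_index

    apparent_fit = cox_fit(table, covariates)
    apparent = apparent_fit.concordance
    rng = np.random.default_rng(seed)
    opt, boot_c = [], []
    failed = 0
    covariates = list(covariates)
    x_orig = table[covariates].astype(float)
    for _ in range(n_boot):
        idx = rng.integers(table.shape[0], size=table.shape[0])
        boot = table.iloc[idx].reset_index(drop=True)
        try:
            fit = cox_fit(boot, covariates)
        except (RuntimeError, ValueError):
            failed += 1
            continue
        beta = fit.summary["coef"].to_numpy()
        lp_boot = boot[covariates].astype(float).to_numpy() @ beta
        lp_orig = x_orig.to_numpy() @ beta
        c_boot = concordance_index(boot["time_days"], -lp_boot, boot["event"])
        c_orig = concordance_index(table["time_days"], -lp_orig, table["event"])
        opt.append(c_boot - c_orig)
        boot_c.append(c_boot)
    opt = np.asarray(opt)
    mean_opt = float(opt.mean()) if opt.size else 0.0
    sd_opt = float(opt.std(ddof=1)) if opt.size > 1 else 0.0
    corrected = apparent - mean_opt
    if boot_c:
        lo, hi = np.percentile(np.asarray(boot_c) - opt, [2.5, 97.5])
    else:
        lo = hi = corrected
    return OptimismResult(
        apparent=apparent, optimism=opt, mean_optimism=mean_opt,
        sd_optimism=sd_opt, corrected=corrected, ci=(float(lo), float(hi)),
        n_boot=n_boot, n_failed=failed, seed=seed,
    )


def predictor_set_comparison(table: pd.DataFrame, predictor_sets: dict) -> dict:
    """Fit one Cox model per named predictor set; run LRTs for nested pairs.

    Returns per-set summaries (concordance, log-likelihood, AIC) and a table
    of nested-pair likelihood-ratio tests identified by the subset relation.
    """
    fits = {name: cox_fit(table, covs) for name, covs in predictor_sets.items()}
    rows = [
        {"set": name, "covariates": ",".join(fit.covariates),
         "concordance": fit.concordance, "log_likelihood": fit.log_likelihood,
         "aic": fit.aic}
        for name, fit in fits.items()
    ]
    lrts = []
    names = list(predictor_sets)
    for a in names:
        for b in names:
            if a != b and set(predictor_sets[a]) < set(predictor_sets[b]):
                chi2, p = nested_lrt(fits[b], fits[a])
                lrts.append({"reduced": a, "full": b, "chi2": chi2,
                             "df": len(fits[b].covariates) - len(fits[a].covariates),
                             "p": p})
    return {"models": pd.DataFrame(rows).set_index("set"),
            "lrt": pd.DataFrame(lrts), "fits": fits}
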