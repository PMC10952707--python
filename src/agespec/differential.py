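"""Per-probe activation differential methylation within one cohort.

Hypothesis testing runs on M-values (log2 of the methylation odds), where
array noise is closer to homoskedastic Gaussian; effect sizes and all
calling thresholds are on the raw beta scale, the field convention.  The
per-probe ordinary-least-squares residual variances are moderated by
empirical-Bayes shrinkage toward a pooled prior: the variances are modeled
as scaled-F around a prior variance s0^2 with d0 prior degrees of freedom,
estimated by moment-matching the log residual variances against the
log-F distribution (digamma/trigamma inversion), and

    s2_post = (d0 * s0^2 + df * s2) / (d0 + df)

with moderated t = coef / (se_unscaled * s_post) referred to a t
distribution on d0 + df degrees of freedom.  Multiple testing is handled
by Benjamini-Hochberg step-up.  A probe is a DMP when its adjusted p is
below ``alpha`` and its |delta beta| exceeds ``min_delta``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from agespec.io_formats import PROBE_STATS_COLUMNS, BetaMatrix

__all__ = [
    "ModerationParams",
    "m_transform",
    "make_design",
    "fit_probe_models",
    "trigamma_inverse",
    "fit_f_dist",
    "ebayes_moderate",
    "bh_adjust",
    "delta_beta",
    "call_dmps",
    "dmp_pipeline",
]

logger = logging.getLogger("agespec")

#: d0 is treated as infinite beyond this cap (no-shrinkage limit).
D0_CAP = 1e8


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes prior: d0 degrees of freedom, s0^2 prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive (math.inf allowed)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")

    @property
    def d0_effective(self) -> float:
        return min(self.d0, D0_CAP)


def m_transform(beta, epsilon: float = 1e-6) -> np.ndarray:
    """M = log2(b / (1 - b)) with b clipped to [epsilon, 1 - epsilon]."""
    if not 0 < epsilon <= 0.01:
        raise ValueError("epsilon must lie in (0, 0.01]")
    values = beta.values if isinstance(beta, BetaMatrix) else np.asarray(beta, dtype=float)
    b = np.clip(values, epsilon, 1 - epsilon)
    return np.log2(b / (1 - b))


def make_design(sheet: pd.DataFrame, covariates: tuple[str, ...] = (),
                pair_by_donor: bool = False) -> pd.DataFrame:
    """Design matrix: intercept, condition (activated=1), covariates, donors.

    Categorical covariates are reference-coded with the lexicographically
    first level as reference; numeric covariates enter as-is.  With
    ``pair_by_donor`` each donor beyond the first gets an indicator.
    """
    idx = sheet["sample_id"]
    cols = {"intercept": np.ones(len(sheet)),
            "condition": (sheet["condition"] == "activated").astype(float).to_numpy()}
    for cov in covariates:
        if cov not in sheet.columns:
            raise ValueError(f"covariate {cov!r} not in sample sheet")
        series = sheet[cov]
        if pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series):
            cols[cov] = series.to_numpy(float)
        else:
            levels = sorted(series.astype(str).unique())
            for level in levels[1:]:
                cols[f"{cov}[{level}]"] = (series.astype(str) == level).astype(float).to_numpy()
    if pair_by_donor:
        donors = sorted(sheet["donor_id"].astype(str).unique())
        for donor in donors[1:]:
            cols[f"donor[{donor}]"] = (sheet["donor_id"].astype(str) == donor).astype(float).to_numpy()
    design = pd.DataFrame(cols, index=idx)
    return design


def _collinear_columns(X: np.ndarray, names) -> list[str]:
    rank = np.linalg.matrix_rank(X)
    out = []
    for j in range(X.shape[1]):
        if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
            out.append(names[j])
    return out


def fit_probe_models(m: np.ndarray, design: pd.DataFrame) -> pd.DataFrame:
    """Ordinary least squares of every probe row of ``m`` on ``design``.

    Returns per-probe coef (condition effect), sigma2, df_resid and the
    unscaled standard error of the condition coefficient.
    """
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    if m.shape[1] != n:
        raise ValueError("M matrix and design have different sample counts")
    if np.linalg.matrix_rank(X) < k:
        bad = _collinear_columns(X, list(design.columns))
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    if "condition" not in design.columns:
        raise ValueError("design must contain a 'condition' column")
    c = list(design.columns).index("condition")

    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = m @ (xtx_inv @ X.T).T          # probes x k
    resid = m - coefs @ X.T
    df = n - k
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    sigma2 = np.einsum("ij,ij->i", resid, resid) / df
    se_unscaled = math.sqrt(xtx_inv[c, c])
    return pd.DataFrame(
        {
            "coef_m": coefs[:, c],
            "sigma2": sigma2,
            "df_resid": df,
            "se_unscaled": se_unscaled,
        }
    )


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        step = (tri - y) / float(special.polygamma(2, x))
        x -= step
        if x <= 0:
            x = 1e-8
        if abs(step) < tol * x:
            break
    return x


def fit_f_dist(sigma2: np.ndarray, df: float) -> ModerationParams:
    """Estimate (d0, s0^2) by moment-matching log(s^2) to a log-scaled-F.

    Under the hierarchical model s^2 ~ s0^2 * F(df, d0); equating the mean
    and variance of log(s^2) to the digamma/trigamma moments of log-F
    yields d0 from a trigamma inversion and s0^2 from the mean.  If the
    observed variances are under-dispersed relative to pure chi-square
    sampling noise, d0 is infinite (complete pooling).
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if len(sigma2) < 10:
        raise ValueError("need at least 10 probes to estimate the variance prior")
    if np.all(sigma2 <= 0):
        raise ValueError("all residual variances are zero; degenerate input")
    s2 = np.maximum(sigma2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        if d0 > D0_CAP:
            d0 = math.inf
    else:
        d0 = math.inf
    if math.isinf(d0):
        # complete-pooling limit: the prior is the geometric mean of the
        # observed variances (no chi-square bias correction), so that equal
        # variances give s2_post == s2 and the moderated t reduces exactly
        # to the ordinary t
        s0 = math.exp(float(np.mean(z)))
        logger.info("fit_f_dist: variances consistent with a common prior; d0 = inf")
    else:
        s0 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    return ModerationParams(d0=d0, s0_sq=s0)


def ebayes_moderate(sigma2: np.ndarray, df: float, coef: np.ndarray | None = None,
                    se_unscaled: float | np.ndarray | None = None):
    """Shrink per-probe variances and (optionally) form moderated t and p.

    Returns (params, s2_post) or, when coef / se_unscaled are supplied,
    (params, s2_post, t_mod, p).
    """
    params = fit_f_dist(sigma2, df)
    d0 = params.d0_effective
    s2_post = (d0 * params.s0_sq + df * np.asarray(sigma2, float)) / (d0 + df)
    if coef is None:
        return params, s2_post
    se = np.asarray(se_unscaled, dtype=float) * np.sqrt(s2_post)
    t_mod = np.asarray(coef, dtype=float) / se
    df_total = df + d0
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    return params, s2_post, t_mod, p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def delta_beta(beta: BetaMatrix, sheet: pd.DataFrame) -> np.ndarray:
    """mean(activated beta) - mean(quiescent beta), per probe, raw beta scale."""
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    cond = sheet.loc[beta.sample_ids, "condition"]
    act = np.flatnonzero((cond == "activated").to_numpy())
    qui = np.flatnonzero((cond == "quiescent").to_numpy())
    if len(act) == 0 or len(qui) == 0:
        raise ValueError("both conditions must be present to compute delta beta")
    values = beta.values
    return values[:, act].mean(axis=1) - values[:, qui].mean(axis=1)


def call_dmps(stats_table: pd.DataFrame, alpha: float = 0.01,
              min_delta: float = 0.05):
    """Set is_dmp (q < alpha and |delta beta| > min_delta) and summarize.

    Returns (table, summary) where summary has the total / hyper / hypo
    DMP counts.
    """
    out = stats_table.copy()
    out["is_dmp"] = (out["q"] < alpha) & (out["delta_beta"].abs() > min_delta)
    dmps = out[out["is_dmp"]]
    summary = {
        "total": int(len(dmps)),
        "hyper": int((dmps["delta_beta"] > 0).sum()),
        "hypo": int((dmps["delta_beta"] <= 0).sum()),
    }
    return out, summary


def dmp_pipeline(beta: BetaMatrix, sheet: pd.DataFrame, cohort: str,
                 covariates: tuple[str, ...] = (), pair_by_donor: bool = False,
                 alpha: float = 0.01, min_delta: float = 0.05,
                 epsilon: float = 1e-6):
    """Full within-cohort differential run; returns (ProbeStats table, summary).

    The two cohorts are analyzed separately with the same pipeline; this
    function subsets to one cohort, so the result is invariant to anything
    happening in the other cohort's samples.
    """
    sub_sheet = sheet[sheet["cohort"] == cohort].reset_index(drop=True)
    if len(sub_sheet) == 0:
        raise ValueError(f"no samples for cohort {cohort!r}")
    sub_beta = beta.subset_samples(sub_sheet["sample_id"])
    m = m_transform(sub_beta, epsilon)
    design = make_design(sub_sheet, covariates=covariates, pair_by_donor=pair_by_donor)
    fit = fit_probe_models(m, design)
    _, _, t_mod, p = ebayes_moderate(
        fit["sigma2"].to_numpy(), float(fit["df_resid"].iloc[0]),
        coef=fit["coef_m"].to_numpy(), se_unscaled=float(fit["se_unscaled"].iloc[0]),
    )
    q = bh_adjust(p)
    db = delta_beta(sub_beta, sub_sheet)
    table = pd.DataFrame(
        {
            "probe_id": sub_beta.probe_ids.to_numpy(),
            "coef_m": fit["coef_m"].to_numpy(),
            "sigma2": fit["sigma2"].to_numpy(),
            "df": fit["df_resid"].to_numpy(),
            "t_mod": t_mod,
            "p": p,
            "q": q,
            "delta_beta": db,
            "direction": np.where(db > 0, "hyper", "hypo"),
            "is_dmp": False,
        }
    )
    table, summary = call_dmps(table, alpha=alpha, min_delta=min_delta)
    logger.info("dmp_pipeline[%s]: %d DMPs (%d hyper / %d hypo) of %d probes",
                cohort, summary["total"], summary["hyper"], summary["hypo"], len(table))
    return table.loc[:, list(PROBE_STATS_COLUMNS)], summary
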