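"""Per-CpG differential methylation tests and significance calling.

Two test paths are provided, mirroring the two estimators commonly used
for cohort methylation scans.  The linear-model path — ordinary least
squares per site against a design matrix, reading the group
coefficient's t-test — is the default: with case groups of 2-6 samples
it pools residual variance over the whole cohort (limma-like residual
degrees of freedom) and remains estimable down to a single case against
the control pool; it also carries any covariate adjustment.  The Welch
t-test (unequal variances, Satterthwaite degrees of freedom) is the
alternative two-group comparison for balanced designs.

Tests operate on the beta scale.  A site is called a DMP when its
Benjamini-Hochberg q-value is below ``q_threshold`` (default 0.05)
and the absolute case-minus-control mean difference exceeds
``min_abs_delta`` (default 0.20) — the joint rule makes the scan
strongly conservative under the null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

P_FLOOR = np.finfo(float).tiny


class InsufficientDataError(ValueError):
    """Raised when a group is too small for the Welch path."""


@dataclass(frozen=True)
class SignificanceParams:
    q_threshold: float = 0.05
    min_abs_delta: float = 0.20
    test: str = "linear_model"  # or "welch"

    def __post_init__(self) -> None:
        if not (0.0 < self.q_threshold < 1.0 and 0.0 < self.min_abs_delta < 1.0):
            raise ValueError("thresholds must be in (0, 1)")
        if self.test not in ("welch", "linear_model"):
            raise ValueError(f"unknown test {self.test!r}")


def welch_test(case: np.ndarray, control: np.ndarray) -> tuple[float, float, float]:
    """Two-sided Welch t-test; returns (t, df, p).

    Degenerate inputs: both variances zero with equal means gives
    (0, n1+n2-2, 1); both zero with unequal means gives p at the
    smallest positive float and infinite t (flagged in the log).
    """
    case = np.asarray(case, float)
    control = np.asarray(control, float)
    case = case[~np.isnan(case)]
    control = control[~np.isnan(control)]
    n1, n2 = len(case), len(control)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("insufficient n, use linear_model path")
    m1, m2 = case.mean(), control.mean()
    v1, v2 = case.var(ddof=1), control.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        if m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        logger.warning("degenerate Welch test: zero variance, unequal means")
        return float(np.sign(m1 - m2) * np.inf), float(n1 + n2 - 2), P_FLOOR
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(max(p, P_FLOOR))


def mean_difference(case: np.ndarray, control: np.ndarray) -> float:
    """mean(case) - mean(control), NaN when a group has no observations."""
    case = np.asarray(case, float)
    control = np.asarray(control, float)
    case = case[~np.isnan(case)]
    control = control[~np.isnan(control)]
    if len(case) == 0 or len(control) == 0:
        return float("nan")
    return float(case.mean() - control.mean())


def linear_model_test(y: np.ndarray, design: pd.DataFrame, coef: str = "group"):
    """OLS of a single site's betas on the design; t-test on one coefficient.

    Missing samples are dropped for this site.  Returns (effect, p);
    both NaN when the design becomes rank-deficient after the drop or
    no residual degrees of freedom remain.
    """
    y = np.asarray(y, float)
    X = design.to_numpy(float)
    ok = ~np.isnan(y)
    yv, Xv = y[ok], X[ok]
    j = list(design.columns).index(coef)
    n, p = Xv.shape
    if n <= p or np.linalg.matrix_rank(Xv) < p:
        return float("nan"), float("nan")
    XtX_inv = np.linalg.inv(Xv.T @ Xv)
    bhat = XtX_inv @ Xv.T @ yv
    resid = yv - Xv @ bhat
    dof = n - p
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * XtX_inv[j, j])
    if se == 0.0:
        pval = 1.0 if bhat[j] == 0.0 else P_FLOOR
    else:
        pval = 2.0 * stats.t.sf(abs(bhat[j] / se), dof)
    return float(bhat[j]), float(max(pval, P_FLOOR))


def adjust_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs are excluded and propagated."""
    p = np.asarray(p, float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _welch_scan(case: np.ndarray, control: np.ndarray):
    """Vectorized Welch test over sites (rows).  Returns t, df, p arrays."""
    n1 = (~np.isnan(case)).sum(axis=1)
    n2 = (~np.isnan(control)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(case, axis=1)
        m2 = np.nanmean(control, axis=1)
        v1 = np.nanvar(case, axis=1, ddof=1)
        v2 = np.nanvar(control, axis=1, ddof=1)
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    testable = (n1 >= 2) & (n2 >= 2)
    zerovar = testable & (v1 == 0) & (v2 == 0)
    eq = zerovar & (m1 == m2)
    ne = zerovar & (m1 != m2)
    t[eq], df[eq], p[eq] = 0.0, (n1 + n2 - 2)[eq], 1.0
    t[ne] = np.sign((m1 - m2)[ne]) * np.inf
    df[ne] = (n1 + n2 - 2)[ne]
    p[ne] = P_FLOOR
    t[~testable] = np.nan
    df[~testable] = np.nan
    p[~testable] = np.nan
    p = np.where(np.isnan(p), np.nan, np.maximum(p, P_FLOOR))
    return t, df, p


def _linear_scan(Y: np.ndarray, design: pd.DataFrame, coef: str = "group"):
    """Vectorized per-site OLS grouped by missingness pattern.

    Returns (effect, p) arrays over sites.  Sites whose missingness
    pattern leaves the design rank-deficient are NaN.
    """
    X = design.to_numpy(float)
    j = list(design.columns).index(coef)
    n_sites = Y.shape[0]
    effect = np.full(n_sites, np.nan)
    pval = np.full(n_sites, np.nan)
    obs = ~np.isnan(Y)
    # group sites sharing a missingness pattern and solve each batch at once
    pattern_ids = {}
    site_pattern = np.empty(n_sites, dtype=int)
    for i in range(n_sites):
        key = obs[i].tobytes()
        site_pattern[i] = pattern_ids.setdefault(key, len(pattern_ids))
    for key, pid in pattern_ids.items():
        mask = np.frombuffer(key, dtype=bool)
        rows = np.where(site_pattern == pid)[0]
        Xv = X[mask]
        n, p = Xv.shape
        if n <= p or np.linalg.matrix_rank(Xv) < p:
            continue
        XtX_inv = np.linalg.inv(Xv.T @ Xv)
        H = XtX_inv @ Xv.T
        Yv = Y[np.ix_(rows, mask)]
        B = Yv @ H.T  # sites x p coefficients
        resid = Yv - B @ Xv.T
        dof = n - p
        sigma2 = (resid**2).sum(axis=1) / dof
        se = np.sqrt(sigma2 * XtX_inv[j, j])
        b = B[:, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = b / se
            pv = 2.0 * stats.t.sf(np.abs(tstat), dof)
        pv = np.where(se == 0.0, np.where(b == 0.0, 1.0, P_FLOOR), pv)
        effect[rows] = b
        pval[rows] = np.maximum(pv, P_FLOOR)
    return effect, pval


def differential_scan(
    beta: pd.DataFrame,
    case_ids: list[str],
    control_ids: list[str],
    design: pd.DataFrame | None = None,
    params: SignificanceParams | None = None,
) -> pd.DataFrame:
    """Run the per-site differential test over a full beta matrix.

    ``beta`` is sites x samples.  With ``params.test == 'welch'`` and no
    design, the vectorized Welch scan is used; sites where a group has
    fewer than two observations fall back to the linear-model path, as
    does everything when a design is supplied.  Returns the site result
    table (chrom, pos, delta_beta, t, df, p, q, direction, n_case,
    n_control) in genomic order.
    """
    params = params or SignificanceParams()
    case = beta[case_ids].to_numpy(float)
    control = beta[control_ids].to_numpy(float)
    n_sites = len(beta)

    n1 = (~np.isnan(case)).sum(axis=1)
    n2 = (~np.isnan(control)).sum(axis=1)
    m1 = np.where(n1 > 0, np.nansum(case, axis=1) / np.maximum(n1, 1), np.nan)
    m2 = np.where(n2 > 0, np.nansum(control, axis=1) / np.maximum(n2, 1), np.nan)
    delta = m1 - m2

    use_linear = params.test == "linear_model" or design is not None
    t = np.full(n_sites, np.nan)
    df = np.full(n_sites, np.nan)
    p = np.full(n_sites, np.nan)
    effect = np.full(n_sites, np.nan)
    if not use_linear:
        t, df, p = _welch_scan(case, control)
        # fallback for sites the Welch path cannot test
        fallback = np.isnan(p) & (n1 >= 1) & (n2 >= 2)
        if fallback.any():
            simple = pd.DataFrame(
                {
                    "intercept": 1.0,
                    "group": [1.0] * len(case_ids) + [0.0] * len(control_ids),
                },
                index=case_ids + control_ids,
            )
            Y = beta[case_ids + control_ids].to_numpy(float)[fallback]
            _, p_fb = _linear_scan(Y, simple)
            p[fallback] = p_fb
    else:
        if design is None:
            design = pd.DataFrame(
                {
                    "intercept": 1.0,
                    "group": [1.0] * len(case_ids) + [0.0] * len(control_ids),
                },
                index=case_ids + control_ids,
            )
        Y = beta[list(design.index)].to_numpy(float)
        effect, p = _linear_scan(Y, design)

    q = adjust_fdr(p)
    idx = beta.index
    out = pd.DataFrame(
        {
            "chrom": idx.get_level_values("chrom"),
            "pos": idx.get_level_values("pos"),
            "delta_beta": delta,
            "effect": effect,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "n_case": n1,
            "n_control": n2,
        }
    )
    out["direction"] = np.where(out["delta_beta"] > 0, "hyper", "hypo")
    out.loc[out["delta_beta"].isna(), "direction"] = ""
    return out.reset_index(drop=True)


def call_significant_sites(
    results: pd.DataFrame, params: SignificanceParams | None = None
) -> pd.DataFrame:
    """Apply the joint FDR + effect-size rule; returns the DMP subset.

    A DMP has q < q_threshold (strict) and |delta_beta| > min_abs_delta
    (strict).  The returned frame keeps result columns and genomic order;
    hyper/hypo counts are attached as ``.attrs['n_hyper']`` /
    ``.attrs['n_hypo']``.
    """
    params = params or SignificanceParams()
    sig = results.loc[
        (results["q"] < params.q_threshold)
        & (results["delta_beta"].abs() > params.min_abs_delta)
    ].copy()
    sig.attrs["n_hyper"] = int((sig["direction"] == "hyper").sum())
    sig.attrs["n_hypo"] = int((sig["direction"] == "hypo").sum())
    return sig
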