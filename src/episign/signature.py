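"""Episignature representation: control-normalized z-scores and summaries.

At the signature sites (the DMPs of a contrast) each sample's beta is
re-expressed relative to the healthy controls,

    z = (beta_sample - control_mean) / control_sd,

with mean and SD computed from controls only (n-1 denominator).  A
sample gains methylation (GOM) at a site when z exceeds +3 and loses it
(LOM) below -3, the conventional 3-SD confidence band.  Unsupervised
summaries — complete-linkage hierarchical clustering of the z-matrix and
PCA of the pre-processed (un-normalized) betas — mirror how episignature
cohorts are visually classified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

GOM_LOM_THRESHOLD = 3.0


@dataclass
class ControlStats:
    """Per-site control mean / SD over the signature sites."""

    mean: pd.Series  # indexed by (chrom, pos)
    sd: pd.Series
    n_control: int

    def __post_init__(self) -> None:
        if self.n_control < 2:
            raise ValueError("need >= 2 controls")
        if not self.mean.index.equals(self.sd.index):
            raise ValueError("mean / sd site mismatch")


def normalize_to_controls(
    beta: pd.DataFrame, control_ids: list[str]
) -> tuple[ControlStats, pd.DataFrame]:
    """Control-referenced z-scores for every sample (controls included).

    ``beta`` is restricted to the signature sites beforehand.  Sites
    where the control SD is zero get missing z for every sample.
    """
    ctrl = beta[control_ids].to_numpy(float)
    n_ctrl_obs = (~np.isnan(ctrl)).sum(axis=1)
    if (n_ctrl_obs < 2).any():
        logger.warning(
            "%d sites have fewer than 2 control observations", int((n_ctrl_obs < 2).sum())
        )
    import warnings as _w

    with np.errstate(invalid="ignore"), _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(ctrl, axis=1)
        sd = np.nanstd(ctrl, axis=1, ddof=1)
    zero_sd = sd == 0
    if zero_sd.any():
        logger.warning("%d sites have zero control SD; z set missing", int(zero_sd.sum()))
    sd_safe = np.where(zero_sd | np.isnan(sd), np.nan, sd)
    z = (beta.to_numpy(float) - mean[:, None]) / sd_safe[:, None]
    stats_ = ControlStats(
        pd.Series(mean, index=beta.index),
        pd.Series(sd, index=beta.index),
        len(control_ids),
    )
    return stats_, pd.DataFrame(z, index=beta.index, columns=beta.columns)


def call_gom_lom(
    z: pd.DataFrame, threshold: float = GOM_LOM_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call gain / loss of methylation per sample per site.

    Returns (calls, counts): calls is a site x sample frame of
    {"GOM", "LOM", ""}; counts is a sample x {GOM, LOM} table.
    """
    vals = z.to_numpy(float)
    calls = np.where(vals > threshold, "GOM", np.where(vals < -threshold, "LOM", ""))
    calls = pd.DataFrame(calls, index=z.index, columns=z.columns)
    counts = pd.DataFrame(
        {
            "GOM": (calls == "GOM").sum(axis=0),
            "LOM": (calls == "LOM").sum(axis=0),
        }
    )
    return calls, counts


def hierarchical_cluster(
    z: pd.DataFrame, method: str = "complete", metric: str = "euclidean"
) -> tuple[np.ndarray, list[str]]:
    """Complete-linkage clustering of samples on the z-matrix.

    Missing cells are imputed to 0 (the control mean on the z scale)
    before computing Euclidean distances.  Returns the scipy linkage
    matrix and the dendrogram leaf order as sample ids.
    """
    X = z.to_numpy(float).T  # samples x sites
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples to cluster")
    X = np.nan_to_num(X, nan=0.0)
    Z = linkage(pdist(X, metric=metric), method=method)
    order = [z.columns[i] for i in leaves_list(Z)]
    return Z, order


def pca_embed(
    beta: pd.DataFrame,
    groups: pd.Series | None = None,
    n_components: int = 2,
    ellipse_level: float = 0.95,
) -> dict:
    """PCA of samples on complete-case pre-processed betas.

    Scores are mean-centered SVD projections; variance-explained
    fractions accompany them.  For each group with more than two
    members a 95% concentration ellipse is fitted from the group mean
    and covariance of the first two scores with a Hotelling-T^2 (F)
    radius, the usual small-sample multivariate-t construction.

    Returns a dict with ``scores`` (samples x PCs), ``variance_ratio``
    and ``ellipses`` (group -> dict(center, cov, radius)).
    """
    X = beta.to_numpy(float)
    complete = ~np.isnan(X).any(axis=1)
    Xc = X[complete].T  # samples x sites
    n, m = Xc.shape
    if n < 3:
        raise ValueError("need >= 3 samples for PCA")
    k = min(n_components, min(n, m))
    if k < n_components:
        logger.warning("reducing components from %d to %d", n_components, k)
    Xc = Xc - Xc.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = pd.DataFrame(
        U[:, :k] * s[:k],
        index=beta.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    var = s**2
    variance_ratio = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)

    ellipses = {}
    if groups is not None and k >= 2:
        for g, members in groups.groupby(groups):
            ids = [i for i in members.index if i in scores.index]
            if len(ids) <= 2:
                continue
            pts = scores.loc[ids, ["PC1", "PC2"]].to_numpy()
            ng = len(ids)
            center = pts.mean(axis=0)
            cov = np.cov(pts.T)
            if ng - 2 <= 0:
                continue
            fq = stats.f.ppf(ellipse_level, 2, ng - 2)
            radius = float(np.sqrt(2 * (ng - 1) / (ng - 2) * fq / ng) * np.sqrt(ng))
            ellipses[g] = {"center": center, "cov": cov, "radius": radius}
    return {"scores": scores, "variance_ratio": variance_ratio, "ellipses": ellipses}


def select_nonredundant(beta: pd.DataFrame, cutoff: float = 0.90) -> pd.MultiIndex:
    """Greedy correlation filter over DMP rows (sites x samples).

    While any pair of sites has absolute Pearson correlation above the
    cutoff, the member of the currently worst pair with the larger mean
    absolute correlation against everything still in play is removed
    (ties keep the lower site index).  Survivors return in genomic
    order.  Constant rows correlate 0 with everything.
    """
    if len(beta) < 2:
        return beta.index
    X = beta.to_numpy(float)
    X = np.where(np.isnan(X), np.nanmean(X, axis=1, keepdims=True), X)
    sds = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    C = np.nan_to_num(C, nan=0.0)
    C[sds == 0, :] = 0.0
    C[:, sds == 0] = 0.0
    np.fill_diagonal(C, 0.0)
    A = np.abs(C)
    alive = np.ones(len(beta), dtype=bool)
    while True:
        sub = np.where(alive)[0]
        if len(sub) < 2:
            break
        Asub = A[np.ix_(sub, sub)]
        mx = Asub.max()
        if mx <= cutoff:
            break
        i_s, j_s = np.unravel_index(np.argmax(Asub), Asub.shape)
        i, j = sub[i_s], sub[j_s]
        mean_i = A[i, sub].sum() / (len(sub) - 1)
        mean_j = A[j, sub].sum() / (len(sub) - 1)
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:
            drop = max(i, j)  # tie: keep the lower site index
        alive[drop] = False
    return beta.index[alive]


def score_sample(
    sample_beta: pd.Series,
    directions: pd.Series,
    control_stats: ControlStats,
    min_usable: float = 0.5,
) -> tuple[float, float]:
    """Direction-aware mean z of a sample over the signature sites.

    ``directions`` maps each signature site to 'hyper' or 'hypo'; the
    score is mean(z * sign), so a sample matching the signature scores
    high regardless of its direction.  Returns (score, usable_fraction);
    the score is NaN when fewer than ``min_usable`` of the signature
    sites are observed in the sample.
    """
    sites = directions.index
    b = sample_beta.reindex(sites).to_numpy(float)
    mu = control_stats.mean.reindex(sites).to_numpy(float)
    sd = control_stats.sd.reindex(sites).to_numpy(float)
    sign = np.where(directions.to_numpy() == "hyper", 1.0, -1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (b - mu) / np.where(sd > 0, sd, np.nan)
    usable = ~np.isnan(z)
    frac = usable.mean() if len(sites) else 0.0
    if frac < min_usable:
        logger.warning("score missing: only %.0f%% of signature sites usable", 100 * frac)
        return float("nan"), float(frac)
    return float(np.mean(z[usable] * sign[usable])), float(frac)
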