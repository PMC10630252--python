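"""Confounder handling: cell-type deconvolution, batch detection, SVA, design.

Blood methylation is a mixture signal: each sample's beta value at a CpG
is (to first order) a convex combination of the cell-type-specific
methylomes weighted by the leukocyte proportions.  Reference-based
deconvolution therefore solves, per sample, a constrained least-squares
projection of the observed marker betas onto the reference profiles
(non-negative proportions summing to at most one).  The estimated
proportions, the recorded covariates (age, sex, batch) and optional
surrogate variables all enter the per-site linear model as columns of a
single design matrix.

Surrogate variables are estimated from the principal components of the
residuals after removing the primary design, keeping only components
whose eigenvalue exceeds the 95th percentile of eigenvalues obtained
from row-permuted residual matrices — a deterministic, seedable
permutation calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import BetaMatrix, SampleSheet

logger = logging.getLogger(__name__)


@dataclass
class CellTypeReference:
    """Marker-CpG reference methylomes, one column per cell type."""

    sites: pd.MultiIndex  # (chrom, pos) of marker CpGs
    profiles: pd.DataFrame  # marker x cell type, betas in [0, 1]

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ValueError("need at least 2 cell types")
        if self.profiles.isna().any().any():
            raise ValueError("reference betas must not be missing")
        vals = self.profiles.to_numpy(float)
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("reference betas outside [0, 1]")
        if len(self.sites) != len(self.profiles):
            raise ValueError("sites / profile row mismatch")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "CellTypeReference":
        """Build from a delimited table with chrom, pos and one column per type."""
        idx = pd.MultiIndex.from_arrays(
            [table["chrom"], table["pos"].astype(int)], names=["chrom", "pos"]
        )
        profiles = table.drop(columns=["chrom", "pos"]).set_index(idx)
        return cls(idx, profiles)


def _project_simplex(y: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Least squares ||R w - y|| s.t. w >= 0, sum w <= 1 (SLSQP)."""
    k = R.shape[1]
    w0 = np.full(k, 1.0 / (k + 1))
    res = optimize.minimize(
        lambda w: float(np.sum((R @ w - y) ** 2)),
        w0,
        jac=lambda w: 2.0 * R.T @ (R @ w - y),
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "ineq", "fun": lambda w: 1.0 - w.sum(),
                      "jac": lambda w: -np.ones_like(w)}],
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0.0, 1.0)
    s = w.sum()
    if s > 1.0:
        w /= s
    return w


def estimate_cell_proportions(
    matrix: BetaMatrix, reference: CellTypeReference
) -> pd.DataFrame:
    """Estimate per-sample cell-type proportions by constrained projection.

    For each sample the marker betas present in the matrix are projected
    onto the reference profiles under non-negativity and sum-to-at-most-
    one constraints.  Markers missing in a sample are excluded pairwise.

    Returns a sample x cell-type DataFrame of proportions.
    """
    common = matrix.sites.intersection(reference.sites)
    k = len(reference.cell_types)
    if len(common) < k:
        raise ValueError(
            f"reference underdetermined: {len(common)} usable markers for {k} cell types"
        )
    R_full = reference.profiles.loc[common].to_numpy(float)
    B = matrix.beta.loc[common]
    out = {}
    for sid in matrix.samples:
        y = B[sid].to_numpy(float)
        ok = ~np.isnan(y)
        if ok.sum() < k:
            raise ValueError(
                f"reference underdetermined for sample {sid}: {int(ok.sum())} markers"
            )
        out[sid] = _project_simplex(y[ok], R_full[ok])
    return pd.DataFrame(out, index=reference.cell_types).T


def _complete_case_pcs(matrix: BetaMatrix, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """PC scores (samples x k) and variance fractions from complete-case sites."""
    X = matrix.beta.to_numpy(float)
    complete = ~np.isnan(X).any(axis=1)
    X = X[complete].T  # samples x sites
    if X.shape[1] == 0:
        raise ValueError("no complete-case sites for PCA")
    Xc = X - X.mean(axis=0)
    if not (Xc.std(axis=0) > 0).any():
        raise ValueError("no variance")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(s))
    var = s**2
    return U[:, :k] * s[:k], var[:k] / var.sum()


def detect_batch_effect(
    matrix: BetaMatrix,
    sheet: SampleSheet,
    n_components: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test top principal components for association with age, sex and batch.

    Age uses a Pearson correlation test; sex and batch use a one-way
    F test across levels.  Covariates with a single observed level are
    skipped.  Returns a tidy frame (pc, covariate, statistic, p, flagged).
    """
    if len(matrix.samples) < 3:
        raise ValueError("need at least 3 samples")
    scores, varfrac = _complete_case_pcs(matrix, n_components)
    meta = sheet.frame.set_index("id").loc[matrix.samples]
    rows = []
    for j in range(scores.shape[1]):
        pc = scores[:, j]
        age = meta["age"].to_numpy(float)
        if np.ptp(age) > 0 and np.std(pc) > 0:
            r, p = stats.pearsonr(pc, age)
            rows.append((j + 1, "age", float(r), float(p)))
        for cov in ("sex", "batch"):
            levels = meta[cov].astype(str)
            uniq = levels.unique()
            if len(uniq) < 2:
                continue
            groups = [pc[(levels == g).to_numpy()] for g in uniq]
            if any(len(g) < 1 for g in groups) or np.std(pc) == 0:
                continue
            f, p = stats.f_oneway(*groups)
            rows.append((j + 1, cov, float(f), float(p)))
    report = pd.DataFrame(rows, columns=["pc", "covariate", "statistic", "p"])
    report["flagged"] = report["p"] < alpha
    report.attrs["variance_explained"] = varfrac
    return report


def estimate_surrogate_variables(
    matrix: BetaMatrix,
    primary_design: pd.DataFrame,
    n_permutations: int = 20,
    max_sv: int = 5,
    quantile: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-calibrated residual PCA for latent-factor estimation.

    Fits the primary design per site by least squares on complete-case
    sites, takes principal components of the residual matrix, and keeps
    components whose eigenvalue exceeds the ``quantile`` of eigenvalues
    from ``n_permutations`` independently row-permuted residual matrices
    (each row permuted independently, breaking sample structure while
    preserving per-site residual distributions).  At most ``max_sv``
    components are returned.
    """
    rng = np.random.default_rng(seed)
    X = primary_design.to_numpy(float)
    Y = matrix.beta.to_numpy(float)
    complete = ~np.isnan(Y).any(axis=1)
    Y = Y[complete]  # sites x samples
    if Y.shape[0] == 0:
        return pd.DataFrame(index=matrix.samples)
    # residuals of beta on the design, all sites at once
    pinv = np.linalg.pinv(X)
    R = Y - (X @ (pinv @ Y.T)).T  # sites x samples
    if not np.any(R):
        return pd.DataFrame(index=matrix.samples)

    def eigvals(mat: np.ndarray) -> np.ndarray:
        # eigenvalue fractions of total variance: invariant to the norm
        # shrinkage the permutation + re-residualization introduces
        m = mat - mat.mean(axis=0, keepdims=True)
        s = np.linalg.svd(m, compute_uv=False)
        tot = (s**2).sum()
        return s**2 / tot if tot > 0 else s**2

    obs = eigvals(R)
    null_max = np.empty((n_permutations, len(obs)))
    for b in range(n_permutations):
        # permute each site's residuals independently across samples, then
        # re-residualize on the design so the null spectrum is comparable
        idx = np.argsort(rng.random(R.shape), axis=1)
        perm = np.take_along_axis(R, idx, axis=1)
        perm = perm - (X @ (pinv @ perm.T)).T
        null_max[b] = eigvals(perm)[: len(obs)]
    thresh = np.quantile(null_max, quantile, axis=0)
    exceeds = obs > thresh
    # surrogate variables are the LEADING components: stop at the first
    # eigenvalue that fails its permutation threshold
    n_keep = 0
    for flag in exceeds:
        if not flag:
            break
        n_keep += 1
    n_keep = min(n_keep, max_sv, len(matrix.samples) - 1)
    if n_keep == 0:
        return pd.DataFrame(index=matrix.samples)
    Rc = R - R.mean(axis=0, keepdims=True)
    _, _, Vt = np.linalg.svd(Rc, full_matrices=False)
    sv = Vt[:n_keep].T  # samples x n_sv
    cols = [f"SV{j + 1}" for j in range(sv.shape[1])]
    return pd.DataFrame(sv, index=matrix.samples, columns=cols)


@dataclass
class DesignOptions:
    include_age: bool = False
    include_sex: bool = False
    include_batch: bool = False
    include_celltype: bool = False
    include_sva: bool = False


def build_design_matrix(
    sheet: SampleSheet,
    case_group: str,
    control_group: str,
    proportions: pd.DataFrame | None = None,
    surrogate_variables: pd.DataFrame | None = None,
    options: DesignOptions | None = None,
) -> pd.DataFrame:
    """Assemble the per-site regression design for a case-vs-control contrast.

    Columns: intercept, group (1 = case, 0 = control), then requested
    covariates.  One cell-type proportion column is dropped (the
    proportions are nearly sum-constrained), and constant or collinear
    columns are pruned with a warning.  Rows cover only the two groups,
    in sample-sheet order.
    """
    options = options or DesignOptions()
    meta = sheet.frame
    sel = meta["group"].isin([case_group, control_group])
    meta = meta.loc[sel]
    if meta["group"].nunique() < 2:
        raise ValueError("cannot contrast groups: group column is constant")
    ids = meta["id"].tolist()
    design = pd.DataFrame(index=ids)
    design["intercept"] = 1.0
    design["group"] = (meta["group"] == case_group).astype(float).to_numpy()

    if options.include_age:
        design["age"] = meta["age"].to_numpy(float)
    if options.include_sex:
        design["sex_M"] = (meta["sex"].astype(str).str.upper() == "M").astype(float).to_numpy()
    if options.include_batch:
        dummies = pd.get_dummies(meta["batch"].astype(str), prefix="batch", drop_first=True)
        for c in dummies.columns:
            design[c] = dummies[c].astype(float).to_numpy()
    if options.include_celltype and proportions is not None:
        props = proportions.loc[ids]
        for c in props.columns[:-1]:  # drop one column: sum-to-<=1 redundancy
            design[f"prop_{c}"] = props[c].to_numpy(float)
    if options.include_sva and surrogate_variables is not None and surrogate_variables.shape[1]:
        sv = surrogate_variables.loc[ids]
        for c in sv.columns:
            design[c] = sv[c].to_numpy(float)

    design = _prune_degenerate(design)
    return design


def _prune_degenerate(design: pd.DataFrame) -> pd.DataFrame:
    """Drop constant (except intercept) then collinear columns, warning per drop."""
    keep = []
    for c in design.columns:
        col = design[c].to_numpy(float)
        if c != "intercept" and np.ptp(col) == 0:
            logger.warning("design column %r is constant; pruned", c)
            continue
        keep.append(c)
    design = design[keep]
    X = design.to_numpy(float)
    kept_idx: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept_idx + [j]]
        if np.linalg.matrix_rank(trial) == len(kept_idx) + 1:
            kept_idx.append(j)
        else:
            logger.warning("design column %r is collinear; pruned", design.columns[j])
    pruned = design.iloc[:, kept_idx]
    if "group" not in pruned.columns:
        raise ValueError("cannot contrast groups: group column pruned as degenerate")
    return pruned
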