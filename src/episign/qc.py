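"""Site and cell-level QC filters applied to the assembled beta matrix.

The filters mirror a standard targeted-bisulfite loading pass: mask
cells below the sequencing coverage threshold (10X by default), then
drop sites on sex chromosomes, sites overlapping a SNP mask, sites with
exceptionally high mean coverage (above a configurable quantile of the
per-site mean-coverage distribution), and sites missing in more than a
tolerated number of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BetaMatrix, RegionSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCParams:
    min_coverage: int = 10
    sex_chroms: frozenset = frozenset({"chrX", "chrY", "X", "Y"})
    max_missing_samples: int = 1
    coverage_outlier_quantile: float = 0.999

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0.0 < self.coverage_outlier_quantile < 1.0:
            raise ValueError("coverage_outlier_quantile must be in (0, 1)")


@dataclass
class QCReport:
    """Counts of what each filter removed and what survived."""

    n_input_sites: int = 0
    n_sex_chrom: int = 0
    n_snp_mask: int = 0
    n_coverage_outlier: int = 0
    n_missingness: int = 0
    n_cells_masked_low_coverage: int = 0
    n_retained_sites: int = 0
    n_samples: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [
            ("input_sites", self.n_input_sites),
            ("removed_sex_chromosome", self.n_sex_chrom),
            ("removed_snp_mask", self.n_snp_mask),
            ("removed_coverage_outlier", self.n_coverage_outlier),
            ("removed_missingness", self.n_missingness),
            ("cells_masked_low_coverage", self.n_cells_masked_low_coverage),
            ("retained_sites", self.n_retained_sites),
            ("samples", self.n_samples),
        ]
        return pd.DataFrame(rows, columns=["metric", "count"])

    def validate(self) -> None:
        removed = (
            self.n_sex_chrom + self.n_snp_mask + self.n_coverage_outlier + self.n_missingness
        )
        if removed + self.n_retained_sites != self.n_input_sites:
            raise AssertionError("QC accounting mismatch")


def mask_low_coverage(matrix: BetaMatrix, params: QCParams | None = None) -> BetaMatrix:
    """Set beta to missing wherever coverage is below the threshold.

    Coverage itself is left untouched so the outlier filter still sees it.
    """
    params = params or QCParams()
    cov = matrix.coverage.to_numpy(float)
    beta = matrix.beta.to_numpy(float).copy()
    low = ~np.isnan(cov) & (cov < params.min_coverage)
    beta[low] = np.nan
    beta[np.isnan(cov)] = np.nan
    return BetaMatrix(
        pd.DataFrame(beta, index=matrix.beta.index, columns=matrix.beta.columns),
        matrix.coverage,
    )


def filter_sites(
    matrix: BetaMatrix,
    snp_mask: RegionSet | None = None,
    params: QCParams | None = None,
) -> tuple[BetaMatrix, QCReport]:
    """Drop sites failing the four site-level rules, in a fixed order.

    Order: (1) sex chromosomes, (2) SNP-mask overlap, (3) mean-coverage
    outliers above the configured quantile, (4) missing in more than
    ``max_missing_samples`` samples.  A site removed by an earlier rule
    is not counted again by a later one.
    """
    params = params or QCParams()
    report = QCReport(n_input_sites=matrix.n_sites, n_samples=len(matrix.samples))

    beta = matrix.beta
    cov = matrix.coverage
    chroms = beta.index.get_level_values("chrom").astype(str)
    alive = np.ones(len(beta), dtype=bool)

    sex = np.asarray(chroms.isin([str(c) for c in params.sex_chroms]))
    report.n_sex_chrom = int((alive & sex).sum())
    alive &= ~sex

    if snp_mask is not None and len(snp_mask) > 0:
        pos = beta.index.get_level_values("pos").to_numpy()
        in_mask = np.fromiter(
            (snp_mask.overlaps_point(c, p) for c, p in zip(chroms, pos)),
            dtype=bool,
            count=len(beta),
        )
        report.n_snp_mask = int((alive & in_mask).sum())
        alive &= ~in_mask

    mean_cov = np.nanmean(cov.to_numpy(float), axis=1)
    if alive.any():
        # method="higher" makes the cutoff an attained value, so the rule
        # is stable under re-application at realistic matrix sizes
        cutoff = np.nanquantile(
            mean_cov[alive], params.coverage_outlier_quantile, method="higher"
        )
        outlier = mean_cov > cutoff
        report.n_coverage_outlier = int((alive & outlier).sum())
        alive &= ~outlier

    n_missing = np.isnan(beta.to_numpy(float)).sum(axis=1)
    too_missing = n_missing > params.max_missing_samples
    report.n_missingness = int((alive & too_missing).sum())
    alive &= ~too_missing

    report.n_retained_sites = int(alive.sum())
    report.n_cells_masked_low_coverage = int(
        (
            ~np.isnan(cov.to_numpy(float))
            & (cov.to_numpy(float) < params.min_coverage)
        ).sum()
    )
    report.validate()
    logger.info(
        "QC: %d/%d sites retained (sex=%d snp=%d outlier=%d missing=%d)",
        report.n_retained_sites,
        report.n_input_sites,
        report.n_sex_chrom,
        report.n_snp_mask,
        report.n_coverage_outlier,
        report.n_missingness,
    )
    return matrix.subset_sites(alive), report


def run_qc(
    matrix: BetaMatrix,
    snp_mask: RegionSet | None = None,
    params: QCParams | None = None,
) -> tuple[BetaMatrix, QCReport]:
    """Convenience wrapper: coverage masking followed by site filtering."""
    params = params or QCParams()
    masked = mask_low_coverage(matrix, params)
    return filter_sites(masked, snp_mask, params)
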