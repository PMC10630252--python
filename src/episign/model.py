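"""The modelling interface: EpisignatureModel -> fit() -> EpisignatureResults.

The model holds the assembled cohort (beta matrix + sample sheet +
annotation) and the analysis options; ``fit`` runs the discovery chain
for one case-vs-control contrast — QC, optional confounder adjustment,
the per-site differential scan, region aggregation, and the
control-normalized episignature — and returns a results object carrying
every table plus a ``summary()`` in the statsmodels tradition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import regions as reg
from . import signature as sig
from .confounds import (
    CellTypeReference,
    DesignOptions,
    build_design_matrix,
    estimate_cell_proportions,
    estimate_surrogate_variables,
)
from .io import BetaMatrix, RegionSet, SampleSheet, write_results
from .qc import QCParams, QCReport, run_qc
from .regions import RegionParams
from .sitetest import SignificanceParams, call_significant_sites, differential_scan

logger = logging.getLogger(__name__)


class EpisignatureModel:
    """Cohort methylation data plus analysis options, ready to fit contrasts.

    Parameters
    ----------
    matrix : BetaMatrix
        Assembled beta/coverage matrices (before QC; QC runs at fit time
        and is cached).
    sheet : SampleSheet
        Cohort metadata; the ``group`` column defines contrasts.
    islands, targets, genes, snp_mask : RegionSet, optional
        Annotation inputs.  Islands drive context annotation and island
        aggregation; targets drive the >= 3 target-region DMB rule.
    reference : CellTypeReference, optional
        Marker methylomes for cell-proportion adjustment.
    """

    def __init__(
        self,
        matrix: BetaMatrix,
        sheet: SampleSheet,
        islands: RegionSet | None = None,
        targets: RegionSet | None = None,
        genes: RegionSet | None = None,
        snp_mask: RegionSet | None = None,
        reference: CellTypeReference | None = None,
        qc_params: QCParams | None = None,
    ):
        self.matrix = matrix
        self.sheet = sheet
        self.islands = islands
        self.targets = targets
        self.genes = genes
        self.snp_mask = snp_mask
        self.reference = reference
        self.qc_params = qc_params or QCParams()
        self._qc_cache: tuple[BetaMatrix, QCReport] | None = None

    @classmethod
    def from_coverage_tables(
        cls, tables: dict[str, pd.DataFrame], sheet: SampleSheet, **kwargs
    ) -> "EpisignatureModel":
        from .io import assemble_beta_matrix

        return cls(assemble_beta_matrix(tables, sheet), sheet, **kwargs)

    # ------------------------------------------------------------------
    @property
    def qc(self) -> tuple[BetaMatrix, QCReport]:
        if self._qc_cache is None:
            self._qc_cache = run_qc(self.matrix, self.snp_mask, self.qc_params)
        return self._qc_cache

    def fit(
        self,
        case_group: str,
        control_group: str = "control",
        sig_params: SignificanceParams | None = None,
        region_params: RegionParams | None = None,
        adjust_celltype: bool = False,
        adjust_sva: bool = False,
        covariates: tuple = (),
        nonredundant_cutoff: float = 0.90,
        gomlom_threshold: float = 3.0,
        seed: int = 0,
    ) -> "EpisignatureResults":
        """Fit one case-vs-control contrast end to end."""
        sig_params = sig_params or SignificanceParams()
        region_params = region_params or RegionParams()
        clean, qc_report = self.qc

        case_ids = self.sheet.samples_in_group(case_group)
        control_ids = self.sheet.samples_in_group(control_group)
        if not case_ids:
            raise ValueError(f"no samples in case group {case_group!r}")
        if len(control_ids) < 2:
            raise ValueError("need >= 2 controls")
        cohort = clean.subset_samples(case_ids + control_ids)

        # --- optional confounder adjustment ---------------------------
        design = None
        proportions = None
        svs = None
        need_linear = (
            adjust_celltype or adjust_sva or bool(covariates) or len(case_ids) < 2
        )
        if adjust_celltype:
            if self.reference is None:
                raise ValueError("adjust_celltype requires a cell-type reference")
            proportions = estimate_cell_proportions(cohort, self.reference)
        if adjust_celltype or adjust_sva or covariates:
            opts = DesignOptions(
                include_age="age" in covariates,
                include_sex="sex" in covariates,
                include_batch="batch" in covariates,
                include_celltype=adjust_celltype,
                include_sva=False,
            )
            design = build_design_matrix(
                self.sheet, case_group, control_group, proportions, None, opts
            )
            if adjust_sva:
                svs = estimate_surrogate_variables(
                    cohort.subset_samples(list(design.index)), design, seed=seed
                )
                opts = DesignOptions(
                    include_age="age" in covariates,
                    include_sex="sex" in covariates,
                    include_batch="batch" in covariates,
                    include_celltype=adjust_celltype,
                    include_sva=True,
                )
                design = build_design_matrix(
                    self.sheet, case_group, control_group, proportions, svs, opts
                )
        scan_params = sig_params
        if need_linear and sig_params.test != "linear_model":
            scan_params = SignificanceParams(
                sig_params.q_threshold, sig_params.min_abs_delta, "linear_model"
            )

        # --- site scan -------------------------------------------------
        site_results = differential_scan(
            cohort.beta, case_ids, control_ids, design=design, params=scan_params
        )
        site_idx = pd.MultiIndex.from_arrays(
            [site_results["chrom"], site_results["pos"]], names=["chrom", "pos"]
        )
        context = (
            reg.annotate_cpg_context(site_idx, self.islands)
            if self.islands is not None
            else pd.Series("open_sea", index=site_idx, name="context")
        )
        site_results = site_results.assign(context=context.to_numpy())
        dmps = call_significant_sites(site_results, scan_params)

        # --- regions ---------------------------------------------------
        nonisland_dmps = dmps[dmps["context"] != "island"]
        dmb_cands = reg.build_dmbs(
            nonisland_dmps,
            gap=region_params.dmb_gap_bp,
            min_span=region_params.dmb_min_span_bp,
            max_span=region_params.dmb_max_span_bp,
        )
        if self.islands is not None:
            island_cands = reg.islands_with_sites(site_results, self.islands, dmps.index)
        else:
            island_cands = pd.DataFrame(
                columns=["chrom", "start", "end", "n_sites", "site_idx"]
            )
        control_beta = cohort.beta[control_ids].set_axis(site_results.index, axis=0)
        regions_out = reg.score_regions(
            dmb_cands,
            island_cands,
            site_results,
            self.targets,
            region_params,
            control_beta=control_beta,
        )
        if self.genes is not None and len(regions_out):
            regions_out = regions_out.assign(
                genes=reg.overlap_genes(regions_out, self.genes).map(",".join)
            )

        # --- episignature ----------------------------------------------
        signature_sites = pd.MultiIndex.from_arrays(
            [dmps["chrom"], dmps["pos"]], names=["chrom", "pos"]
        )
        control_stats = None
        zmat = None
        gomlom_counts = None
        link = None
        leaf_order = None
        nonredundant = None
        if len(signature_sites) >= 1:
            sub = cohort.beta.loc[signature_sites]
            control_stats, zmat = sig.normalize_to_controls(sub, control_ids)
            _, gomlom_counts = sig.call_gom_lom(zmat, gomlom_threshold)
            if len(cohort.samples) >= 2 and len(signature_sites) >= 1:
                link, leaf_order = sig.hierarchical_cluster(zmat)
            if len(signature_sites) >= 2:
                nonredundant = sig.select_nonredundant(sub, nonredundant_cutoff)
            else:
                nonredundant = signature_sites

        pca = None
        if len(cohort.samples) >= 3 and len(signature_sites) >= 1:
            pca = sig.pca_embed(
                cohort.beta.loc[signature_sites],
                groups=self.sheet.groups.loc[cohort.samples],
            )

        comp = reg.context_composition(dmps, context)

        return EpisignatureResults(
            model=self,
            case_group=case_group,
            control_group=control_group,
            case_ids=case_ids,
            control_ids=control_ids,
            qc_report=qc_report,
            site_results=site_results,
            dmps=dmps,
            regions=regions_out,
            context_composition=comp,
            control_stats=control_stats,
            z_matrix=zmat,
            gomlom_counts=gomlom_counts,
            linkage_matrix=link,
            leaf_order=leaf_order,
            nonredundant_sites=nonredundant,
            pca=pca,
            design=design,
            proportions=proportions,
            surrogate_variables=svs,
            sig_params=scan_params,
            region_params=region_params,
        )


@dataclass
class EpisignatureResults:
    """Everything one fitted contrast produced."""

    model: EpisignatureModel
    case_group: str
    control_group: str
    case_ids: list[str]
    control_ids: list[str]
    qc_report: QCReport
    site_results: pd.DataFrame
    dmps: pd.DataFrame
    regions: pd.DataFrame
    context_composition: pd.Series
    control_stats: sig.ControlStats | None
    z_matrix: pd.DataFrame | None
    gomlom_counts: pd.DataFrame | None
    linkage_matrix: np.ndarray | None
    leaf_order: list[str] | None
    nonredundant_sites: pd.MultiIndex | None
    pca: dict | None
    design: pd.DataFrame | None
    proportions: pd.DataFrame | None
    surrogate_variables: pd.DataFrame | None
    sig_params: SignificanceParams
    region_params: RegionParams

    # ------------------------------------------------------------------
    @property
    def n_dmps(self) -> int:
        return len(self.dmps)

    @property
    def n_islands(self) -> int:
        return int((self.regions["klass"] == "island").sum()) if len(self.regions) else 0

    @property
    def n_dmbs(self) -> int:
        return int((self.regions["klass"] == "dmb").sum()) if len(self.regions) else 0

    @property
    def n_hyper(self) -> int:
        return int(self.dmps.attrs.get("n_hyper", (self.dmps["direction"] == "hyper").sum()))

    @property
    def n_hypo(self) -> int:
        return int(self.dmps.attrs.get("n_hypo", (self.dmps["direction"] == "hypo").sum()))

    def score_sample(self, sample_beta: pd.Series) -> tuple[float, float]:
        """Signature score of an arbitrary sample (see signature.score_sample)."""
        if self.control_stats is None or len(self.dmps) == 0:
            return float("nan"), 0.0
        directions = pd.Series(
            self.dmps["direction"].to_numpy(),
            index=pd.MultiIndex.from_arrays(
                [self.dmps["chrom"], self.dmps["pos"]], names=["chrom", "pos"]
            ),
        )
        return sig.score_sample(sample_beta, directions, self.control_stats)

    def summary(self) -> str:
        qc = self.qc_report
        lines = [
            "Episignature discovery results",
            "=" * 46,
            f"contrast:        {self.case_group} (n={len(self.case_ids)})"
            f" vs {self.control_group} (n={len(self.control_ids)})",
            f"test path:       {self.sig_params.test}",
            f"sites tested:    {qc.n_retained_sites}"
            f" (of {qc.n_input_sites}; sex={qc.n_sex_chrom}, snp={qc.n_snp_mask},"
            f" outlier={qc.n_coverage_outlier}, missing={qc.n_missingness})",
            f"DMPs:            {self.n_dmps}"
            f" ({self.n_hyper} hyper / {self.n_hypo} hypo)",
            f"significant regions: {self.n_islands} islands, {self.n_dmbs} DMBs",
            "DMP context:     "
            + ", ".join(
                f"{k}={self.context_composition[k]:.2f}"
                for k in self.context_composition.index
            ),
        ]
        if self.nonredundant_sites is not None:
            lines.append(f"non-redundant DMPs: {len(self.nonredundant_sites)}")
        if self.gomlom_counts is not None and len(self.case_ids):
            gl = self.gomlom_counts.loc[self.case_ids]
            lines.append(
                "case GOM/LOM:    "
                + "; ".join(
                    f"{s}: {int(r.GOM)}/{int(r.LOM)}" for s, r in gl.iterrows()
                )
            )
        return "\n".join(lines)

    def save(self, prefix: str | Path) -> dict[str, Path]:
        """Write the site/region tables and episignature bundle as TSV/JSON."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {}
        site_path, region_path = write_results(
            self.site_results.rename(columns={"q": "q", "p": "p"}),
            self.regions.drop(columns=["site_idx"], errors="ignore"),
            prefix,
        )
        paths["sites"], paths["regions"] = site_path, region_path
        if self.z_matrix is not None:
            zp = prefix.with_suffix(prefix.suffix + ".zmatrix.tsv")
            self.z_matrix.to_csv(zp, sep="\t", float_format="%.4f")
            paths["zmatrix"] = zp
        if self.gomlom_counts is not None:
            gp = prefix.with_suffix(prefix.suffix + ".gomlom.tsv")
            self.gomlom_counts.to_csv(gp, sep="\t")
            paths["gomlom"] = gp
        return paths

    # --- plotting ------------------------------------------------------
    def plot_heatmap(self, path: str | Path) -> None:
        """Z-score heatmap with samples in dendrogram leaf order."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if self.z_matrix is None:
            raise ValueError("no signature sites to plot")
        order = self.leaf_order or list(self.z_matrix.columns)
        Z = self.z_matrix[order].to_numpy(float)
        fig, ax = plt.subplots(figsize=(8, 6))
        im = ax.imshow(Z, aspect="auto", cmap="RdBu_r", vmin=-4, vmax=4)
        ax.set_xticks(range(len(order)))
        ax.set_xticklabels(order, rotation=90, fontsize=5)
        ax.set_ylabel("signature CpGs")
        fig.colorbar(im, ax=ax, label="z (control-normalized)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    def plot_scatter(self, path: str | Path) -> None:
        """Per-sample mean z with the +/-3 SD band, scatter style."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if self.z_matrix is None:
            raise ValueError("no signature sites to plot")
        fig, ax = plt.subplots(figsize=(8, 4))
        samples = list(self.z_matrix.columns)
        means = self.z_matrix.mean(axis=0)
        colors = ["tab:red" if s in self.case_ids else "tab:gray" for s in samples]
        ax.scatter(range(len(samples)), means[samples], c=colors, s=18)
        for y in (3.0, -3.0):
            ax.axhline(y, color="red", lw=0.8, ls="--")
        ax.set_xticks(range(len(samples)))
        ax.set_xticklabels(samples, rotation=90, fontsize=5)
        ax.set_ylabel("mean z across signature CpGs")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    def plot_pca(self, path: str | Path) -> None:
        """PC1/PC2 scores colored by group, with 95% group ellipses."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib.patches import Ellipse

        if self.pca is None:
            raise ValueError("no PCA available")
        scores = self.pca["scores"]
        groups = self.model.sheet.groups.loc[scores.index]
        fig, ax = plt.subplots(figsize=(6, 5))
        for g in groups.unique():
            pts = scores.loc[groups[groups == g].index]
            ax.scatter(pts["PC1"], pts["PC2"], label=g, s=20)
        for g, e in self.pca["ellipses"].items():
            vals, vecs = np.linalg.eigh(e["cov"])
            ang = float(np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1])))
            w, h = 2 * e["radius"] * np.sqrt(np.maximum(vals[::-1], 0))
            ax.add_patch(
                Ellipse(e["center"], w, h, angle=ang, fill=False, ls="--", lw=0.8)
            )
        vr = self.pca["variance_ratio"]
        ax.set_xlabel(f"PC1 ({100 * vr[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * vr[1]:.1f}%)" if len(vr) > 1 else "PC2")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
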