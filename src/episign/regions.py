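"""CpG context annotation and region-level aggregation (islands and DMBs).

Contexts follow the standard island / shore / shelf / open-sea scheme:
a site inside an annotated CpG island is ``island``; within 2 kb of an
island edge, ``shore``; within 2-4 kb, ``shelf``; everything else,
``open_sea``.  Island assignment takes priority over shore over shelf.

Differentially methylated blocks (DMBs) are built from significant
non-island sites by single-linkage merging of neighbours with inter-site
gaps of at most ``gap`` bp (default 5 kb); the resulting block must span
5-200 kb and, at scoring time, contain at least three capture target
regions.  Region significance combines member-site p-values (Fisher by
default, Brown's correlation-corrected variant optionally), adjusts
across the joint candidate list (islands + DMBs) by Benjamini-Hochberg,
and applies the same |mean delta| > 0.20 effect rule as the site scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import RegionSet
from .sitetest import adjust_fdr

logger = logging.getLogger(__name__)

CONTEXTS = ("island", "shore", "shelf", "open_sea")

SHORE_BP = 2000
SHELF_BP = 4000


@dataclass(frozen=True)
class RegionParams:
    dmb_gap_bp: int = 5000
    dmb_min_span_bp: int = 5000
    dmb_max_span_bp: int = 200000
    min_target_regions: int = 3
    combine_method: str = "fisher"  # or "brown"
    adjusted_p_threshold: float = 0.05
    min_abs_delta: float = 0.20


def annotate_cpg_context(sites: pd.MultiIndex, islands: RegionSet) -> pd.Series:
    """Assign island / shore / shelf / open_sea to each (chrom, pos) site."""
    merged = islands.merged() if len(islands) else islands
    ctx = np.full(len(sites), "open_sea", dtype=object)
    chroms = sites.get_level_values("chrom").astype(str)
    pos = sites.get_level_values("pos").to_numpy()
    for chrom in pd.unique(chroms):
        iv = merged.intervals
        sub = iv[iv["chrom"].astype(str) == chrom]
        if len(sub) == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        sel = (chroms == chrom).to_numpy() if hasattr(chroms == chrom, "to_numpy") else np.asarray(chroms == chrom)
        p = pos[sel]
        # distance to nearest island: 0 if inside
        k = np.searchsorted(starts, p, side="right") - 1
        d_inside = np.zeros(len(p), dtype=bool)
        dist = np.full(len(p), np.inf)
        valid = k >= 0
        inside = valid & (p <= ends[np.clip(k, 0, None)])
        d_inside[inside] = True
        left = valid & ~inside
        dist[left] = p[left] - ends[k[left]]
        nxt = np.clip(k + 1, 0, len(starts) - 1)
        has_next = (k + 1) < len(starts)
        dist_next = np.where(has_next, starts[nxt] - p, np.inf)
        dist = np.minimum(dist, np.where(dist_next > 0, dist_next, np.inf))
        labels = np.where(
            d_inside,
            "island",
            np.where(dist <= SHORE_BP, "shore", np.where(dist <= SHELF_BP, "shelf", "open_sea")),
        )
        ctx[sel] = labels
    return pd.Series(ctx, index=sites, name="context")


def build_dmbs(
    sites: pd.DataFrame,
    gap: int = 5000,
    min_span: int = 5000,
    max_span: int = 200000,
) -> pd.DataFrame:
    """Merge significant non-island sites into candidate blocks.

    ``sites`` needs chrom and pos columns, pre-sorted or not; sorting is
    applied.  Consecutive same-chromosome sites with inter-site gap
    <= ``gap`` join one block (single linkage); a block is kept iff its
    span (end - start + 1) lies within [min_span, max_span].  Returns a
    frame (chrom, start, end, n_sites, site_idx) where site_idx lists the
    row labels of member sites.
    """
    if len(sites) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_sites", "site_idx"])
    s = sites.sort_values(["chrom", "pos"], kind="mergesort")
    blocks = []
    cur_chrom, cur_pos, cur_idx = None, [], []
    def flush():
        if not cur_pos:
            return
        span = cur_pos[-1] - cur_pos[0] + 1
        if min_span <= span <= max_span:
            blocks.append(
                (cur_chrom, cur_pos[0], cur_pos[-1], len(cur_pos), list(cur_idx))
            )
    for idx, r in s.iterrows():
        if cur_chrom != r["chrom"] or (cur_pos and r["pos"] - cur_pos[-1] > gap):
            flush()
            cur_chrom, cur_pos, cur_idx = r["chrom"], [], []
        cur_pos.append(int(r["pos"]))
        cur_idx.append(idx)
    flush()
    return pd.DataFrame(blocks, columns=["chrom", "start", "end", "n_sites", "site_idx"])


def combine_pvalues(
    p: np.ndarray,
    method: str = "fisher",
    correlation: np.ndarray | None = None,
) -> float:
    """Combine member p-values by Fisher's method or Brown's extension.

    Fisher: X^2 = -2 sum(ln p) against chi-square with 2k df.  Brown:
    the same statistic against a scaled chi-square whose moments are
    corrected by the pairwise covariance of the -2 ln p terms, here
    approximated from the supplied correlation matrix of the underlying
    member statistics via the Kost-McDermott polynomial
    cov = 3.263 r + 0.710 r^2 + 0.027 r^3.
    """
    p = np.asarray(p, float)
    p = p[~np.isnan(p)]
    if len(p) == 0:
        return float("nan")
    if (p <= 0).any():
        logger.warning("p-value of 0 clamped to the smallest positive float")
        p = np.maximum(p, np.finfo(float).tiny)
    x2 = -2.0 * np.log(p).sum()
    k = len(p)
    if method == "fisher" or correlation is None or k == 1:
        return float(max(stats.chi2.sf(x2, 2 * k), np.finfo(float).tiny))
    if method != "brown":
        raise ValueError(f"unknown combination method {method!r}")
    r = np.asarray(correlation, float)
    iu = np.triu_indices(k, 1)
    rij = np.clip(r[iu], -1.0, 1.0)
    cov = 3.263 * rij + 0.710 * rij**2 + 0.027 * rij**3
    mean = 2.0 * k
    var = 4.0 * k + 2.0 * cov.sum()
    if var <= 0:
        return float(max(stats.chi2.sf(x2, 2 * k), np.finfo(float).tiny))
    c = var / (2.0 * mean)
    df = 2.0 * mean**2 / var
    return float(max(stats.chi2.sf(x2 / c, df), np.finfo(float).tiny))


def score_regions(
    dmb_candidates: pd.DataFrame,
    island_candidates: pd.DataFrame,
    site_results: pd.DataFrame,
    target_regions: RegionSet | None,
    params: RegionParams | None = None,
    control_beta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score candidate DMBs and islands and apply the significance rules.

    ``island_candidates`` has the same shape as ``build_dmbs`` output
    (chrom, start, end, n_sites, site_idx) for islands containing at
    least one significant site; its site_idx may cover all tested member
    sites.  Per region the member p-values are combined, q-values
    computed jointly across the candidate list, target regions counted
    by overlap, and the retained set requires adjusted_p < 0.05,
    |mean delta| > 0.20 and (DMBs only) >= 3 target regions.

    ``control_beta`` (sites x control samples, indexed like
    site_results rows) enables Brown's correlation correction.
    """
    params = params or RegionParams()
    cands = []
    for klass, frame in (("dmb", dmb_candidates), ("island", island_candidates)):
        for _, r in frame.iterrows():
            idx = list(r["site_idx"])
            sub = site_results.loc[idx]
            sub = sub[~sub["p"].isna()]
            if len(sub) == 0:
                logger.warning(
                    "%s %s:%d-%d has no tested member sites; excluded",
                    klass, r["chrom"], r["start"], r["end"],
                )
                continue
            corr = None
            if params.combine_method == "brown" and control_beta is not None and len(sub) > 1:
                X = control_beta.loc[sub.index].to_numpy(float)
                with np.errstate(invalid="ignore"):
                    corr = np.corrcoef(np.nan_to_num(X - np.nanmean(X, axis=1, keepdims=True)))
            cp = combine_pvalues(sub["p"].to_numpy(), params.combine_method, corr)
            deltas = sub["delta_beta"].to_numpy(float)
            mean_delta = float(np.nanmean(deltas))
            if (deltas > 0).all():
                direction = "hyper"
            elif (deltas < 0).all():
                direction = "hypo"
            else:
                direction = "mixed"
            n_targets = (
                target_regions.count_overlapping(r["chrom"], int(r["start"]), int(r["end"]))
                if target_regions is not None
                else 0
            )
            cands.append(
                {
                    "chrom": r["chrom"],
                    "start": int(r["start"]),
                    "end": int(r["end"]),
                    "klass": klass,
                    "n_sites": int(len(sub)),
                    "n_target_regions": int(n_targets),
                    "combined_p": cp,
                    "mean_delta": mean_delta,
                    "direction": direction,
                    "site_idx": list(sub.index),
                }
            )
    if not cands:
        cols = ["chrom", "start", "end", "klass", "n_sites", "n_target_regions",
                "combined_p", "adjusted_p", "mean_delta", "direction", "site_idx"]
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(cands)
    out["adjusted_p"] = adjust_fdr(out["combined_p"].to_numpy())
    keep = (out["adjusted_p"] < params.adjusted_p_threshold) & (
        out["mean_delta"].abs() > params.min_abs_delta
    )
    is_dmb = out["klass"] == "dmb"
    keep &= ~is_dmb | (out["n_target_regions"] >= params.min_target_regions)
    out = out.loc[keep].sort_values(["chrom", "start", "end"], kind="mergesort")
    return out.reset_index(drop=True)


def islands_with_sites(
    site_results: pd.DataFrame, islands: RegionSet, significant_idx: pd.Index
) -> pd.DataFrame:
    """Candidate islands: those containing >= 1 significant site.

    Member sites are all tested sites inside the island (not only the
    significant ones), so the combined p-value reflects the whole island.
    Returns the build_dmbs-shaped candidate frame.
    """
    rows = []
    sig = site_results.loc[significant_idx]
    for _, isl in islands.intervals.iterrows():
        in_isl_sig = sig[
            (sig["chrom"] == isl["chrom"])
            & (sig["pos"] >= isl["start"])
            & (sig["pos"] <= isl["end"])
        ]
        if len(in_isl_sig) == 0:
            continue
        members = site_results[
            (site_results["chrom"] == isl["chrom"])
            & (site_results["pos"] >= isl["start"])
            & (site_results["pos"] <= isl["end"])
        ]
        rows.append(
            {
                "chrom": isl["chrom"],
                "start": int(isl["start"]),
                "end": int(isl["end"]),
                "n_sites": len(members),
                "site_idx": list(members.index),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "site_idx"])


def context_composition(dmps: pd.DataFrame, context: pd.Series) -> pd.Series:
    """Fraction of DMPs in each context (island, shore, shelf, open_sea).

    Fractions are rounded to 2 decimals for reporting; an empty DMP set
    returns zeros with ``attrs['empty'] = True``.
    """
    out = pd.Series(0.0, index=list(CONTEXTS))
    if len(dmps) == 0:
        out.attrs["empty"] = True
        return out
    sites = pd.MultiIndex.from_arrays([dmps["chrom"], dmps["pos"]], names=["chrom", "pos"])
    labels = context.loc[sites]
    frac = labels.value_counts(normalize=True)
    for c in CONTEXTS:
        out[c] = round(float(frac.get(c, 0.0)), 2)
    out.attrs["empty"] = False
    return out


def overlap_genes(regions: pd.DataFrame, genes: RegionSet) -> pd.Series:
    """Annotate each region row with overlapping gene names (position order)."""
    ann = []
    for _, r in regions.iterrows():
        ann.append(genes.overlapping_names(r["chrom"], int(r["start"]), int(r["end"])))
    return pd.Series(ann, index=regions.index, name="genes")
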