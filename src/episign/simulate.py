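"""Synthetic targeted-bisulfite cohorts with planted episignatures.

The generator emulates the statistical shape of a clinical methylation
discovery cohort: a large healthy-control pool (64 by default) against
small case groups (2-6 samples), with block-structured hyper- or
hypo-methylation planted at CpG islands and open-sea runs at effect
sizes of 0.2-0.4 on the beta scale.  Observed data are read counts:
coverage is negative-binomial (deep capture sequencing), methylated
counts are binomial in the latent beta, so the 10X coverage filter and
the high-coverage outlier rule both have realistic bite.

Latent betas are a convex mixture of cell-type reference methylomes
(Dirichlet-distributed blood composition), plus mild age / sex / batch
covariate effects, plus the planted case effect, plus Gaussian noise on
the beta scale, clipped to [0, 1].  Planted regions have their baseline
set to an intermediate methylation level (0.5) in every sample so that
both gain and loss effects of up to 0.4 survive clipping — disease-
responsive regions are modelled as intermediately methylated.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .confounds import CellTypeReference
from .io import BetaMatrix, RegionSet, SampleSheet

# typical healthy adult leukocyte composition (neutrophils, CD4 T, CD8 T,
# B cells, NK cells, monocytes)
BLOOD_CELL_TYPES = ("Neu", "CD4T", "CD8T", "Bcell", "NK", "Mono")
BLOOD_BASE_PROPS = (0.55, 0.15, 0.10, 0.05, 0.05, 0.10)


@dataclass(frozen=True)
class CaseGroupSpec:
    name: str
    n: int
    direction: str  # "hyper" or "hypo"
    delta: float  # effect size on the beta scale
    n_islands: int = 20  # planted CpG islands
    n_blocks: int = 5  # planted open-sea blocks

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be hyper or hypo")
        if self.n < 1:
            raise ValueError("case group must have n >= 1")
        if not 0.0 < self.delta <= 0.5:
            raise ValueError("delta outside the supported (0, 0.5] range")


@dataclass(frozen=True)
class SimulationParams:
    seed: int = 0
    chrom_lengths: tuple = (
        ("chr1", 30_000_000),
        ("chr2", 30_000_000),
        ("chr3", 25_000_000),
        ("chr4", 25_000_000),
        ("chrX", 8_000_000),
    )
    n_cpg: int = 50_000
    sex_chrom_fraction: float = 0.03  # CpGs placed on chrX (removed by QC)
    n_islands: int = 1200
    island_size_mean: float = 900.0  # bp, lognormal-ish island lengths
    island_cpg_fraction: float = 0.55  # CpGs falling inside islands
    n_controls: int = 64
    case_groups: tuple = (CaseGroupSpec("case_hyper", 4, "hyper", 0.30),)
    noise_sd: float = 0.05
    batches: tuple = ("B1", "B2")
    batch_shift: float = 0.0  # added to batch-2 samples at batch_site_fraction sites
    batch_site_fraction: float = 0.2
    age_range: tuple = (1.0, 60.0)
    age_effect: float = 0.0005  # beta per year at age_site_fraction of sites
    age_site_fraction: float = 0.10
    sex_effect: float = 0.02
    sex_site_fraction: float = 0.05
    cell_types: tuple = BLOOD_CELL_TYPES
    dirichlet_concentration: float = 60.0  # scales BLOOD_BASE_PROPS
    n_markers: int = 300
    marker_divergence: float = 0.35  # min between-type beta range at markers
    coverage_mean: float = 100.0
    coverage_dispersion: float = 10.0  # negative-binomial size parameter
    snp_mask_fraction: float = 0.005
    target_fraction: float = 0.95  # fraction of CpG clusters covered by capture targets
    n_genes: int = 400


@dataclass
class TruthRecord:
    """What was planted, for end-to-end recovery checks."""

    planted_regions: pd.DataFrame  # chrom, start, end, context, direction, delta, group
    proportions: pd.DataFrame  # sample x cell type (true mixing weights)
    batch_factor: pd.Series  # per-sample batch label

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_regions": self.planted_regions.to_dict(orient="records"),
            "proportions": self.proportions.round(6).to_dict(orient="index"),
            "batch_factor": self.batch_factor.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class Annotation:
    cpgs: pd.DataFrame  # chrom, pos
    islands: RegionSet
    targets: RegionSet
    genes: RegionSet
    snp_mask: RegionSet


def _place_islands(params: SimulationParams, rng: np.random.Generator) -> pd.DataFrame:
    lengths = dict(params.chrom_lengths)
    autosomes = [c for c in lengths if c not in ("chrX", "chrY", "X", "Y")]
    weights = np.array([lengths[c] for c in autosomes], float)
    weights /= weights.sum()
    counts = rng.multinomial(params.n_islands, weights)
    rows = []
    for chrom, n in zip(autosomes, counts):
        starts = np.sort(rng.integers(1, lengths[chrom] - 10_000, size=n))
        sizes = np.maximum(
            200, rng.lognormal(np.log(params.island_size_mean), 0.4, size=n)
        ).astype(int)
        last_end = 0
        i = 0
        for s, L in zip(starts, sizes):
            if s <= last_end + 8000:  # keep islands well separated
                continue
            e = min(s + L - 1, lengths[chrom])
            rows.append((chrom, int(s), int(e), f"isl_{chrom}_{i}"))
            last_end = e
            i += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def generate_annotation(params: SimulationParams | None = None) -> Annotation:
    """Deterministic synthetic annotation: CpGs, islands, targets, genes, SNP mask."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    lengths = dict(params.chrom_lengths)
    islands = _place_islands(params, rng)

    n_sex = int(round(params.n_cpg * params.sex_chrom_fraction))
    n_auto = params.n_cpg - n_sex
    n_in_islands = int(round(n_auto * params.island_cpg_fraction)) if len(islands) else 0
    n_open = n_auto - n_in_islands

    pos_rows = []
    if n_in_islands:
        sizes = (islands["end"] - islands["start"] + 1).to_numpy()
        alloc = rng.multinomial(n_in_islands, sizes / sizes.sum())
        for (_, isl), m in zip(islands.iterrows(), alloc):
            if m == 0:
                continue
            p = np.unique(rng.integers(isl["start"], isl["end"] + 1, size=m))
            pos_rows.extend((isl["chrom"], int(x)) for x in p)
    autosomes = [c for c in lengths if c not in ("chrX", "chrY", "X", "Y")]
    weights = np.array([lengths[c] for c in autosomes], float)
    weights /= weights.sum()
    open_alloc = rng.multinomial(n_open, weights)
    for chrom, m in zip(autosomes, open_alloc):
        p = np.unique(rng.integers(1, lengths[chrom], size=m))
        pos_rows.extend((chrom, int(x)) for x in p)
    if n_sex and "chrX" in lengths:
        p = np.unique(rng.integers(1, lengths["chrX"], size=n_sex))
        pos_rows.extend(("chrX", int(x)) for x in p)

    cpgs = (
        pd.DataFrame(pos_rows, columns=["chrom", "pos"])
        .drop_duplicates()
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    # top up duplicates lost to np.unique so the count contract holds
    deficit = params.n_cpg - len(cpgs)
    guard = 0
    while deficit > 0 and guard < 50:
        chrom = autosomes[guard % len(autosomes)]
        extra = rng.integers(1, lengths[chrom], size=deficit)
        cpgs = (
            pd.concat(
                [cpgs, pd.DataFrame({"chrom": chrom, "pos": extra})], ignore_index=True
            )
            .drop_duplicates()
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )
        deficit = params.n_cpg - len(cpgs)
        guard += 1

    island_set = RegionSet("cpg_island", islands)

    # capture targets: one interval per CpG cluster (<=150 bp spacing),
    # a random fraction of clusters retained to emulate capture dropout
    t_rows = []
    for chrom, sub in cpgs.groupby("chrom", sort=False):
        p = sub["pos"].to_numpy()
        breaks = np.where(np.diff(p) > 150)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(p) - 1]])
        for i, (a, b) in enumerate(zip(starts, ends)):
            if rng.random() > params.target_fraction:
                continue
            t_rows.append((chrom, max(1, int(p[a]) - 50), int(p[b]) + 50, f"tgt_{chrom}_{i}"))
    targets = RegionSet("target_region", pd.DataFrame(t_rows, columns=["chrom", "start", "end", "name"]))

    g_rows = []
    g_weights = weights
    g_alloc = rng.multinomial(params.n_genes, g_weights)
    for chrom, m in zip(autosomes, g_alloc):
        for i in range(m):
            s = int(rng.integers(1, lengths[chrom] - 120_000))
            L = int(rng.integers(10_000, 120_000))
            g_rows.append((chrom, s, s + L - 1, f"gene_{chrom}_{i}"))
    genes = RegionSet("gene", pd.DataFrame(g_rows, columns=["chrom", "start", "end", "name"]))

    n_snp = int(round(len(cpgs) * params.snp_mask_fraction))
    snp_idx = rng.choice(len(cpgs), size=n_snp, replace=False) if n_snp else []
    s_rows = [
        (cpgs.iloc[i]["chrom"], int(cpgs.iloc[i]["pos"]), int(cpgs.iloc[i]["pos"]), f"snp_{j}")
        for j, i in enumerate(sorted(snp_idx))
    ]
    snp_mask = RegionSet("snp_mask", pd.DataFrame(s_rows, columns=["chrom", "start", "end", "name"]))

    return Annotation(cpgs, island_set, targets, genes, snp_mask)


def generate_reference_methylomes(
    params: SimulationParams, annotation: Annotation
) -> tuple[CellTypeReference, pd.Series]:
    """Baseline methylome (bimodal: islands low, open sea high) + cell-type reference.

    Cell types share the baseline except at a designated marker subset,
    where the between-type beta range is at least ``marker_divergence``.
    Returns (reference over the markers, baseline beta per CpG).
    """
    if len(params.cell_types) < 2:
        raise ValueError("need >= 2 cell types")
    rng = np.random.default_rng(params.seed + 1)
    cpgs = annotation.cpgs
    sites = pd.MultiIndex.from_arrays([cpgs["chrom"], cpgs["pos"]], names=["chrom", "pos"])
    in_island = np.fromiter(
        (annotation.islands.overlaps_point(c, p) for c, p in zip(cpgs["chrom"], cpgs["pos"])),
        dtype=bool,
        count=len(cpgs),
    )
    base = np.where(
        in_island,
        np.clip(rng.normal(0.12, 0.04, len(cpgs)), 0.01, 0.4),
        np.clip(rng.normal(0.85, 0.05, len(cpgs)), 0.5, 0.99),
    )
    baseline = pd.Series(base, index=sites, name="baseline")

    k = len(params.cell_types)
    n_markers = min(params.n_markers, len(cpgs))
    marker_idx = np.sort(rng.choice(len(cpgs), size=n_markers, replace=False))
    profiles = np.tile(base[marker_idx][:, None], (1, k))
    if params.marker_divergence > 0:
        for i in range(n_markers):
            lo = rng.uniform(0.05, 0.9 - params.marker_divergence)
            vals = rng.uniform(lo, lo + params.marker_divergence + 0.05, size=k)
            # force the configured minimum between-type range
            j_lo, j_hi = rng.choice(k, size=2, replace=False)
            vals[j_lo] = lo
            vals[j_hi] = lo + params.marker_divergence
            profiles[i] = np.clip(vals, 0.0, 1.0)
    ref_sites = sites[marker_idx]
    reference = CellTypeReference(
        ref_sites,
        pd.DataFrame(profiles, index=ref_sites, columns=list(params.cell_types)),
    )
    return reference, baseline


def _plant_regions(
    params: SimulationParams,
    annotation: Annotation,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Choose the planted islands and open-sea blocks for each case group."""
    cpgs = annotation.cpgs
    in_island = np.fromiter(
        (annotation.islands.overlaps_point(c, p) for c, p in zip(cpgs["chrom"], cpgs["pos"])),
        dtype=bool,
        count=len(cpgs),
    )
    # islands with enough member CpGs to aggregate
    iv = annotation.islands.intervals
    island_sizes = []
    for _, isl in iv.iterrows():
        n = int(
            (
                (cpgs["chrom"] == isl["chrom"])
                & (cpgs["pos"] >= isl["start"])
                & (cpgs["pos"] <= isl["end"])
            ).sum()
        )
        island_sizes.append(n)
    eligible_islands = iv.index[np.array(island_sizes) >= 3].to_numpy()

    rows = []
    used_islands: set = set()
    for grp in params.case_groups:
        pool = [i for i in eligible_islands if i not in used_islands]
        chosen = rng.choice(pool, size=min(grp.n_islands, len(pool)), replace=False)
        used_islands.update(int(i) for i in chosen)
        for i in chosen:
            isl = iv.loc[int(i)]
            rows.append(
                (isl["chrom"], int(isl["start"]), int(isl["end"]), "island",
                 grp.direction, grp.delta, grp.name)
            )
        # open-sea blocks: runs of consecutive non-island, non-sex CpGs with
        # gaps < 5 kb spanning 8-60 kb
        auto = cpgs.loc[~in_island].copy()
        auto = auto[~auto["chrom"].astype(str).isin(["chrX", "chrY", "X", "Y"])]
        planted_blocks = 0
        attempts = 0
        taken: list[tuple[str, int, int]] = [
            (r[0], r[1], r[2]) for r in rows
        ]
        while planted_blocks < grp.n_blocks and attempts < 500:
            attempts += 1
            start_i = int(rng.integers(0, len(auto) - 30))
            sub = auto.iloc[start_i : start_i + 60]
            sub = sub[sub["chrom"] == sub["chrom"].iloc[0]]
            p = sub["pos"].to_numpy()
            if len(p) < 4:
                continue
            span_target = float(rng.uniform(9_000, 60_000))
            keep = [0]
            for j in range(1, len(p)):
                if p[j] - p[keep[-1]] > 4_999:
                    break
                keep.append(j)
                if p[j] - p[0] >= span_target:
                    break
            span = p[keep[-1]] - p[0] + 1
            if span < 8_000 or len(keep) < 4:
                continue
            chrom = sub["chrom"].iloc[0]
            s, e = int(p[0]), int(p[keep[-1]])
            if any(c == chrom and not (e < a or s > b) for c, a, b in taken):
                continue
            taken.append((chrom, s, e))
            rows.append((chrom, s, e, "open_sea", grp.direction, grp.delta, grp.name))
            planted_blocks += 1
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "context", "direction", "delta", "group"],
    )


def simulate_cohort(
    params: SimulationParams | None = None,
    annotation: Annotation | None = None,
) -> tuple[dict[str, pd.DataFrame], SampleSheet, TruthRecord, Annotation]:
    """Generate the full synthetic cohort.

    Returns (coverage tables per sample id, sample sheet, truth record,
    annotation).  Coverage tables are in the Bismark-coverage column
    layout accepted by :func:`episign.io.assemble_beta_matrix`.
    """
    params = params or SimulationParams()
    if annotation is None:
        annotation = generate_annotation(params)
    rng = np.random.default_rng(params.seed + 2)
    reference, baseline = generate_reference_methylomes(params, annotation)
    cpgs = annotation.cpgs
    n_sites = len(cpgs)
    sites = baseline.index

    # --- sample sheet -------------------------------------------------
    rows = []
    for i in range(params.n_controls):
        rows.append(
            (f"C{i + 1:02d}", "control",
             float(np.round(rng.uniform(*params.age_range), 1)),
             "M" if rng.random() < 0.5 else "F",
             params.batches[int(rng.integers(len(params.batches)))], "")
        )
    for grp in params.case_groups:
        for i in range(grp.n):
            rows.append(
                (f"{grp.name}_P{i + 1}", grp.name,
                 float(np.round(rng.uniform(*params.age_range), 1)),
                 "M" if rng.random() < 0.5 else "F",
                 params.batches[int(rng.integers(len(params.batches)))],
                 f"c.{int(rng.integers(100, 9999))}A>G")
            )
    sheet = SampleSheet(
        pd.DataFrame(rows, columns=["id", "group", "age", "sex", "batch", "variant"])
    )

    planted = _plant_regions(params, annotation, rng)

    # --- latent betas -------------------------------------------------
    base = baseline.to_numpy(float).copy()
    planted_mask_by_group: dict[str, np.ndarray] = {}
    all_planted = np.zeros(n_sites, dtype=bool)
    chrom_arr = cpgs["chrom"].to_numpy()
    pos_arr = cpgs["pos"].to_numpy()
    for grp in params.case_groups:
        mask = np.zeros(n_sites, dtype=bool)
        for _, r in planted[planted["group"] == grp.name].iterrows():
            mask |= (
                (chrom_arr == r["chrom"]) & (pos_arr >= r["start"]) & (pos_arr <= r["end"])
            )
        planted_mask_by_group[grp.name] = mask
        all_planted |= mask
    # intermediate baseline at planted regions so both directions fit in [0,1]
    base[all_planted] = 0.5

    # cell-type profiles over all sites: baseline except at markers
    k = len(params.cell_types)
    profiles = np.tile(base[:, None], (1, k))
    marker_locs = sites.get_indexer(reference.sites)
    profiles[marker_locs] = reference.profiles.to_numpy(float)

    conc = params.dirichlet_concentration * np.asarray(BLOOD_BASE_PROPS[:k])
    if k != len(BLOOD_BASE_PROPS):
        conc = np.full(k, params.dirichlet_concentration / k)
    props = rng.dirichlet(conc, size=len(sheet))
    proportions = pd.DataFrame(props, index=sheet.ids, columns=list(params.cell_types))

    age_sites = rng.random(n_sites) < params.age_site_fraction
    sex_sites = rng.random(n_sites) < params.sex_site_fraction
    batch_sites = rng.random(n_sites) < params.batch_site_fraction

    meta = sheet.frame.set_index("id")
    group_of = meta["group"]
    mean_age = meta["age"].mean()

    tables: dict[str, pd.DataFrame] = {}
    for sid in sheet.ids:
        w = proportions.loc[sid].to_numpy()
        true_beta = profiles @ w
        true_beta = true_beta + params.age_effect * (meta.loc[sid, "age"] - mean_age) * age_sites
        if meta.loc[sid, "sex"] == "M":
            true_beta = true_beta + params.sex_effect * sex_sites
        if params.batch_shift and meta.loc[sid, "batch"] == params.batches[-1]:
            true_beta = true_beta + params.batch_shift * batch_sites
        g = group_of[sid]
        if g != "control":
            grp = next(x for x in params.case_groups if x.name == g)
            signed = grp.delta if grp.direction == "hyper" else -grp.delta
            true_beta = true_beta + signed * planted_mask_by_group[g]
        true_beta = np.clip(true_beta + rng.normal(0.0, params.noise_sd, n_sites), 0.0, 1.0)

        lam = rng.gamma(
            params.coverage_dispersion,
            params.coverage_mean / params.coverage_dispersion,
            n_sites,
        )
        cov = rng.poisson(lam)
        n_meth = rng.binomial(cov, true_beta)
        n_unmeth = cov - n_meth
        with np.errstate(invalid="ignore"):
            beta_obs = np.where(cov > 0, n_meth / np.maximum(cov, 1), np.nan)
        tables[sid] = pd.DataFrame(
            {
                "chrom": chrom_arr,
                "pos": pos_arr,
                "pct_meth": 100.0 * np.nan_to_num(beta_obs),
                "n_meth": n_meth,
                "n_unmeth": n_unmeth,
                "beta": beta_obs,
            }
        )

    truth = TruthRecord(planted, proportions, meta["batch"])
    return tables, sheet, truth, annotation


def simulate_beta_matrix(
    params: SimulationParams | None = None,
) -> tuple[BetaMatrix, SampleSheet, TruthRecord, Annotation]:
    """Convenience: simulate and assemble into a BetaMatrix in one call."""
    from .io import assemble_beta_matrix

    tables, sheet, truth, annotation = simulate_cohort(params)
    return assemble_beta_matrix(tables, sheet), sheet, truth, annotation
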