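"""Reading and writing the pipeline's file formats.

Coverage files use the Bismark coverage convention: six tab-separated
columns (chrom, start, end, %methylation, methylated count, unmethylated
count) with one CpG per line and start == end.  Internally every
coordinate is 1-based inclusive; BED inputs (0-based half-open) are
converted on read and back-converted on write.  Counts are authoritative:
the beta value carried forward is always n_meth / (n_meth + n_unmeth),
never the printed percentage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

REGION_KINDS = frozenset({"cpg_island", "snp_mask", "target_region", "gene"})

SAMPLE_SHEET_REQUIRED = ("id", "group", "age", "sex", "batch")

COVERAGE_COLUMNS = ("chrom", "pos", "pct_meth", "n_meth", "n_unmeth", "beta")


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line."""


@dataclass
class SampleSheet:
    """Validated cohort sample sheet.

    The underlying frame keeps every column found in the file; the
    required ones are id, group, age, sex, batch.  A ``variant`` column
    is optional and defaults to empty strings.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in SAMPLE_SHEET_REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing required column(s): {missing}")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate sample id: {dups}")
        if len(df) == 0:
            raise ValueError("empty sample sheet")
        ages = pd.to_numeric(df["age"], errors="raise").astype(float)
        if not np.isfinite(ages).all() or (ages < 0).any():
            raise ValueError("ages must be finite and non-negative")
        df = df.copy()
        df["age"] = ages
        if "variant" not in df.columns:
            df["variant"] = ""
        df["variant"] = df["variant"].fillna("").astype(str)
        df = df.reset_index(drop=True)
        object.__setattr__(self, "frame", df)

    @property
    def ids(self) -> list[str]:
        return self.frame["id"].tolist()

    @property
    def groups(self) -> pd.Series:
        return self.frame.set_index("id")["group"]

    def samples_in_group(self, group: str) -> list[str]:
        df = self.frame
        return df.loc[df["group"] == group, "id"].tolist()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class RegionSet:
    """A set of named genomic intervals of one kind.

    Coordinates are 1-based inclusive.  ``intervals`` has columns
    chrom, start, end, name and is sorted by (chrom, start, end).
    """

    kind: str
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind: {self.kind!r}")
        df = self.intervals
        if len(df) == 0:
            df = pd.DataFrame(columns=["chrom", "start", "end", "name"])
        df = df[["chrom", "start", "end", "name"]].copy()
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] < 0).any() or (df["end"] < 0).any():
            raise ValueError("negative region coordinates")
        if (df["start"] > df["end"]).any():
            raise ValueError("region start > end after coordinate conversion")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "intervals", df)
        object.__setattr__(self, "_trees", None)

    def __len__(self) -> int:
        return len(self.intervals)

    def _build_trees(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for chrom, sub in self.intervals.groupby("chrom", sort=False):
            # half-open tree coords: [start, end+1) covers the inclusive span
            trees[str(chrom)] = IntervalTree.from_tuples(
                (int(s), int(e) + 1, str(n))
                for s, e, n in zip(sub["start"], sub["end"], sub["name"])
            )
        return trees

    @property
    def trees(self) -> dict[str, IntervalTree]:
        if getattr(self, "_trees") is None:
            object.__setattr__(self, "_trees", self._build_trees())
        return self._trees

    def overlaps_point(self, chrom: str, pos: int) -> bool:
        tree = self.trees.get(str(chrom))
        return bool(tree is not None and tree.overlaps_point(int(pos)))

    def overlapping_names(self, chrom: str, start: int, end: int) -> list[str]:
        """Names of member intervals overlapping [start, end] by >= 1 bp, in positional order."""
        tree = self.trees.get(str(chrom))
        if tree is None:
            return []
        hits = sorted(tree.overlap(int(start), int(end) + 1), key=lambda iv: (iv.begin, iv.end))
        return [iv.data for iv in hits]

    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        return len(self.overlapping_names(chrom, start, end))

    def merged(self) -> "RegionSet":
        """Union of overlapping/adjacent member intervals (names joined with ',')."""
        rows = []
        for chrom, sub in self.intervals.groupby("chrom", sort=False):
            cur = None
            for _, r in sub.iterrows():
                if cur is None:
                    cur = [chrom, r["start"], r["end"], [r["name"]]]
                elif r["start"] <= cur[2] + 1:
                    cur[2] = max(cur[2], r["end"])
                    cur[3].append(r["name"])
                else:
                    rows.append((cur[0], cur[1], cur[2], ",".join(cur[3])))
                    cur = [chrom, r["start"], r["end"], [r["name"]]]
            if cur is not None:
                rows.append((cur[0], cur[1], cur[2], ",".join(cur[3])))
        return RegionSet(self.kind, pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))


@dataclass
class BetaMatrix:
    """CpG x sample methylation fractions with a parallel coverage matrix.

    Rows are indexed by a (chrom, pos) MultiIndex, columns by sample id.
    Missing observations are NaN in both matrices; beta is additionally
    NaN wherever a QC step masked the cell.
    """

    beta: pd.DataFrame
    coverage: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.coverage.index) or not list(
            self.beta.columns
        ) == list(self.coverage.columns):
            raise ValueError("beta and coverage matrices are not aligned")
        vals = self.beta.to_numpy(float)
        ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
        if not ok.all():
            raise ValueError("beta values outside [0, 1]")

    @property
    def sites(self) -> pd.MultiIndex:
        return self.beta.index

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def n_sites(self) -> int:
        return len(self.beta)

    def subset_sites(self, mask_or_index) -> "BetaMatrix":
        return BetaMatrix(self.beta.loc[mask_or_index], self.coverage.loc[mask_or_index])

    def subset_samples(self, ids: Iterable[str]) -> "BetaMatrix":
        ids = list(ids)
        return BetaMatrix(self.beta[ids], self.coverage[ids])


def read_bismark_cov(path: str | Path) -> pd.DataFrame:
    """Read a Bismark coverage file into a per-CpG table.

    Returns a DataFrame with columns chrom, pos, pct_meth, n_meth,
    n_unmeth, beta, sorted by (chrom, pos).  Beta is recomputed from the
    counts; the percentage column is carried only for provenance.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 columns, found {len(parts)}"
                )
            chrom, start, end, pct, n_meth, n_unmeth = parts
            try:
                start_i = int(start)
                pct_f = float(pct)
                m = int(n_meth)
                u = int(n_unmeth)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if m < 0 or u < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if start_i < 1:
                raise ValueError(f"{path}:{lineno}: position must be >= 1")
            beta = m / (m + u) if (m + u) > 0 else np.nan
            rows.append((chrom, start_i, pct_f, m, u, beta))
    if not rows:
        logger.warning("empty coverage file: %s", path)
        return pd.DataFrame(columns=list(COVERAGE_COLUMNS))
    df = pd.DataFrame(rows, columns=list(COVERAGE_COLUMNS))
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_bismark_cov(table: pd.DataFrame, path: str | Path) -> None:
    """Write a coverage table back to Bismark coverage format (start == end)."""
    with open(path, "w") as fh:
        for r in table.itertuples(index=False):
            total = r.n_meth + r.n_unmeth
            pct = 100.0 * r.n_meth / total if total > 0 else 0.0
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos}\t{pct:g}\t{r.n_meth}\t{r.n_unmeth}\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a CSV or TSV sample sheet (delimiter sniffed from the header)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str, "group": str}, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return SampleSheet(df)


def read_region_bed(path: str | Path, kind: str) -> RegionSet:
    """Read a BED3+ file (0-based half-open) into a 1-based inclusive RegionSet."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: BED start >= end")
            name = parts[3] if len(parts) > 3 else f"{kind}_{lineno}"
            rows.append((chrom, start + 1, end, name))
    rs = RegionSet(kind, pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))
    if len(rs) == 0:
        logger.warning("empty BED file: %s", path)
    else:
        iv = rs.intervals
        overl = (iv.groupby("chrom")["start"].shift(-1) <= iv["end"]).fillna(False)
        if overl.any():
            logger.warning("%s: %d overlapping intervals kept as-is", path, int(overl.sum()))
    return rs


def write_region_bed(regions: RegionSet, path: str | Path) -> None:
    """Write a RegionSet as BED4 (back-converted to 0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions.intervals.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}\n")


def assemble_beta_matrix(
    tables: Mapping[str, pd.DataFrame], sheet: SampleSheet
) -> BetaMatrix:
    """Assemble per-sample coverage tables into the cohort BetaMatrix.

    The site set is the union of CpG positions across samples; a sample
    missing a site gets NaN beta and NaN coverage there.  Sample order
    follows the sheet; site order is (chrom, pos).
    """
    if len(sheet) == 0 or not tables:
        raise ValueError("empty cohort")
    unknown = set(tables) - set(sheet.ids)
    if unknown:
        raise ValueError(f"coverage table(s) for unknown sample id(s): {sorted(unknown)}")
    missing = [s for s in sheet.ids if s not in tables]
    if missing:
        raise ValueError(f"no coverage table for sample(s): {missing}")
    beta_cols = {}
    cov_cols = {}
    for sid in sheet.ids:
        t = tables[sid]
        idx = pd.MultiIndex.from_arrays([t["chrom"], t["pos"]], names=["chrom", "pos"])
        beta_cols[sid] = pd.Series(t["beta"].to_numpy(float), index=idx)
        cov_cols[sid] = pd.Series(
            (t["n_meth"] + t["n_unmeth"]).to_numpy(float), index=idx
        )
    beta = pd.DataFrame(beta_cols).sort_index()
    cov = pd.DataFrame(cov_cols).reindex(beta.index)
    beta = beta[sheet.ids]
    cov = cov[sheet.ids]
    return BetaMatrix(beta, cov)


SITE_RESULT_COLUMNS = ["chrom", "pos", "context", "delta_beta", "p", "q", "direction"]
REGION_RESULT_COLUMNS = [
    "chrom", "start", "end", "klass", "n_sites", "n_target_regions",
    "combined_p", "adjusted_p", "mean_delta", "direction",
]


def write_results(
    site_results: pd.DataFrame, regions: pd.DataFrame, prefix: str | Path
) -> tuple[Path, Path]:
    """Write the site and region result tables as TSV with fixed column order.

    Returns the two file paths (``<prefix>.sites.tsv``, ``<prefix>.regions.tsv``).
    Rows are sorted by genomic position so reruns are byte-identical.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    site_path = prefix.with_suffix(prefix.suffix + ".sites.tsv")
    region_path = prefix.with_suffix(prefix.suffix + ".regions.tsv")

    sites = site_results.copy()
    for c in SITE_RESULT_COLUMNS:
        if c not in sites.columns:
            sites[c] = np.nan
    sites = sites[SITE_RESULT_COLUMNS]
    if len(sites):
        sites = sites.sort_values(["chrom", "pos"], kind="mergesort")
    sites.to_csv(site_path, sep="\t", index=False, float_format="%.6g")

    regs = regions.copy()
    for c in REGION_RESULT_COLUMNS:
        if c not in regs.columns:
            regs[c] = np.nan
    regs = regs[REGION_RESULT_COLUMNS]
    if len(regs):
        regs = regs.sort_values(["chrom", "start", "end"], kind="mergesort")
    regs.to_csv(region_path, sep="\t", index=False, float_format="%.6g")
    return site_path, region_path
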