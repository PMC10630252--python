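import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from episign.io import RegionSet
from episign.regions import (
    RegionParams,
    annotate_cpg_context,
    build_dmbs,
    combine_pvalues,
    context_composition,
    islands_with_sites,
    overlap_genes,
    score_regions,
)


def dmb_brute_force(positions, gap, min_span, max_span):
    """Oracle: enumerate maximal runs by definition, then apply span bounds."""
    blocks = []
    if not positions:
        return blocks
    positions = sorted(positions)
    run = [positions[0]]
    for p in positions[1:]:
        if p - run[-1] <= gap:
            run.append(p)
        else:
            blocks.append(run)
            run = [p]
    blocks.append(run)
    return [
        (r[0], r[-1], len(r))
        for r in blocks
        if min_span <= r[-1] - r[0] + 1 <= max_span
    ]


def _island_set(rows):
    return RegionSet(
        "cpg_island",
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]),
    )


class TestContextAnnotation:
    def test_distance_rules(self):
        islands = _island_set([("chr1", 10_000, 12_000, "i1")])
        sites = pd.MultiIndex.from_tuples(
            [
                ("chr1", 11_000),  # inside
                ("chr1", 13_500),  # 1,500 bp away -> shore
                ("chr1", 15_000),  # 3,000 bp away -> shelf
                ("chr1", 22_000),  # 10,000 bp away -> open sea
                ("chr1", 8_500),  # 1,500 bp upstream -> shore
                ("chr2", 11_000),  # no islands on chr2
            ],
            names=["chrom", "pos"],
        )
        ctx = annotate_cpg_context(sites, islands)
        assert list(ctx) == ["island", "shore", "shelf", "open_sea", "shore", "open_sea"]

    def test_island_priority_at_boundaries(self):
        islands = _island_set([("chr1", 100, 200, "i1")])
        sites = pd.MultiIndex.from_tuples(
            [("chr1", 100), ("chr1", 200), ("chr1", 201)], names=["chrom", "pos"]
        )
        ctx = annotate_cpg_context(sites, islands)
        assert list(ctx) == ["island", "island", "shore"]


class TestDmbConstruction:
    def _frame(self, positions, chrom="chr1"):
        return pd.DataFrame({"chrom": chrom, "pos": positions})

    def test_worked_example(self):
        out = build_dmbs(self._frame([1_000, 3_000, 7_000, 20_000]))
        assert len(out) == 1
        r = out.iloc[0]
        assert (r["start"], r["end"], r["n_sites"]) == (1_000, 7_000, 3)

    def test_overlong_chain_dropped(self):
        positions = list(range(1_000, 301_000, 4_000))  # 300 kb chain
        out = build_dmbs(self._frame(positions))
        assert len(out) == 0

    def test_empty_input(self):
        assert len(build_dmbs(pd.DataFrame(columns=["chrom", "pos"]))) == 0

    @given(
        st.lists(st.integers(1, 300_000), min_size=0, max_size=20),
        st.integers(500, 10_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, positions, gap):
        positions = sorted(set(positions))
        got = build_dmbs(self._frame(positions), gap=gap)
        expected = dmb_brute_force(positions, gap, 5_000, 200_000)
        assert len(got) == len(expected)
        for (_, r), (s, e, n) in zip(got.iterrows(), expected):
            assert (r["start"], r["end"], r["n_sites"]) == (s, e, n)

    def test_blocks_disjoint_and_cover_members(self):
        rng = np.random.default_rng(0)
        positions = sorted(set(rng.integers(1, 150_000, 20).tolist()))
        out = build_dmbs(self._frame(positions), gap=4_000)
        spans = sorted((r["start"], r["end"]) for _, r in out.iterrows())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
        member = set()
        for _, r in out.iterrows():
            member |= {positions[i] for i in range(len(positions))
                       if r["start"] <= positions[i] <= r["end"]}
        oracle_members = set()
        for s, e, _ in dmb_brute_force(positions, 4_000, 5_000, 200_000):
            oracle_members |= {p for p in positions if s <= p <= e}
        assert member == oracle_members


class TestCombinePvalues:
    def test_all_ones_give_one(self):
        assert combine_pvalues(np.array([1.0, 1.0])) == pytest.approx(1.0)

    def test_fisher_hand_example(self):
        # X^2 = -2(ln .5 + ln .5) = 2.7726 on 4 df
        got = combine_pvalues(np.array([0.5, 0.5]), "fisher")
        assert got == pytest.approx(stats.chi2.sf(2.772589, 4), rel=1e-5)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(0.001, 1, size=rng.integers(2, 8))
            ours = combine_pvalues(p, "fisher")
            ref = stats.combine_pvalues(p, method="fisher").pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_brown_with_zero_correlation_equals_fisher(self):
        p = np.array([0.1, 0.3, 0.7])
        corr = np.eye(3)
        assert combine_pvalues(p, "brown", corr) == pytest.approx(
            combine_pvalues(p, "fisher"), rel=1e-9
        )

    def test_brown_with_positive_correlation_less_extreme(self):
        p = np.array([0.01, 0.01, 0.01])
        corr = np.full((3, 3), 0.8)
        np.fill_diagonal(corr, 1.0)
        assert combine_pvalues(p, "brown", corr) > combine_pvalues(p, "fisher")

    def test_zero_p_clamped(self):
        assert 0 < combine_pvalues(np.array([0.0, 0.5])) < 1

    def test_uniform_under_null(self):
        # Fisher's statistic on iid uniforms is itself uniform
        rng = np.random.default_rng(2)
        combined = [
            combine_pvalues(rng.uniform(size=4), "fisher") for _ in range(2_000)
        ]
        assert stats.kstest(combined, "uniform").pvalue > 0.01


class TestScoreRegions:
    def _sites(self, n, chrom="chr1", start=10_000, step=1_000, delta=0.3, p=1e-6):
        return pd.DataFrame(
            {
                "chrom": chrom,
                "pos": [start + i * step for i in range(n)],
                "delta_beta": delta,
                "p": p,
                "q": p * 10,
            }
        )

    def _targets(self, n, chrom="chr1", start=9_000, step=2_000):
        rows = [(chrom, start + i * step, start + i * step + 500, f"t{i}") for i in range(n)]
        return RegionSet("target_region", pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]))

    def test_dmb_with_two_targets_filtered(self):
        sites = self._sites(8)
        cands = build_dmbs(sites)
        assert len(cands) == 1
        few_targets = self._targets(2)
        out = score_regions(cands, pd.DataFrame(columns=cands.columns), sites, few_targets)
        assert len(out) == 0

    def test_dmb_with_three_targets_retained_hyper(self):
        sites = self._sites(8)
        cands = build_dmbs(sites)
        out = score_regions(cands, pd.DataFrame(columns=cands.columns), sites, self._targets(4))
        assert len(out) == 1 and out.iloc[0]["direction"] == "hyper"
        assert out.iloc[0]["n_target_regions"] >= 3

    def test_island_effect_rule(self):
        sites_strong = self._sites(4, delta=0.30)
        sites_weak = self._sites(4, delta=0.10)
        island_cand = pd.DataFrame(
            [{"chrom": "chr1", "start": 9_500, "end": 14_000, "n_sites": 4,
              "site_idx": list(range(4))}]
        )
        empty = pd.DataFrame(columns=["chrom", "start", "end", "n_sites", "site_idx"])
        kept = score_regions(empty, island_cand, sites_strong, None)
        dropped = score_regions(empty, island_cand, sites_weak, None)
        assert len(kept) == 1 and len(dropped) == 0

    def test_retained_set_monotone_in_delta_threshold(self):
        rng = np.random.default_rng(3)
        sites = self._sites(8, delta=0.0)
        sites["delta_beta"] = rng.uniform(0.15, 0.45, len(sites))
        cands = build_dmbs(sites)
        counts = []
        for thr in (0.10, 0.25, 0.40):
            params = RegionParams(min_abs_delta=thr)
            out = score_regions(cands, pd.DataFrame(columns=cands.columns), sites,
                                self._targets(5), params)
            counts.append(len(out))
        assert counts == sorted(counts, reverse=True)

    def test_mixed_direction_label(self):
        sites = self._sites(6)
        sites.loc[0, "delta_beta"] = -0.4
        cands = build_dmbs(sites)
        out = score_regions(cands, pd.DataFrame(columns=cands.columns), sites, self._targets(4),
                            RegionParams(min_abs_delta=0.1))
        assert out.iloc[0]["direction"] == "mixed"


class TestIslandCandidates:
    def test_island_with_significant_site_included_with_all_members(self):
        islands = _island_set([("chr1", 1_000, 2_000, "i1"), ("chr1", 9_000, 9_500, "i2")])
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": [1_100, 1_500, 9_200], "delta_beta": 0.3,
             "p": [1e-6, 0.5, 0.9], "q": [1e-5, 0.8, 0.95]}
        )
        cands = islands_with_sites(sites, islands, pd.Index([0]))
        assert len(cands) == 1
        assert cands.iloc[0]["n_sites"] == 2  # both tested members of i1


class TestComposition:
    def test_fraction_example(self):
        dmps = pd.DataFrame({"chrom": "chr1", "pos": [1, 2, 3, 4]})
        ctx = pd.Series(
            ["island", "island", "island", "open_sea"],
            index=pd.MultiIndex.from_tuples(
                [("chr1", 1), ("chr1", 2), ("chr1", 3), ("chr1", 4)], names=["chrom", "pos"]
            ),
        )
        comp = context_composition(dmps, ctx)
        assert comp["island"] == 0.75 and comp["open_sea"] == 0.25

    def test_empty_set_flagged(self):
        comp = context_composition(pd.DataFrame(columns=["chrom", "pos"]), pd.Series(dtype=object))
        assert comp.sum() == 0 and comp.attrs["empty"]


class TestGeneOverlap:
    def test_gene_annotation_orders_and_empties(self):
        genes = RegionSet("gene", pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 600], "end": [500, 900],
             "name": ["gA", "gB"]}
        ))
        regions = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr1"], "start": [200, 400, 5_000],
             "end": [300, 700, 6_000]}
        )
        ann = overlap_genes(regions, genes)
        assert ann[0] == ["gA"]
        assert ann[1] == ["gA", "gB"]
        assert ann[2] == []
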