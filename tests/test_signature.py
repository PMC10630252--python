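import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import linkage

from episign.signature import (
    ControlStats,
    call_gom_lom,
    hierarchical_cluster,
    normalize_to_controls,
    pca_embed,
    score_sample,
    select_nonredundant,
)

from conftest import make_beta_matrix


def _beta_frame(vals, samples=None):
    vals = np.asarray(vals, float)
    samples = samples or [f"S{i}" for i in range(vals.shape[1])]
    idx = pd.MultiIndex.from_arrays(
        [["chr1"] * len(vals), range(100, 100 + 100 * len(vals), 100)],
        names=["chrom", "pos"],
    )
    return pd.DataFrame(vals, index=idx, columns=samples)


class TestNormalization:
    def test_z_arithmetic(self):
        # controls 0.4/0.5/0.6 -> mean 0.5, sd 0.1; sample at 0.8 -> z = 3
        beta = _beta_frame([[0.8, 0.4, 0.5, 0.6]], ["P1", "C1", "C2", "C3"])
        cs, z = normalize_to_controls(beta, ["C1", "C2", "C3"])
        assert cs.mean.iloc[0] == pytest.approx(0.5)
        assert cs.sd.iloc[0] == pytest.approx(0.1)
        assert z.iloc[0]["P1"] == pytest.approx(3.0)
        assert z.iloc[0]["C2"] == pytest.approx(0.0)

    def test_control_columns_standardized(self):
        rng = np.random.default_rng(0)
        beta = _beta_frame(rng.uniform(0.2, 0.8, (50, 8)))
        ctrl = [f"S{i}" for i in range(2, 8)]
        _, z = normalize_to_controls(beta, ctrl)
        zc = z[ctrl].to_numpy()
        assert np.allclose(zc.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(zc.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_zero_control_sd_gives_missing_z(self):
        beta = _beta_frame([[0.9, 0.5, 0.5, 0.5]], ["P1", "C1", "C2", "C3"])
        _, z = normalize_to_controls(beta, ["C1", "C2", "C3"])
        assert z.iloc[0].isna().all()


class TestGomLom:
    def test_threshold_rule(self):
        z = _beta_frame([[3.5, -3.2, 2.9]], ["A", "B", "C"])
        calls, counts = call_gom_lom(z)
        assert list(calls.iloc[0]) == ["GOM", "LOM", ""]
        assert counts.loc["A", "GOM"] == 1 and counts.loc["B", "LOM"] == 1

    def test_gaussian_null_rate_matches_two_sided_tail(self):
        rng = np.random.default_rng(1)
        z = _beta_frame(rng.standard_normal((40_000, 5)))
        _, counts = call_gom_lom(z)
        rate = (counts["GOM"].sum() + counts["LOM"].sum()) / (40_000 * 5)
        expected = 2 * stats.norm.sf(3.0)  # ~0.27%
        assert rate == pytest.approx(expected, rel=0.25)

    def test_planted_hyper_case_is_gom_dominant(self, small_hyper_cohort):
        from episign.model import EpisignatureModel

        d = small_hyper_cohort
        m = EpisignatureModel(d["matrix"], d["sheet"], d["annotation"].islands,
                              d["annotation"].targets)
        r = m.fit("case_hyper")
        counts = r.gomlom_counts.loc[r.case_ids]
        assert (counts["GOM"] > 10 * np.maximum(counts["LOM"], 1)).all()


class TestClustering:
    def test_hand_computed_complete_linkage(self):
        # 1-D points 0, 1, 3: pairwise distances 1, 2, 3.
        # first merge at 1; complete linkage joins the rest at height 3.
        z = _beta_frame([[0.0, 1.0, 3.0]], ["A", "B", "C"])
        Z, order = hierarchical_cluster(z)
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(3.0)

    def test_duplicate_samples_merge_first_at_zero(self):
        z = _beta_frame(np.array([[0.5, 0.5, 2.0], [1.0, 1.0, 0.0]]), ["A", "B", "C"])
        Z, order = hierarchical_cluster(z)
        assert Z[0, 2] == pytest.approx(0.0)
        assert set(order[:2]) == {"A", "B"} or set(order[-2:]) == {"A", "B"}

    def test_two_samples_single_merge(self):
        z = _beta_frame([[0.0, 1.0]], ["A", "B"])
        Z, _ = hierarchical_cluster(z)
        assert Z.shape == (1, 4)

    def test_cases_form_one_subtree_on_planted_cohort(self, small_hyper_cohort):
        from episign.model import EpisignatureModel
        from scipy.cluster.hierarchy import fcluster

        d = small_hyper_cohort
        m = EpisignatureModel(d["matrix"], d["sheet"], d["annotation"].islands,
                              d["annotation"].targets)
        r = m.fit("case_hyper")
        Z, order = hierarchical_cluster(r.z_matrix)
        labels = fcluster(Z, t=2, criterion="maxclust")
        samples = list(r.z_matrix.columns)
        case_labels = {labels[samples.index(s)] for s in r.case_ids}
        ctrl_labels = {labels[samples.index(s)] for s in r.control_ids}
        assert len(case_labels) == 1 and case_labels.isdisjoint(ctrl_labels)


class TestPca:
    def test_centering_and_spectral_properties(self):
        rng = np.random.default_rng(2)
        beta = _beta_frame(rng.uniform(0, 1, (100, 10)))
        out = pca_embed(beta, n_components=4)
        scores = out["scores"].to_numpy()
        assert np.allclose(scores.mean(axis=0), 0, atol=1e-9)
        vr = out["variance_ratio"]
        assert vr.sum() <= 1 + 1e-9
        assert all(vr[i] >= vr[i + 1] for i in range(len(vr) - 1))

    def test_duplicate_samples_have_identical_coordinates(self):
        rng = np.random.default_rng(3)
        col = rng.uniform(0, 1, 50)
        beta = _beta_frame(np.column_stack([col, col, rng.uniform(0, 1, 50)]))
        out = pca_embed(beta)
        s = out["scores"]
        assert np.allclose(s.iloc[0], s.iloc[1], atol=1e-9)

    def test_ellipses_only_for_groups_of_three_plus(self):
        rng = np.random.default_rng(4)
        beta = _beta_frame(rng.uniform(0, 1, (60, 7)))
        groups = pd.Series(["a"] * 4 + ["b"] * 2 + ["c"], index=beta.columns)
        out = pca_embed(beta, groups=groups)
        assert set(out["ellipses"]) == {"a"}
        assert out["ellipses"]["a"]["radius"] > 0


def greedy_trace_oracle(C, cutoff):
    """Step-by-step trace of the greedy correlation-filter rule."""
    C = np.abs(np.array(C, float))
    np.fill_diagonal(C, 0.0)
    alive = list(range(len(C)))
    while len(alive) > 1:
        best = max(
            ((i, j) for i in alive for j in alive if i < j), key=lambda ij: C[ij]
        )
        if C[best] <= cutoff:
            break
        i, j = best
        mi = sum(C[i, k] for k in alive if k != i) / (len(alive) - 1)
        mj = sum(C[j, k] for k in alive if k != j) / (len(alive) - 1)
        drop = i if mi > mj else j if mj > mi else max(i, j)
        alive.remove(drop)
    return alive


class TestNonredundant:
    def test_perfectly_correlated_pair_reduced_to_one(self):
        row = np.random.default_rng(5).uniform(0, 1, 30)
        beta = _beta_frame(np.vstack([row, row]).T).T
        beta = _beta_frame(np.vstack([row, row]))
        kept = select_nonredundant(beta, cutoff=0.9)
        assert len(kept) == 1

    def test_uncorrelated_rows_all_kept(self):
        rng = np.random.default_rng(6)
        beta = _beta_frame(rng.uniform(0, 1, (5, 200)))
        kept = select_nonredundant(beta, cutoff=0.9)
        assert len(kept) == 5

    @pytest.mark.parametrize("seed", [7, 17, 27])
    def test_survivors_match_greedy_trace_oracle(self, seed):
        # two latent factors give a correlated block structure; the filter
        # must reproduce an independent step-by-step trace of the rule
        rng = np.random.default_rng(seed)
        f1, f2 = rng.standard_normal((2, 60))
        rows = np.vstack([
            f1 + 0.2 * rng.standard_normal(60),
            f1 + 0.3 * rng.standard_normal(60),
            f1 + 0.25 * rng.standard_normal(60),
            f2 + 0.2 * rng.standard_normal(60),
            f2 + 0.25 * rng.standard_normal(60),
        ])
        beta = _beta_frame(0.5 + 0.05 * rows / np.abs(rows).max())
        emp = np.corrcoef(beta.to_numpy())
        kept = select_nonredundant(beta, cutoff=0.8)
        expected = greedy_trace_oracle(emp, 0.8)
        assert [beta.index.get_loc(s) for s in kept] == expected

    def test_no_surviving_pair_above_cutoff(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal(100)
        rows = np.vstack([base + rng.standard_normal(100) * s for s in (0.1, 0.2, 1.0, 2.0)])
        beta = _beta_frame(0.5 + 0.05 * rows)
        kept = select_nonredundant(beta, cutoff=0.8)
        surv = beta.loc[kept].to_numpy()
        C = np.abs(np.corrcoef(surv))
        np.fill_diagonal(C, 0.0)
        assert C.max() <= 0.8


class TestScoreSample:
    def _stats_and_dirs(self, n=40, seed=9):
        rng = np.random.default_rng(seed)
        idx = pd.MultiIndex.from_arrays(
            [["chr1"] * n, range(100, 100 + 100 * n, 100)], names=["chrom", "pos"]
        )
        mean = pd.Series(rng.uniform(0.3, 0.7, n), index=idx)
        sd = pd.Series(np.full(n, 0.05), index=idx)
        dirs = pd.Series(rng.choice(["hyper", "hypo"], n), index=idx)
        return ControlStats(mean, sd, 20), dirs

    def test_control_like_sample_scores_near_zero(self):
        cs, dirs = self._stats_and_dirs()
        rng = np.random.default_rng(10)
        sample = cs.mean + rng.normal(0, 0.05, len(cs.mean))
        score, frac = score_sample(pd.Series(sample, index=cs.mean.index), dirs, cs)
        assert abs(score) < 0.5 and frac == 1.0

    def test_signature_matching_sample_scores_high(self):
        cs, dirs = self._stats_and_dirs()
        shift = np.where(dirs == "hyper", 0.25, -0.25)
        sample = pd.Series(cs.mean.to_numpy() + shift, index=cs.mean.index)
        score, _ = score_sample(sample, dirs, cs)
        assert score > 2

    def test_all_missing_gives_missing_score(self):
        cs, dirs = self._stats_and_dirs()
        sample = pd.Series(np.nan, index=cs.mean.index)
        score, frac = score_sample(sample, dirs, cs)
        assert np.isnan(score) and frac == 0.0
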