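import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from structcov import (
    ValidationError,
    cluster_block_values,
    compare_blocks_across_groups,
    group_covariance,
    kruskal_wallis,
    mean_block_correlation,
)
from structcov.structural_covariance import (
    ETA_SQUARED_LARGE,
    GroupCovariance,
    classify_effect,
    cluster_pairs,
    per_region_block_means,
)
from structcov.volumes_io import AtlasHierarchy

from conftest import make_volume_table


def _hierarchy(cluster_of: dict) -> AtlasHierarchy:
    table = pd.DataFrame(
        {"area": "x", "cluster": list(cluster_of.values())},
        index=pd.Index(list(cluster_of.keys()), name="region_id"),
    )
    return AtlasHierarchy(table=table)


def _cov_from_matrix(mat: np.ndarray, regions, label="g", n=10) -> GroupCovariance:
    return GroupCovariance(
        label=label,
        matrix=pd.DataFrame(mat, index=list(regions), columns=list(regions)),
        n_subjects=n,
    )


class TestGroupCovariance:
    def test_exact_collinearity(self):
        vt = make_volume_table(n_per_cell=(3, 0, 0, 0), regions=["A", "B"], seed=0)
        vt.volumes["B"] = 2 * vt.volumes["A"]
        vt.tbv = vt.volumes.sum(axis=1)
        h = _hierarchy({"A": "midbrain", "B": "midbrain"})
        cov = group_covariance(vt, h, group="control", sex="M")
        assert cov.matrix.loc["A", "B"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self):
        vt = make_volume_table(n_per_cell=(6, 0, 0, 0), regions=list("abcde"), seed=1)
        h = _hierarchy({r: "subcortical" for r in "abcde"})
        cov = group_covariance(vt, h, group="control", sex="M")
        m = cov.matrix.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert (np.abs(m) <= 1 + 1e-12).all()

    def test_independent_regions_null_mean(self):
        # independent regions, n=11: mean off-diagonal r averages ~0 over reps
        h = _hierarchy({f"r{i}": "midbrain" for i in range(9)})
        means = []
        for seed in range(200):
            vt = make_volume_table(n_per_cell=(11, 0, 0, 0),
                                   regions=[f"r{i}" for i in range(9)], seed=seed)
            cov = group_covariance(vt, h, group="control", sex="M")
            m = cov.matrix.to_numpy()
            means.append(m[np.triu_indices(9, 1)].mean())
        assert abs(np.mean(means)) < 0.1

    def test_too_few_subjects(self):
        vt = make_volume_table(n_per_cell=(2, 0, 0, 0), regions=["a", "b"], seed=0)
        h = _hierarchy({"a": "midbrain", "b": "midbrain"})
        with pytest.raises(ValidationError, match=">= 3"):
            group_covariance(vt, h, group="control", sex="M")

    def test_zero_variance_region_excluded(self):
        vt = make_volume_table(n_per_cell=(5, 0, 0, 0), regions=["a", "b", "c"], seed=2)
        vt.volumes["c"] = 7.0
        vt.tbv = vt.volumes.sum(axis=1)
        h = _hierarchy({"a": "midbrain", "b": "midbrain", "c": "midbrain"})
        with pytest.warns(UserWarning, match="zero-variance"):
            cov = group_covariance(vt, h, group="control", sex="M")
        assert cov.excluded_regions == ["c"]
        assert "c" not in cov.regions


class TestClusterBlockValues:
    def setup_method(self):
        self.h = _hierarchy({"a1": "midbrain", "a2": "midbrain", "a3": "midbrain",
                             "b1": "hippocampal", "b2": "hippocampal"})
        rng = np.random.default_rng(0)
        x = rng.standard_normal((30, 5))
        self.mat = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(self.mat, 1.0)
        self.cov = _cov_from_matrix(self.mat, ["a1", "a2", "a3", "b1", "b2"])

    def test_paper_intra_includes_diagonal_and_copies(self):
        vals = cluster_block_values(self.cov, self.h, "midbrain", "midbrain")
        assert len(vals) == 9
        assert np.sort(vals)[-3:] == pytest.approx([1, 1, 1])

    def test_unique_intra(self):
        vals = cluster_block_values(self.cov, self.h, "midbrain", "midbrain",
                                    convention="unique")
        assert len(vals) == 3

    def test_identity_block_mean(self):
        cov = _cov_from_matrix(np.eye(5), ["a1", "a2", "a3", "b1", "b2"])
        vals = cluster_block_values(cov, self.h, "midbrain", "midbrain")
        assert mean_block_correlation(vals) == pytest.approx(3 / 9)

    def test_inter_block_lengths(self):
        for convention in ("paper", "unique"):
            vals = cluster_block_values(self.cov, self.h, "midbrain", "hippocampal",
                                        convention=convention)
            assert len(vals) == 6

    def test_paper_unique_mean_identity(self):
        # paper intra mean = (k + 2*sum_upper) / k^2
        k = 3
        vals_u = cluster_block_values(self.cov, self.h, "midbrain", "midbrain",
                                      convention="unique")
        vals_p = cluster_block_values(self.cov, self.h, "midbrain", "midbrain")
        expect = (k + 2 * vals_u.sum()) / k**2
        assert vals_p.mean() == pytest.approx(expect)

    def test_relabeling_invariance(self):
        perm = ["b2", "a3", "a1", "b1", "a2"]
        idx = [["a1", "a2", "a3", "b1", "b2"].index(r) for r in perm]
        cov_p = _cov_from_matrix(self.mat[np.ix_(idx, idx)], perm)
        v1 = np.sort(cluster_block_values(self.cov, self.h, "midbrain", "hippocampal"))
        v2 = np.sort(cluster_block_values(cov_p, self.h, "midbrain", "hippocampal"))
        assert np.allclose(v1, v2)

    def test_unknown_cluster(self):
        with pytest.raises(ValidationError):
            cluster_block_values(self.cov, self.h, "midbrain", "hippocampal"[::-1])


class TestMeanBlockCorrelation:
    def test_simple_mean(self):
        assert mean_block_correlation([0.2, 0.4]) == pytest.approx(0.3)

    def test_all_equal(self):
        assert mean_block_correlation([0.17] * 5) == pytest.approx(0.17)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            mean_block_correlation([])

    def test_fisher_jensen_inequality(self):
        # arctanh is convex on (0,1): z-averaging >= raw averaging there
        rng = np.random.default_rng(0)
        for _ in range(50):
            vals = rng.uniform(0.05, 0.9, size=20)
            assert mean_block_correlation(vals, fisher=True) >= mean_block_correlation(vals) - 1e-12


def _kw_bruteforce(groups):
    """Independent oracle: H from the definition with midrank ties, no shortcuts."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average of ranks i+1..j
        i = j
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    tie = 0.0
    for v in set(pooled.tolist()):
        t = (pooled == v).sum()
        tie += t**3 - t
    denom = 1 - tie / (n**3 - n)
    return 0.0 if denom == 0 else h / denom


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        res = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert res.h_statistic == pytest.approx(27 / 7)
        assert res.eta_squared == pytest.approx(5 / 7)

    def test_identical_groups(self):
        res = kruskal_wallis([2, 2, 2], [2, 2, 2])
        assert res.h_statistic == 0.0
        assert res.eta_squared == 0.0

    def test_large_effect_threshold_strict(self):
        assert 0.15 > ETA_SQUARED_LARGE
        assert not (0.14 > ETA_SQUARED_LARGE)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            groups = [rng.integers(0, 6, size=rng.integers(3, 10)).astype(float)
                      for _ in range(rng.integers(2, 5))]
            if all(np.ptp(np.concatenate(groups)) == 0 for _ in [0]):
                continue
            mine = kruskal_wallis(*groups)
            try:
                h, p = stats.kruskal(*groups)
            except ValueError:  # all values identical
                continue
            assert mine.h_statistic == pytest.approx(h, abs=1e-10)
            assert mine.p_value == pytest.approx(p, abs=1e-10)

    def test_bruteforce_oracle_all_small_configs(self):
        # every group-size configuration with total n <= 8, values with ties
        rng = np.random.default_rng(1)
        configs = []
        for total in range(3, 9):
            for k in (2, 3):
                for sizes in itertools.combinations_with_replacement(range(1, total), k):
                    if sum(sizes) == total and total >= k + 1:
                        configs.append(sizes)
        for sizes in configs:
            for _ in range(3):
                values = rng.integers(0, 4, size=sum(sizes)).astype(float)
                if np.ptp(values) == 0:
                    continue
                groups, start = [], 0
                for s in sizes:
                    groups.append(values[start:start + s])
                    start += s
                mine = kruskal_wallis(*groups)
                assert mine.h_statistic == pytest.approx(_kw_bruteforce(groups), abs=1e-10)

    def test_eta_squared_zero_when_h_equals_km1(self):
        # eta^2 = (H - k + 1)/(n - k): exactly 0 at H = k-1, floored below
        res = kruskal_wallis([1.0, 2.0], [1.5, 2.5], [1.2, 2.2])
        assert res.eta_squared >= 0.0

    def test_permutation_p_exhaustive(self):
        res_perm = kruskal_wallis([1, 2], [3, 4], p_mode="permutation")
        # 6 assignments of ranks {1,2,3,4} into two pairs; 2 reach H_obs
        assert res_perm.p_value == pytest.approx(2 / 6)

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([1.0, 2.0], [])


class TestClassifyEffect:
    def _values(self, tm, tf, cm, cf):
        return {"treated_M": np.asarray(tm), "treated_F": np.asarray(tf),
                "control_M": np.asarray(cm), "control_F": np.asarray(cf)}

    def test_omnibus_not_passed(self):
        rng = np.random.default_rng(0)
        vals = self._values(*[rng.normal(0, 1, 50) for _ in range(4)])
        assert classify_effect(vals, omnibus_passed=False) == "none"

    def test_uniform_treatment_shift(self):
        rng = np.random.default_rng(1)
        vals = self._values(
            rng.normal(-1, 0.3, 100), rng.normal(-1, 0.3, 100),
            rng.normal(0, 0.3, 100), rng.normal(0, 0.3, 100),
        )
        assert classify_effect(vals, omnibus_passed=True) == "treatment"

    def test_male_treated_only_shift(self):
        rng = np.random.default_rng(2)
        vals = self._values(
            rng.normal(-1, 0.3, 100), rng.normal(0, 0.3, 100),
            rng.normal(0, 0.3, 100), rng.normal(0, 0.3, 100),
        )
        assert classify_effect(vals, omnibus_passed=True) == "sex_within_treated"

    def test_no_difference_none(self):
        rng = np.random.default_rng(3)
        vals = self._values(*[rng.normal(0, 1, 60) for _ in range(4)])
        assert classify_effect(vals, omnibus_passed=True) == "none"


class TestCompareBlocks:
    def test_structure_and_pair_count(self, preset_cohort, hierarchy159):
        from structcov.structural_covariance import covariance_by_cell

        vt, _, _ = preset_cohort
        covs = covariance_by_cell(vt, hierarchy159)
        with pytest.warns(UserWarning, match="convention"):
            blocks = compare_blocks_across_groups(covs, hierarchy159)
        assert len(blocks) == 21
        assert set(zip(blocks["cluster_a"], blocks["cluster_b"])) == set(cluster_pairs())
        assert (blocks["eta_squared"] >= 0).all()
        assert ((blocks["mean_r_treated_M"] <= 1) & (blocks["mean_r_treated_M"] >= -1)).all()
        # paper-convention length: intra cluster k -> k^2
        intra = blocks[(blocks.cluster_a == "posterior_cortical")
                       & (blocks.cluster_b == "posterior_cortical")]
        assert intra["block_n_per_group"].iloc[0] == 19 * 19

    def test_region_set_mismatch_errors(self, preset_cohort, hierarchy159):
        from structcov.structural_covariance import covariance_by_cell

        vt, _, _ = preset_cohort
        covs = covariance_by_cell(vt, hierarchy159)
        first = next(iter(covs))
        mat = covs[first].matrix
        covs[first] = GroupCovariance(label=first, matrix=mat.iloc[1:, 1:],
                                      n_subjects=covs[first].n_subjects)
        with pytest.raises(ValidationError, match="mismatch"):
            compare_blocks_across_groups(covs, hierarchy159)


class TestPerRegionMeans:
    def test_matches_matrix_rows(self):
        h = _hierarchy({"a1": "midbrain", "a2": "midbrain", "b1": "hippocampal"})
        mat = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.4], [0.2, 0.4, 1.0]])
        cov = _cov_from_matrix(mat, ["a1", "a2", "b1"])
        means = per_region_block_means(cov, h, "midbrain", "hippocampal")
        assert means["a1"] == pytest.approx(0.2)
        assert means["a2"] == pytest.approx(0.4)
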