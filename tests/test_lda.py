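import math

import numpy as np
import pytest
from scipy import stats

from spcprof.core import map_accessions
from spcprof.errors import ValidationError
from spcprof.lda import (
    agglomerative_coefficient,
    hierarchical_cluster,
    mahalanobis_assign,
    mahalanobis_distance,
    protein_f_ratio,
    select_lda_sps,
    selected_proteins,
)
from spcprof.simulate import SimulationConfig, simulate_dataset

from conftest import make_matrix


def anova_oracle(groups):
    """Brute-force one-way ANOVA from first-principles sums of squares."""
    allv = [v for g in groups for v in g]
    grand = sum(allv) / len(allv)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    msb, msw = ssb / df_b, ssw / df_w
    if msw == 0:
        return (0.0, 1.0) if msb == 0 else (math.inf, 0.0)
    f = msb / msw
    return f, float(stats.f.sf(f, df_b, df_w))


class TestProteinFRatio:
    def test_hand_anova_f_equals_one(self):
        # between MS 2, within MS 2
        f, p = protein_f_ratio([[0, 2], [1, 3], [2, 4]])
        assert f == pytest.approx(1.0)
        assert 0 < p < 1

    def test_identical_constant_groups(self):
        f, p = protein_f_ratio([[5, 5], [5, 5], [5, 5]])
        assert f == 0.0 and p == 1.0

    def test_zero_error_mean_square_sentinel(self):
        f, p = protein_f_ratio([[1, 1], [2, 2], [3, 3]])
        assert math.isinf(f) and p == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            protein_f_ratio([[1, 2], []])

    def test_needs_two_groups(self):
        with pytest.raises(ValidationError):
            protein_f_ratio([[1, 2, 3]])

    def test_shift_invariance(self):
        groups = [[1.0, 4.0], [2.0, 6.0], [9.0, 3.0]]
        f1, p1 = protein_f_ratio(groups)
        f2, p2 = protein_f_ratio([[v + 100 for v in g] for g in groups])
        assert f1 == pytest.approx(f2)
        assert p1 == pytest.approx(p2)

    def test_group_relabel_invariance(self):
        groups = [[1.0, 4.0], [2.0, 6.0], [9.0, 3.0]]
        f1, _ = protein_f_ratio(groups)
        f2, _ = protein_f_ratio(groups[::-1])
        assert f1 == pytest.approx(f2)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        groups = [list(rng.normal(rng.uniform(0, 5), 1.0, rng.integers(2, 6)))
                  for _ in range(int(rng.integers(2, 5)))]
        f, p = protein_f_ratio(groups)
        f_ref, p_ref = anova_oracle(groups)
        assert f == pytest.approx(f_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_f_oneway(self, seed):
        rng = np.random.default_rng(100 + seed)
        groups = [rng.normal(0, 1, 5) for _ in range(3)]
        f, p = protein_f_ratio(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(float(ref.statistic), rel=1e-12)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-12)


class TestSelectLdaSps:
    def _matrix(self, shift=50):
        data = {
            "GRP": [5, 6, 5, 5, shift, shift + 1],
            "FLAT": [10, 11, 10, 11, 10, 11],
        }
        cohorts = ["Wt", "Wt", "He", "He", "Ho", "Ho"]
        return make_matrix(data, cohorts)

    def test_planted_group_shift_selected(self):
        records = select_lda_sps(self._matrix(), collapse_by_gene=False,
                                 normalize=False)
        by_name = {r.protein: r for r in records}
        assert by_name["GRP"].selected
        assert not by_name["FLAT"].selected

    def test_infinite_threshold_selects_nothing(self):
        records = select_lda_sps(self._matrix(), f_thr=math.inf,
                                 collapse_by_gene=False, normalize=False)
        assert selected_proteins(records) == []

    def test_pure_noise_type_one_rate(self):
        # thresholds (3.4, 0.05) on pure noise select <= 7% over 20 seeds
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = {f"P{i}": list(rng.poisson(20, 6) + 1) for i in range(500)}
            m = make_matrix(data, ["Wt", "Wt", "He", "He", "Ho", "Ho"])
            records = select_lda_sps(m, collapse_by_gene=False, normalize=False)
            fractions.append(np.mean([r.selected for r in records]))
        assert np.mean(fractions) <= 0.07

    def test_agrees_with_oracle_on_small_matrices(self):
        # <= 20 x 10 matrices: F ratios match the brute-force ANOVA to 1e-10
        rng = np.random.default_rng(77)
        for _ in range(10):
            n = int(rng.integers(2, 21))
            data = {f"P{i}": list(rng.integers(0, 60, 9)) for i in range(n)}
            cohorts = ["Wt"] * 3 + ["He"] * 3 + ["Ho"] * 3
            m = make_matrix(data, cohorts)
            records = select_lda_sps(m, collapse_by_gene=False, normalize=False)
            for rec in records:
                groups = [
                    [float(v) for v in m.counts.loc[rec.protein, m.cohort_run_ids(c)]]
                    for c in ("He", "Ho", "Wt")
                ]
                f_ref, p_ref = anova_oracle(groups)
                if math.isinf(f_ref):
                    assert math.isinf(rec.f_ratio)
                else:
                    assert rec.f_ratio == pytest.approx(f_ref, rel=1e-10)
                    assert rec.p_value == pytest.approx(p_ref, rel=1e-10)

    def test_selection_rule_consistency(self, default_dataset):
        from spcprof import assemble_matrix

        runs, ann, _ = default_dataset
        m = assemble_matrix(runs)
        for rec in select_lda_sps(m, ann=ann):
            assert rec.selected == (rec.f_ratio > 3.4 and rec.p_value < 0.05)

    def test_gene_collapse_changes_keys(self, default_dataset):
        from spcprof import assemble_matrix

        runs, ann, _ = default_dataset
        m = assemble_matrix(runs)
        records = select_lda_sps(m, ann=ann, collapse_by_gene=True)
        keys = {r.protein for r in records}
        assert any(k.startswith("G") for k in keys)

    def test_cohort_with_one_run_rejected(self):
        m = make_matrix({"A": [1, 2, 3]}, ["Wt", "Wt", "He"])
        with pytest.raises(ValidationError):
            select_lda_sps(m, collapse_by_gene=False)


class TestMahalanobis:
    def test_identity_covariance_unit_distance(self):
        d = mahalanobis_distance([1.0, 0.0], [0.0, 0.0], np.eye(2))
        assert d == pytest.approx(1.0)

    def test_diagonal_covariance_hand_value(self):
        d = mahalanobis_distance([2.0, 0.0], [0.0, 0.0], np.diag([4.0, 1.0]))
        assert d == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        point, mean = rng.normal(size=2), rng.normal(size=2)
        from scipy.spatial.distance import mahalanobis as scipy_maha

        assert mahalanobis_distance(point, mean, cov) == pytest.approx(
            scipy_maha(point, mean, np.linalg.inv(cov))
        )

    def test_default_synthetic_all_runs_correct(self):
        for seed in range(5):
            cfg = SimulationConfig(n_proteins=500, frac_dep=0.08,
                                   fold_range=(2.5, 3.5), dep_mean_spc=40.0,
                                   seed=seed)
            runs, ann, _ = simulate_dataset(cfg)
            from spcprof import assemble_matrix

            m = assemble_matrix(runs)
            records = select_lda_sps(m, ann=ann)
            chosen = selected_proteins(records)
            base = map_accessions(m, ann, True)
            result = mahalanobis_assign(base.subset_proteins(chosen))
            assert result.accuracy == 1.0

    def test_shrunk_falls_back_when_singular(self, caplog):
        # more proteins than runs -> singular full covariance
        cfg = SimulationConfig(n_proteins=100, seed=3)
        runs, ann, _ = simulate_dataset(cfg)
        from spcprof import assemble_matrix

        m = assemble_matrix(runs)
        result = mahalanobis_assign(m, covariance_mode="shrunk_pooled")
        assert len(result.predicted) == 19

    def test_unknown_mode_rejected(self):
        m = make_matrix({"A": [1, 2, 3, 4]}, ["Wt", "Wt", "He", "He"])
        with pytest.raises(ValidationError):
            mahalanobis_assign(m, covariance_mode="full")


class TestHierarchicalCluster:
    def test_two_runs_single_merge(self):
        m = make_matrix({"A": [1, 10], "B": [2, 20]}, ["Wt", "Ho"])
        result = hierarchical_cluster(m, normalize=False)
        assert result.linkage_matrix.shape == (1, 4)
        cut = result.cut(2)
        assert len(set(cut.values())) == 2

    def test_three_separated_cohorts_pure_cut(self):
        for seed in range(5):
            cfg = SimulationConfig(n_proteins=400, frac_dep=0.1,
                                   fold_range=(3.0, 4.0), dep_mean_spc=50.0,
                                   seed=seed)
            runs, ann, _ = simulate_dataset(cfg)
            from spcprof import assemble_matrix

            m = assemble_matrix(runs)
            chosen = selected_proteins(select_lda_sps(m, ann=ann))
            base = map_accessions(m, ann, True)
            result = hierarchical_cluster(base.subset_proteins(chosen))
            cut = result.cut(3)
            cohort_of = {r.run_id: r.cohort for r in m.runs}
            clusters = {}
            for run_id, label in cut.items():
                clusters.setdefault(label, set()).add(cohort_of[run_id])
            assert all(len(c) == 1 for c in clusters.values())

    def test_identical_runs_zero_ac(self):
        m = make_matrix({"A": [5, 5, 5], "B": [2, 2, 2]}, ["Wt", "He", "Ho"])
        result = hierarchical_cluster(m, normalize=False)
        assert result.agglomerative_coefficient == 0.0

    def test_duplicating_runs_raises_ac(self):
        rng = np.random.default_rng(5)
        data = {f"P{i}": list(rng.integers(1, 50, 4)) for i in range(30)}
        m = make_matrix(data, ["Wt", "He", "Ho", "Ho"])
        base_ac = hierarchical_cluster(m, normalize=False).agglomerative_coefficient
        dup_data = {p: v + v for p, v in data.items()}
        m2 = make_matrix(dup_data, ["Wt", "He", "Ho", "Ho"] * 2,
                         run_ids=[f"r{i}" for i in range(8)])
        dup_ac = hierarchical_cluster(m2, normalize=False).agglomerative_coefficient
        assert dup_ac > base_ac

    def test_ac_range_and_formula(self):
        z = np.array([[0.0, 1.0, 1.0, 2.0], [2.0, 3.0, 4.0, 3.0]])
        # leaves 0,1 first merge at 1.0; leaf 2 at 4.0; final height 4.0
        expected = np.mean([1 - 1.0 / 4.0, 1 - 1.0 / 4.0, 1 - 4.0 / 4.0])
        assert agglomerative_coefficient(z) == pytest.approx(expected)

    def test_newick_export_parses(self, default_dataset):
        runs, ann, _ = default_dataset
        from spcprof import assemble_matrix

        m = assemble_matrix(runs)
        result = hierarchical_cluster(m)
        newick = result.to_newick()
        assert newick.endswith(";")
        for run_id in m.run_ids:
            assert run_id in newick

    def test_column_order_invariance(self, default_dataset):
        runs, _, _ = default_dataset
        from spcprof import assemble_matrix

        a = hierarchical_cluster(assemble_matrix(runs))
        b = hierarchical_cluster(assemble_matrix(list(reversed(runs))))
        assert a.run_ids == b.run_ids
        assert np.allclose(a.linkage_matrix, b.linkage_matrix)

    def test_heho_topology_recovered(self):
        # planted effects shared by He/Ho: the k=2 cut isolates Wt
        for seed in range(5):
            cfg = SimulationConfig(n_proteins=400, frac_dep=0.1,
                                   dep_pattern="heho", fold_range=(3.0, 4.0),
                                   dep_mean_spc=50.0, seed=seed)
            runs, ann, _ = simulate_dataset(cfg)
            from spcprof import assemble_matrix

            m = assemble_matrix(runs)
            chosen = selected_proteins(select_lda_sps(m, ann=ann))
            base = map_accessions(m, ann, True)
            result = hierarchical_cluster(base.subset_proteins(chosen))
            cut = result.cut(2)
            cohort_of = {r.run_id: r.cohort for r in m.runs}
            groups = {}
            for run_id, label in cut.items():
                groups.setdefault(label, set()).add(cohort_of[run_id])
            assert {"Wt"} in groups.values()
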