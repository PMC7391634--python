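"""QC filters, beta/M transform, deconvolution and latent covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methylmr.datatypes import CellTypeReference
from methylmr.qc import (
    CellTypeDeconvolver,
    MethylationPCA,
    SurrogateVariableEstimator,
    beta_to_m,
    compare_cell_fractions,
    estimate_cell_fractions,
    filter_probes,
    filter_samples,
    m_to_beta,
    methylation_pcs,
)

from conftest import toy_methylation


class TestFilterSamples:
    def test_high_detection_failure_sample_removed(self):
        rng = np.random.default_rng(0)
        det = np.full((100, 3), 0.001)
        det[:10, 1] = 0.5  # 10% of probes fail in sample 2
        m = toy_methylation(rng.uniform(0.1, 0.9, (100, 3)), detection_p=det)
        filtered, report = filter_samples(m, 0.01, 0.05)
        assert list(filtered.sample_ids) == ["S1", "S3"]
        assert report.samples_removed["reason"].tolist() == ["detection"]

    def test_clean_matrix_unchanged(self):
        m = toy_methylation(np.full((5, 4), 0.5))
        filtered, report = filter_samples(m)
        assert list(filtered.sample_ids) == list(m.sample_ids)
        assert report.samples_removed.empty

    def test_sex_mismatch_flag_removes_exactly_one(self):
        m = toy_methylation(np.full((5, 4), 0.5))
        filtered, report = filter_samples(m, sex_mismatch_flags=["S2"])
        assert filtered.n_samples == 3
        assert report.samples_removed.iloc[0].tolist() == ["S2", "sex_mismatch"]

    def test_removing_all_samples_is_an_error(self):
        m = toy_methylation(np.full((5, 2), 0.5))
        with pytest.raises(ValueError):
            filter_samples(m, sex_mismatch_flags=["S1", "S2"])


class TestFilterProbes:
    def _fixture(self):
        # 10 probes: 2 non-CpG (ch), 1 SNP-flagged, 1 bead-failing in 6%
        rng = np.random.default_rng(1)
        n_samples = 50
        classes = ["cg"] * 10
        classes[3], classes[4] = "ch", "ch"
        flags = [False] * 10
        flags[6] = True
        bead = np.zeros((10, n_samples), dtype=bool)
        bead[8, :3] = True  # 3/50 = 6% of samples
        return toy_methylation(
            rng.uniform(0.2, 0.8, (10, n_samples)),
            probe_class=classes, snp_flag=flags, bead_fail=bead,
        )

    def test_counts_by_construction(self):
        filtered, report = filter_probes(self._fixture())
        assert filtered.n_probes == 6
        reasons = report.probes_removed.set_index("probe_id")["reason"]
        assert (reasons == "non-CpG").sum() == 2
        assert (reasons == "SNP-associated").sum() == 1
        assert (reasons == "beads").sum() == 1

    def test_retained_set_matches_manifest_predicate_oracle(self):
        m = self._fixture()
        filtered, _ = filter_probes(m)
        bead_frac = m.bead_fail.mean(axis=1)
        det_frac = (m.detection_p > 0.01).mean(axis=1)
        expected = {
            p for p in m.probe_ids
            if bead_frac[p] < 0.05
            and m.manifest.loc[p, "probe_class"] == "cg"
            and not m.manifest.loc[p, "snp_flag"]
            and det_frac[p] < 0.05
        }
        assert set(filtered.probe_ids) == expected

    def test_clean_matrix_unchanged_and_idempotent(self):
        m = toy_methylation(np.full((8, 5), 0.4))
        once, report = filter_probes(m)
        assert list(once.probe_ids) == list(m.probe_ids)
        twice, report2 = filter_probes(once)
        pd.testing.assert_frame_equal(once.beta, twice.beta)
        assert report2.probes_removed.empty


class TestBetaMTransform:
    @pytest.mark.parametrize("beta,expected", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_reference_points(self, beta, expected):
        assert beta_to_m(beta) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(min_value=0.002, max_value=0.998))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity_inside_clip_region(self, beta):
        assert m_to_beta(beta_to_m(beta)) == pytest.approx(beta, abs=1e-12)

    def test_antisymmetry(self):
        b = np.array([0.1, 0.3, 0.45])
        np.testing.assert_allclose(beta_to_m(b), -beta_to_m(1 - b), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            beta_to_m(1.2)

    def test_clipping_bounds_extreme_values(self):
        assert beta_to_m(0.0, epsilon=1e-3) == beta_to_m(1e-3)
        assert beta_to_m(1.0, epsilon=1e-3) == beta_to_m(1 - 1e-3)


class TestDeconvolution:
    def test_pure_profile_recovers_vertex(self, cell_reference):
        beta = cell_reference.profiles[["epithelial"]].rename(
            columns={"epithelial": "S1"}
        )
        frac = CellTypeDeconvolver(cell_reference).fit(beta).fractions_
        assert frac.loc["S1", "epithelial"] == pytest.approx(1.0, abs=1e-8)
        assert frac.loc["S1"].drop("epithelial").abs().max() < 1e-8

    def test_noiseless_two_component_mixture_exact(self, cell_reference):
        mix = (0.6 * cell_reference.profiles["epithelial"]
               + 0.4 * cell_reference.profiles["fibroblast"])
        frac = CellTypeDeconvolver(cell_reference).fit(mix.to_frame("S1")).fractions_
        assert frac.loc["S1", "epithelial"] == pytest.approx(0.6, abs=1e-6)
        assert frac.loc["S1", "fibroblast"] == pytest.approx(0.4, abs=1e-6)

    def test_noisy_mixtures_recovered_within_tolerance(self, cell_reference):
        rng = np.random.default_rng(3)
        k = cell_reference.profiles.shape[1]
        true = rng.dirichlet(np.full(k, 2.0), size=100)
        obs = cell_reference.profiles.to_numpy() @ true.T
        obs = np.clip(obs + rng.normal(0, 0.02, obs.shape), 0, 1)
        beta = pd.DataFrame(obs, index=cell_reference.marker_ids,
                            columns=[f"S{i}" for i in range(100)])
        frac = CellTypeDeconvolver(cell_reference).fit(beta).fractions_
        mae = np.abs(frac.to_numpy() - true).mean()
        assert mae < 0.05

    def test_fractions_always_simplex(self, study, cell_reference):
        frac = estimate_cell_fractions(study["methylation"], cell_reference)
        assert (frac.to_numpy() >= 0).all()
        np.testing.assert_allclose(frac.sum(axis=1), 1.0, atol=1e-9)

    def test_no_shared_markers_is_an_error(self, cell_reference):
        beta = pd.DataFrame({"S1": [0.5]}, index=["cg_not_a_marker"])
        with pytest.raises(ValueError, match="marker"):
            CellTypeDeconvolver(cell_reference).fit(beta)

    def test_robust_variant_tolerates_contaminated_markers(self, cell_reference):
        mix = (0.7 * cell_reference.profiles["epithelial"]
               + 0.3 * cell_reference.profiles["neutrophil"])
        corrupted = mix.copy()
        corrupted.iloc[:2] = 0.99  # two wrecked markers
        frac = CellTypeDeconvolver(cell_reference, robust=True).fit(
            corrupted.to_frame("S1")
        ).fractions_
        assert frac.loc["S1", "epithelial"] == pytest.approx(0.7, abs=0.05)


class TestCompareCellFractions:
    def test_identical_groups_report_no_evidence(self):
        frac = pd.DataFrame({"epithelial": [0.5, 0.6, 0.5, 0.6]},
                            index=["a", "b", "c", "d"])
        res = compare_cell_fractions(frac, ["x", "x", "y", "y"])
        assert res.loc["epithelial", "p"] == 1.0

    def test_planted_shift_detected_in_most_replicates(self):
        rng = np.random.default_rng(11)
        hits = 0
        reps = 40
        for _ in range(reps):
            a = np.clip(rng.normal(0.5, 0.08, 45), 0, 1)
            b = np.clip(rng.normal(0.7, 0.08, 46), 0, 1)
            frac = pd.DataFrame({"fibroblast": np.concatenate([a, b])})
            groups = ["case"] * 45 + ["control"] * 46
            res = compare_cell_fractions(frac, groups)
            hits += res.loc["fibroblast", "p"] < 0.05
        assert hits / reps > 0.9

    def test_matches_permutation_oracle_on_toy(self):
        frac = pd.DataFrame({"ct": [0.1, 0.4, 0.2, 0.8, 0.7, 0.9]})
        groups = np.array([0, 0, 0, 1, 1, 1])
        res = compare_cell_fractions(frac, groups)
        # exact permutation distribution of the rank-sum statistic
        from itertools import combinations
        x = frac["ct"].to_numpy()
        ranks = stats.rankdata(x)
        obs = ranks[groups == 0].sum()
        perms = [sum(ranks[list(c)]) for c in combinations(range(6), 3)]
        tail = np.mean([min(p, 21 - p) <= min(obs, 21 - obs) for p in perms])
        assert res.loc["ct", "p"] == pytest.approx(tail, abs=0.05)

    def test_degenerate_group_rejected(self):
        frac = pd.DataFrame({"ct": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            compare_cell_fractions(frac, ["a", "a", "b"])


class TestSurrogateVariables:
    def test_planted_batch_effect_recovered(self):
        rng = np.random.default_rng(5)
        n, p = 60, 300
        batch = np.repeat([0, 1], n // 2)
        load = rng.normal(0, 1, p)
        data = np.outer(batch - batch.mean(), load).T * 2 + rng.normal(0, 0.1, (p, n))
        est = SurrogateVariableEstimator(n_components=1).fit(data)
        sv1 = est.surrogate_variables_["SV1"].to_numpy()
        assert abs(np.corrcoef(sv1, batch)[0, 1]) > 0.9

    def test_pure_noise_selects_zero_components(self):
        zeros = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            data = rng.normal(0, 1, (200, 40))
            est = SurrogateVariableEstimator(
                n_components="auto", n_permutations=50, random_state=seed
            ).fit(data)
            zeros += est.n_components_ == 0
        assert zeros >= 9

    def test_columns_orthogonal(self):
        rng = np.random.default_rng(7)
        data = rng.normal(0, 1, (100, 30))  # plain noise, fixed k
        est = SurrogateVariableEstimator(n_components=4).fit(data)
        gram = est.surrogate_variables_.T @ est.surrogate_variables_
        off = gram.to_numpy() - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_protected_signal_not_absorbed(self):
        # an effect aligned with the protected design must not leak into SVs
        rng = np.random.default_rng(9)
        n, p = 50, 200
        group = np.repeat([0.0, 1.0], n // 2)
        data = np.outer(group, rng.normal(0, 1, p)).T + rng.normal(0, 0.5, (p, n))
        est = SurrogateVariableEstimator(n_components=1).fit(data, group)
        sv1 = est.surrogate_variables_["SV1"].to_numpy()
        assert abs(np.corrcoef(sv1, group)[0, 1]) < 0.3

    def test_rank_deficient_design_rejected(self):
        data = np.random.default_rng(0).normal(0, 1, (20, 10))
        design = np.ones((10, 2))  # duplicate of the implicit intercept
        with pytest.raises(ValueError, match="rank"):
            SurrogateVariableEstimator(n_components=1).fit(data, design)

    def test_sample_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(13)
        data = pd.DataFrame(rng.normal(0, 1, (80, 20)),
                            columns=[f"S{i}" for i in range(20)])
        est1 = SurrogateVariableEstimator(n_components=2).fit(data)
        perm = rng.permutation(20)
        est2 = SurrogateVariableEstimator(n_components=2).fit(data.iloc[:, perm])
        a = est1.surrogate_variables_.iloc[perm].to_numpy()
        b = est2.surrogate_variables_.to_numpy()
        for j in range(2):
            assert min(np.abs(a[:, j] - b[:, j]).max(),
                       np.abs(a[:, j] + b[:, j]).max()) < 1e-8


class TestMethylationPCA:
    def test_planted_rank_one_structure_dominates(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(0, 3, 30)
        load = rng.uniform(0.2, 0.8, 100)
        data = np.outer(load, scores) * 0.05 + 0.5
        data += rng.normal(0, 1e-4, data.shape)
        est = MethylationPCA(n_components=3).fit(np.clip(data, 0, 1))
        assert est.explained_variance_ratio_[0] > 0.99

    def test_variance_explained_non_increasing(self, study):
        _, ratios = methylation_pcs(study["methylation"], 5)
        assert (np.diff(ratios) <= 1e-12).all()

    def test_agrees_with_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(4)
        data = rng.uniform(0.1, 0.9, (20, 10))  # probes x samples
        est = MethylationPCA(n_components=3).fit(data)
        centered = data.T - data.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered @ centered.T)
        order = np.argsort(evals)[::-1]
        oracle = evecs[:, order[:3]] * np.sqrt(evals[order[:3]])
        got = est.components_df_.to_numpy()
        for j in range(3):
            assert min(np.abs(got[:, j] - oracle[:, j]).max(),
                       np.abs(got[:, j] + oracle[:, j]).max()) < 1e-8

    def test_excessive_components_rejected(self):
        data = np.random.default_rng(0).uniform(0.2, 0.8, (5, 4))
        with pytest.raises(ValueError):
            MethylationPCA(n_components=4).fit(data)
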