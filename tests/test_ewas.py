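"""Association scans: closed-form agreement, calibration, inflation
control, FDR and candidate lookup."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methylmr.datatypes import QCReport
from methylmr.ewas import (
    DESIGNS,
    EwasScanner,
    bh_fdr,
    delta_beta,
    genomic_inflation,
    lookup_candidates,
    run_ewas,
    select_suggestive,
    tune_covariates,
)
from methylmr.qc import estimate_surrogate_variables
from methylmr.simulate import SimulationConfig, simulate_genotypes, simulate_methylation, simulate_outcome

from conftest import toy_methylation


def _labels(n_case, n_control):
    return pd.Series(
        [1] * n_case + [0] * n_control,
        index=[f"S{j + 1}" for j in range(n_case + n_control)],
    )


class TestEwasScanner:
    def test_matches_closed_form_two_sample_t(self):
        rng = np.random.default_rng(0)
        beta = rng.uniform(0.2, 0.8, (1, 40))
        m = toy_methylation(beta)
        y = _labels(18, 22)
        res = EwasScanner().fit(m, y).results_
        a = beta[0, :18]
        b = beta[0, 18:]
        t_ref, p_ref = stats.ttest_ind(a, b)  # equal-variance two-sample t
        assert res["t"].iloc[0] == pytest.approx(t_ref, abs=1e-10)
        assert res["p"].iloc[0] == pytest.approx(p_ref, abs=1e-10)
        assert res["effect"].iloc[0] == pytest.approx(a.mean() - b.mean(), abs=1e-12)

    def test_null_scan_is_calibrated(self):
        rng = np.random.default_rng(1)
        m = toy_methylation(np.clip(rng.normal(0.5, 0.08, (1000, 91)), 0.01, 0.99))
        res = EwasScanner().fit(m, _labels(45, 46)).results_
        frac = (res["p"] < 0.05).mean()
        assert abs(frac - 0.05) < 2.576 * np.sqrt(0.05 * 0.95 / 1000)

    def test_planted_effect_ranks_first(self):
        # 0.15 beta shift against ~0.085 beta-scale noise at n=45/46
        wins = 0
        reps = 20
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            beta = np.clip(rng.normal(0.5, 0.085, (200, 91)), 0.01, 0.99)
            beta[0, :45] = np.clip(beta[0, :45] + 0.15, 0.01, 0.99)
            res = EwasScanner().fit(toy_methylation(beta), _labels(45, 46)).results_
            wins += res.index[0] == "cg00000001"
        assert wins >= 19

    def test_constant_cpg_gets_na_and_is_excluded_from_fdr(self):
        rng = np.random.default_rng(2)
        beta = rng.uniform(0.3, 0.7, (5, 20))
        beta[2] = 0.5
        with pytest.warns(UserWarning, match="constant"):
            res = EwasScanner().fit(toy_methylation(beta), _labels(10, 10)).results_
        assert np.isnan(res.loc["cg00000003", "p"])
        assert np.isnan(res.loc["cg00000003", "q"])
        assert res["q"].notna().sum() == 4

    def test_orthogonal_covariates_leave_scan_unchanged(self):
        rng = np.random.default_rng(3)
        beta = rng.uniform(0.3, 0.7, (20, 40))
        m = toy_methylation(beta)
        y = _labels(20, 20)
        plain = EwasScanner().fit(m, y).results_
        # covariate orthogonal to both the intercept and the group label
        cov = np.tile([1.0, -1.0], 20)
        cov = pd.DataFrame({"c": cov - cov.mean()}, index=y.index)
        adjusted = EwasScanner(covariates=cov).fit(m, y).results_
        np.testing.assert_allclose(
            plain["effect"].sort_index(), adjusted["effect"].sort_index(), atol=1e-10
        )

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(4)
        beta = rng.uniform(0.3, 0.7, (15, 30))
        m = toy_methylation(beta)
        y = _labels(15, 15)
        res1 = EwasScanner().fit(m, y).results_
        perm = rng.permutation(30)
        m2 = m.subset_samples(m.sample_ids[perm])
        res2 = EwasScanner().fit(m2, y).results_
        np.testing.assert_allclose(
            res1["p"].sort_index(), res2["p"].sort_index(), atol=1e-12
        )

    def test_rank_deficient_covariates_rejected(self):
        m = toy_methylation(np.random.default_rng(0).uniform(0.3, 0.7, (5, 10)))
        y = _labels(5, 5)
        cov = pd.DataFrame({"dup": y.to_numpy()}, index=y.index)
        with pytest.raises(ValueError, match="rank"):
            EwasScanner(covariates=cov).fit(m, y)


class TestDeltaBeta:
    @pytest.mark.parametrize(
        "case,comparison,expected_diff,expected_pct",
        [
            (0.591, 0.748, 0.157, 15.7),   # largest case-control difference
            (0.392, 0.506, 0.114, 11.4),
            (0.552, 0.592, 0.040, 4.0),    # chordee
            (0.745, 0.708, -0.037, 3.7),   # chordee, case-hypermethylated
            (0.814, 0.747, -0.067, 6.7),   # severity
        ],
    )
    def test_published_group_mean_arithmetic(self, case, comparison,
                                             expected_diff, expected_pct):
        diff, pct = delta_beta(case, comparison)
        assert diff == pytest.approx(expected_diff, abs=1e-12)
        assert round(pct, 1) == expected_pct

    def test_equal_means_give_zero(self):
        assert delta_beta(0.4, 0.4) == (0.0, 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            delta_beta(1.2, 0.5)


class TestGenomicInflation:
    def test_single_null_median_p_gives_unity(self):
        assert genomic_inflation([0.5]) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_pvalues_give_unity(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 100_000)
        assert genomic_inflation(p) == pytest.approx(1.0, abs=0.02)

    def test_doubled_chi_squares_double_lambda(self):
        rng = np.random.default_rng(7)
        chi2 = stats.chi2.rvs(1, size=50_000, random_state=rng)
        p = stats.chi2.sf(2 * chi2, 1)
        assert genomic_inflation(p) == pytest.approx(2.0, abs=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            genomic_inflation([])


class TestBhFdr:
    @staticmethod
    def brute_force_bh(p):
        """Quadratic-time textbook BH: q_i = min over j with p_j >= p_i of
        p_j * m / rank_j."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        for pos, i in enumerate(order):
            candidates = [
                p[order[k]] * m / (k + 1) for k in range(pos, m)
            ]
            q[i] = min(min(candidates), 1.0)
        return q

    def test_hand_computed_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037, abs=1e-15)

    def test_equals_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), self.brute_force_bh(p), atol=1e-12)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0, 1, 50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestTuneCovariates:
    def _batched_study(self, seed=42):
        g = simulate_genotypes(91, 8, seed=seed)
        cfg = SimulationConfig(
            n_cases=45, n_controls=46, n_chordee=21, n_severe=9,
            n_cpgs=400, n_variants_per_chrom=8,
            batch_sd=1.0, batch_case_confounding=0.85, seed=seed,
        )
        matrix, truth = simulate_methylation(g, cfg)
        pheno = simulate_outcome(truth, cfg)
        # regenerate measurements with batch aligned to realized labels
        matrix, truth = simulate_methylation(
            g, cfg, case_mask=pheno["case"].to_numpy().astype(bool), seed=cfg.seed
        )
        cpgs = matrix.manifest[matrix.manifest["chrom"] != "M"].index
        return matrix.subset_probes(cpgs), pheno

    def test_batch_confounding_inflates_and_svs_restore(self):
        matrix, pheno = self._batched_study()
        unadjusted = run_ewas(matrix, pheno, "hypospadias")
        assert unadjusted.attrs["lambda"] > 1.5
        # unprotected SVs: under the global null the batch direction is
        # recoverable without shielding the (confounded) case label
        svs = estimate_surrogate_variables(
            matrix, None, k="auto", n_permutations=50, random_state=0
        )
        assert svs.shape[1] >= 1
        name, chosen, trace = tune_covariates(
            matrix, pheno, "hypospadias", [("none", None), ("svs", svs)]
        )
        assert name == "svs"
        chosen_lambda = trace.set_index("candidate").loc["svs", "lambda"]
        # residual inflation scales with SV estimation error at this
        # small probe count; the tighter bound lives in the larger fixture
        assert abs(chosen_lambda - 1.0) < 0.3

    def test_single_candidate_returned_unchanged(self, study):
        matrix = study["methylation"]
        cpgs = matrix.manifest[matrix.manifest["chrom"] != "M"].index
        matrix = matrix.subset_probes(cpgs)
        name, chosen, trace = tune_covariates(
            matrix, study["phenotypes"], "hypospadias", [("only", None)]
        )
        assert name == "only" and chosen is None and len(trace) == 1

    def test_tie_broken_toward_fewer_covariates(self, monkeypatch):
        import methylmr.ewas as ewas_mod

        lambdas = {"big": 1.07, "small": 1.07}
        calls = []

        def fake_run(m, pheno, design, covariates=None):
            name = "big" if covariates is not None and covariates.shape[1] == 3 else "small"
            calls.append(name)
            res = pd.DataFrame({"p": [0.5]})
            res.attrs["lambda"] = lambdas[name]
            return res

        monkeypatch.setattr(ewas_mod, "run_ewas", fake_run)
        idx = [f"S{i}" for i in range(4)]
        big = pd.DataFrame(np.eye(4, 3), index=idx)
        small = pd.DataFrame(np.eye(4, 1), index=idx)
        name, chosen, _ = ewas_mod.tune_covariates(
            None, None, "hypospadias", [("big", big), ("small", small)]
        )
        assert name == "small"


class TestSuggestiveSelection:
    def _fake_results(self, qs, design="hypospadias"):
        res = pd.DataFrame(
            {
                "p": np.asarray(qs) / 2,
                "q": qs,
                "effect": 0.1,
                "case_mean": 0.5,
                "comparison_mean": 0.6,
                "delta_beta": 0.1,
            },
            index=pd.Index([f"cg{i:08d}" for i in range(1, len(qs) + 1)], name="cpg"),
        )
        res.attrs["fdr_threshold"] = DESIGNS[design].fdr_threshold
        return res

    def test_all_above_threshold_yields_empty(self):
        out = select_suggestive({"hypospadias": self._fake_results([0.5, 0.9])})
        assert out.empty

    def test_planted_subthreshold_cpgs_selected(self):
        out = select_suggestive(
            {"hypospadias": self._fake_results([0.01, 0.19, 0.05, 0.5, 0.21])}
        )
        assert len(out) == 3

    def test_design_specific_thresholds(self):
        q = [0.17, 0.5]
        both = select_suggestive(
            {"hypospadias": self._fake_results(q),
             "chordee": self._fake_results(q, "chordee")}
        )
        # 0.17 passes the 0.20 case-control threshold, not the 0.15 case-only
        assert both["design"].tolist() == ["hypospadias"]

    def test_deduplicated_by_cpg_design_pair(self):
        res = self._fake_results([0.01])
        out = select_suggestive({"hypospadias": pd.concat([res, res])})
        assert len(out) == 1


class TestLookupCandidates:
    def test_statuses_partition_candidates(self):
        # 14 external candidates: 2 absent from the platform, 5 failing QC,
        # 7 tested in the scan
        all_cpgs = [f"cg_qc{i}" for i in range(5)] + [f"cg_ok{i}" for i in range(7)]
        manifest = pd.DataFrame(
            {"chrom": "1", "pos": range(1, 13), "probe_class": "cg",
             "snp_flag": False},
            index=pd.Index(all_cpgs, name="probe_id"),
        )
        results = pd.DataFrame(
            {"effect": 0.1, "p": 0.5},
            index=pd.Index([f"cg_ok{i}" for i in range(7)], name="cpg"),
        )
        qc = QCReport(
            probes_removed=pd.DataFrame(
                {"probe_id": [f"cg_qc{i}" for i in range(5)],
                 "reason": "detection"}
            )
        )
        candidates = [f"cg_absent{i}" for i in range(2)] + all_cpgs
        table = lookup_candidates(results, candidates, manifest, qc)
        counts = table["status"].value_counts()
        assert counts["absent_from_array"] == 2
        assert counts["failed_qc"] == 5
        assert counts["tested"] == 7
        assert table.loc[table["status"] == "tested", "p"].notna().all()

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            lookup_candidates(pd.DataFrame(), [], pd.DataFrame())
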