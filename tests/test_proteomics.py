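"""Spectral-count workflow: filters, VSN, imputation, DE, overlaps."""


import numpy as np
import pandas as pd
import pytest

from mixtox.errors import ValidationError
from mixtox.proteomics import (
    IMPUTED_KNN,
    IMPUTED_QRILC,
    OBSERVED,
    ProteinMatrix,
    aggregate_peptides,
    bh_adjust,
    de_test,
    filter_min_peptides,
    filter_replicate_presence,
    impute_mixed,
    overlap_analysis,
    spectral_index,
    vsn_normalize,
)
from mixtox.synthetic import (
    PeptideCountMatrix,
    ProteomeSimConfig,
    generate_spectral_counts,
    inject_missingness,
)


def _protein_matrix(values, conditions=("ctl", "trt"), reps=3):
    samples = [f"{c}_r{r}" for c in conditions for r in range(1, reps + 1)]
    vals = pd.DataFrame(values, columns=samples)
    vals.index = [f"prot{i}" for i in range(len(vals))]
    design = pd.DataFrame(
        {
            "sample": samples,
            "condition": [c for c in conditions for _ in range(reps)],
            "biorep": list(range(1, reps + 1)) * len(conditions),
        }
    )
    n_pep = pd.Series(3, index=vals.index)
    return ProteinMatrix(vals, n_pep, design)


class TestPeptideFilter:
    def test_three_peptide_rule_on_toy_matrix(self, toy_peptide_matrix):
        out, audit = filter_min_peptides(toy_peptide_matrix, min_peptides=3)
        surviving = set(out.protein_map.unique())
        assert surviving == {"prot3", "prot4", "prot5"}
        assert audit.set_index("protein")["kept"].to_dict() == {
            "prot1": False, "prot2": False, "prot3": True, "prot4": True, "prot5": True,
        }

    def test_matrix_with_all_proteins_passing_is_unchanged(self, toy_peptide_matrix):
        out, _ = filter_min_peptides(toy_peptide_matrix, min_peptides=1)
        pd.testing.assert_frame_equal(out.counts, toy_peptide_matrix.counts)

    def test_empty_result_warns(self, toy_peptide_matrix):
        with pytest.warns(UserWarning, match="empty"):
            out, _ = filter_min_peptides(toy_peptide_matrix, min_peptides=10)
        assert out.counts.empty


class TestAggregation:
    def _mini(self, cells):
        counts = pd.DataFrame(cells, index=["p1", "p2"], columns=["s1", "s2"])
        pmap = pd.Series(["P", "P"], index=["p1", "p2"])
        design = pd.DataFrame(
            {"sample": ["s1", "s2"], "condition": ["c", "c"], "biorep": [1, 2]}
        )
        return PeptideCountMatrix(counts, pmap, design)

    def test_scaled_sum_of_observed_peptides(self):
        pm = aggregate_peptides(self._mini([[4, 4], [6, np.nan]]))
        assert pm.values.loc["P", "s1"] == 5  # (4+6)/2
        assert pm.values.loc["P", "s2"] == 4  # missing excluded from sum and divisor

    def test_cell_missing_only_when_all_peptides_missing(self):
        pm = aggregate_peptides(self._mini([[np.nan, np.nan], [np.nan, 3]]))
        assert np.isnan(pm.values.loc["P", "s1"])
        assert pm.values.loc["P", "s2"] == 3

    def test_aggregation_conserves_total_counts(self):
        cfg = ProteomeSimConfig(n_proteins=100, mcar_rate=0.1, seed=2)
        mtx, _ = generate_spectral_counts(cfg)
        pm = aggregate_peptides(mtx)
        n_obs = mtx.counts.notna().groupby(mtx.protein_map).sum()
        recon = (pm.values * n_obs).sum()
        expected = mtx.counts.sum()
        pd.testing.assert_series_equal(recon, expected, check_names=False)


class TestReplicatePresence:
    def test_protein_absent_everywhere_removed(self):
        vals = [[1, 2, np.nan, 1, np.nan, 3],  # 2 reps in each condition
                [1, 2, 3, np.nan, np.nan, np.nan]]  # all 3 in ctl only
        pm = _protein_matrix(vals)
        out = filter_replicate_presence(pm, min_bioreps=3)
        assert list(out.values.index) == ["prot1"]

    def test_zero_counts_do_not_count_as_presence(self):
        pm = _protein_matrix([[0, 0, 0, 1, 2, 3]])
        out = filter_replicate_presence(pm, min_bioreps=3)
        assert len(out.values) == 1  # present in all trt replicates
        out2 = filter_replicate_presence(_protein_matrix([[0, 0, 0, 1, 2, 0]]), 3)
        assert len(out2.values) == 0

    def test_empty_matrix_warns(self):
        pm = _protein_matrix([[np.nan] * 6])
        with pytest.warns(UserWarning):
            out = filter_replicate_presence(pm, min_bioreps=3)
        assert len(out.values) == 0


class TestVsn:
    def test_identical_samples_map_identically(self):
        col = [3.0, 10.0, 50.0, 7.0]
        pm = _protein_matrix(np.column_stack([col] * 6))
        out = vsn_normalize(pm)
        for s in out.values.columns[1:]:
            pd.testing.assert_series_equal(
                out.values[s], out.values[out.values.columns[0]], check_names=False
            )

    def test_transform_preserves_within_sample_ranks(self):
        rng = np.random.default_rng(0)
        pm = _protein_matrix(rng.gamma(2, 10, size=(50, 6)))
        out = vsn_normalize(pm)
        for s in pm.values.columns:
            before = pm.values[s].rank()
            after = out.values[s].rank()
            pd.testing.assert_series_equal(before, after)

    def test_reduces_sd_mean_dependence(self):
        # multiplicative + additive noise: SD grows with mean before glog
        rng = np.random.default_rng(1)
        base = np.exp(rng.normal(3, 1.5, size=300))
        mult = np.exp(rng.normal(0, 0.4, size=(300, 8)))
        add = rng.normal(0, 2.0, size=(300, 8))
        x = np.clip(base[:, None] * mult + add, 0.01, None)
        pm = _protein_matrix(x, conditions=("a", "b"), reps=4)
        out = vsn_normalize(pm)
        from scipy.stats import spearmanr

        rho_before = abs(spearmanr(x.mean(1), x.std(1, ddof=1)).statistic)
        t = out.values.to_numpy()
        rho_after = abs(spearmanr(t.mean(1), t.std(1, ddof=1)).statistic)
        assert rho_after < rho_before

    def test_missing_cells_untouched(self):
        vals = np.array([[1.0, 2, 3, 4, 5, 6], [np.nan, 2, 3, 4, 5, 6]])
        out = vsn_normalize(_protein_matrix(vals))
        assert np.isnan(out.values.iloc[1, 0])

    def test_all_missing_sample_rejected(self):
        vals = np.array([[np.nan, 2, 3, 4, 5, 6], [np.nan, 2, 3, 4, 5, 6]])
        with pytest.raises(ValidationError):
            vsn_normalize(_protein_matrix(vals))


def _masked_matrix(seed, n_prot=150, mcar=0.15):
    """VSN-scale matrix with MCAR holes plus fully-censored condition blocks."""
    cfg = ProteomeSimConfig(n_proteins=n_prot, seed=seed)
    mtx, _ = generate_spectral_counts(cfg)
    f, _ = filter_min_peptides(mtx)
    pm = filter_replicate_presence(aggregate_peptides(f))
    pm = vsn_normalize(pm)
    rng = np.random.default_rng(seed + 1)
    vals = pm.values.to_numpy().copy()
    truth = vals.copy()
    mask = rng.random(vals.shape) < mcar
    # knock out a few whole condition blocks -> QRILC territory
    for i in rng.choice(len(vals), size=min(5, len(vals)), replace=False):
        mask[i, :3] = True
    vals[mask] = np.nan
    out = pm.copy()
    out.values = pd.DataFrame(vals, index=pm.values.index, columns=pm.values.columns)
    out.provenance = pd.DataFrame(
        np.where(np.isnan(vals), "missing", "observed"),
        index=pm.values.index, columns=pm.values.columns,
    )
    return out, truth, mask


class TestImputation:
    def test_complete_matrix_unchanged(self):
        pm = _protein_matrix(np.arange(24.0).reshape(4, 6) + 1)
        out = impute_mixed(pm, k=2, seed=0)
        pd.testing.assert_frame_equal(out.values, pm.values)
        assert (out.provenance.to_numpy() == OBSERVED).all()

    def test_observed_cells_never_altered_and_flags_partition(self):
        pm, _, mask = _masked_matrix(seed=0)
        out = impute_mixed(pm, k=5, seed=1)
        obs = pm.values.notna().to_numpy()
        assert np.array_equal(
            out.values.to_numpy()[obs], pm.values.to_numpy()[obs]
        )
        prov = out.provenance.to_numpy()
        was_missing = pm.values.isna().to_numpy()
        assert set(prov[was_missing]) <= {IMPUTED_KNN, IMPUTED_QRILC}
        assert (prov[~was_missing] == OBSERVED).all()
        assert not out.values.isna().any().any()

    def test_qrilc_values_below_censoring_quantile(self):
        pm, _, _ = _masked_matrix(seed=3)
        q = 0.05
        out = impute_mixed(pm, k=5, qrilc_quantile=q, seed=2)
        for j, s in enumerate(out.values.columns):
            flags = out.provenance[s]
            imputed = out.values.loc[flags == IMPUTED_QRILC, s]
            if imputed.empty:
                continue
            observed = pm.values[s].dropna()
            assert (imputed <= np.quantile(observed, q) + 1e-12).all()

    def test_knn_beats_column_mean_on_mcar(self):
        wins = 0
        n_seeds = 8
        for seed in range(n_seeds):
            pm, truth, _ = _masked_matrix(seed=seed)
            out = impute_mixed(pm, k=5, seed=seed)
            knn_mask = (out.provenance == IMPUTED_KNN).to_numpy()
            if not knn_mask.any():
                continue
            col_mean = np.nanmean(pm.values.to_numpy(), axis=0)
            est = out.values.to_numpy()[knn_mask]
            naive = np.broadcast_to(col_mean, pm.values.shape)[knn_mask]
            true = truth[knn_mask]
            rmse_knn = np.sqrt(np.mean((est - true) ** 2))
            rmse_naive = np.sqrt(np.mean((naive - true) ** 2))
            if rmse_knn < rmse_naive:
                wins += 1
        assert wins >= 0.75 * n_seeds

    def test_reproducible_given_seed(self):
        pm, _, _ = _masked_matrix(seed=5)
        o1 = impute_mixed(pm, k=5, seed=9)
        o2 = impute_mixed(pm, k=5, seed=9)
        pd.testing.assert_frame_equal(o1.values, o2.values)


class TestSpectralIndex:
    def test_single_protein_gets_full_weight(self):
        pm = _protein_matrix([[3.0] * 6])
        si = spectral_index(pm)
        assert (si.to_numpy() == 1.0).all()

    def test_proportions(self):
        pm = _protein_matrix([[3.0] * 6, [1.0] * 6])
        si = spectral_index(pm)
        assert np.allclose(si.iloc[0], 0.75) and np.allclose(si.iloc[1], 0.25)

    def test_scale_invariance_and_unit_sum(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2, 5, size=(20, 6))
        si1 = spectral_index(_protein_matrix(vals))
        scaled = vals.copy()
        scaled[:, 0] *= 7.0
        si2 = spectral_index(_protein_matrix(scaled))
        assert np.allclose(si1.to_numpy(), si2.to_numpy())
        assert np.allclose(si1.sum(axis=0), 1.0)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValidationError):
            spectral_index(_protein_matrix([[0.0] * 6]))


class TestDeTest:
    def test_identical_conditions_null_result(self):
        pm = _protein_matrix([[5.0, 6, 7, 5, 6, 7], [9.0, 9, 9, 9, 9, 9]])
        res = de_test(pm, ("ctl", "trt"))
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["pvalue"], 1.0)

    def test_all_zero_protein_excluded(self):
        pm = _protein_matrix([[0.0] * 6, [5.0, 6, 7, 20, 21, 22]])
        res = de_test(pm, ("ctl", "trt")).set_index("protein")
        assert not res.loc["prot0", "tested"]
        assert res.loc["prot1", "tested"]

    def test_direction_follows_fold_change(self):
        pm = _protein_matrix(
            [[5.0, 6, 7, 20, 21, 22], [20.0, 21, 22, 5, 6, 7], [8, 9, 10, 8, 9, 10]]
        )
        res = de_test(pm, ("ctl", "trt"))
        # library-size offsets shift the per-protein rates, but the extremes keep sign
        assert res.loc[0, "log2fc"] > 0 and res.loc[0, "direction"] == "up"
        assert res.loc[1, "log2fc"] < 0 and res.loc[1, "direction"] == "down"

    def test_agrees_with_statsmodels_glm_oracle(self):
        # independent route: per-protein Poisson GLM with offset via statsmodels
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        vals = rng.poisson(20, size=(6, 6)).astype(float)
        pm = _protein_matrix(vals)
        prior_df = 4.0
        res = de_test(pm, ("ctl", "trt"), prior_df=prior_df)
        totals = vals.sum(axis=0)
        x = sm.add_constant(np.array([0, 0, 0, 1, 1, 1], dtype=float))
        deltas, resid = [], []
        for i in range(len(vals)):
            fit = sm.GLM(
                vals[i], x, family=sm.families.Poisson(), offset=np.log(totals)
            ).fit()
            null = sm.GLM(
                vals[i], x[:, :1], family=sm.families.Poisson(), offset=np.log(totals)
            ).fit()
            lfc = fit.params[1] / np.log(2)
            assert res.loc[i, "log2fc"] == pytest.approx(lfc, abs=1e-6)
            deltas.append(null.deviance - fit.deviance)
            resid.append(fit.deviance)
        # quasi-F with median-squeezed dispersion, reconstructed from the
        # statsmodels deviances
        phi = np.array(resid) / 4.0
        phi0 = np.median(phi[phi > 0])
        phi_sq = (prior_df * phi0 + 4.0 * phi) / (prior_df + 4.0)
        for i in range(len(vals)):
            f_oracle = deltas[i] / phi_sq[i]
            assert res.loc[i, "statistic"] == pytest.approx(f_oracle, rel=1e-6)

    def test_requires_two_replicates(self):
        pm = _protein_matrix([[1.0, 2]], conditions=("ctl", "trt"), reps=1)
        with pytest.raises(ValidationError):
            de_test(pm, ("ctl", "trt"))

    def test_null_type_one_error_controlled(self):
        fracs = []
        for seed in range(5):
            cfg = ProteomeSimConfig(n_proteins=600, frac_de=0.0, dispersion=0.1, seed=seed)
            mtx, _ = generate_spectral_counts(cfg)
            f, _ = filter_min_peptides(mtx)
            pm = filter_replicate_presence(aggregate_peptides(f))
            res = de_test(pm, ("control", "treated"))
            sub = res[res["tested"]]
            fracs.append((sub["pvalue"] < 0.05).mean())
        assert 0.02 < np.mean(fracs) < 0.09


class TestBh:
    def test_step_up_arithmetic(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_step_up(self, rng):
        # oracle: direct step-up computation q_(i) = min_{j>=i} p_(j) * m / j
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            order = np.argsort(p)
            m = len(p)
            ranked = p[order] * m / np.arange(1, m + 1)
            oracle_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
            oracle = np.empty(m)
            oracle[order] = np.minimum(oracle_sorted, 1.0)
            assert np.allclose(bh_adjust(p), oracle)

    def test_monotone_in_p_rank(self, rng):
        p = rng.random(25)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestOverlap:
    def test_disjoint_and_identical(self):
        res = overlap_analysis({"a": {1, 2}, "b": {3, 4}})
        assert res["pairwise_percent"]["a&b"] == 0.0
        res2 = overlap_analysis({"a": {1, 2}, "b": {1, 2}})
        assert res2["pairwise_percent"]["a&b"] == 100.0

    def test_three_set_enumeration(self):
        sets = {"x": {"a", "b", "c"}, "y": {"b", "c", "d"}, "z": {"c", "d", "e"}}
        res = overlap_analysis(sets)
        assert res["regions"]["x&y&z"] == 1  # {c}
        assert res["union_size"] == 5
        assert res["all_sets_percent"] == pytest.approx(20.0)
        assert res["regions"]["x"] == 1  # {a}
        assert res["regions"]["x&y"] == 1  # {b}

    def test_region_counts_partition_union(self, rng):
        sets = {
            n: set(rng.choice(30, size=rng.integers(5, 15), replace=False))
            for n in "abc"
        }
        res = overlap_analysis(sets)
        assert sum(res["regions"].values()) == res["union_size"]

    def test_requires_two_sets(self):
        with pytest.raises(ValidationError):
            overlap_analysis({"a": {1}})
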