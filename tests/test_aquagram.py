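import numpy as np
import pandas as pd
import pytest

from aquaspec import (CompositionTable, SpectraSet, anova_per_wamac,
                      aquagram_pca, bh_adjust, compute_aquagram,
                      composition_correlation, default_cannabis_config,
                      default_registry, planted_correlation_config,
                      simulate_spectraset, wamacs_correlation_matrix,
                      average_replicates, crop_wavelengths)
from aquaspec.aquagram import AquagramError

WL = np.arange(1300, 1601, 2.0)


def _flat_set(values_at_c5, group):
    """Spectra whose absorbance at every wavelength is affine in a single
    per-sample scalar (a C5-centred band plus a broad offset), so each WAMAC
    column is a linear rescaling of that scalar."""
    X = []
    for v in values_at_c5:
        X.append(0.5 + v * (np.exp(-0.5 * ((WL - 1412) / 8) ** 2) + 0.1)
                 + 0.05 * np.sin((WL - 1300) / 40))
    meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(values_at_c5))],
                         "chemovar": group})
    return SpectraSet(WL, np.vstack(X), pd.DataFrame(meta))


class TestComputeAquagram:
    def test_identical_samples_degenerate_sigma(self):
        s = _flat_set([0.2, 0.2, 0.2, 0.2], ["a", "a", "b", "b"])
        with pytest.raises(AquagramError, match="σλ = 0"):
            compute_aquagram(s, "chemovar", apply_msc=False)

    def test_two_symmetric_groups_give_plus_minus_one(self):
        # groups at +d and -d around the global mean standardize to exactly ±1
        s = _flat_set([0.3, 0.3, 0.1, 0.1], ["hi", "hi", "lo", "lo"])
        a = compute_aquagram(s, "chemovar", apply_msc=False)
        assert a.values.loc["hi", "C5"] == pytest.approx(1.0, rel=1e-9)
        assert a.values.loc["lo", "C5"] == pytest.approx(-1.0, rel=1e-9)

    def test_classic_mode_weighted_group_mean_zero(self, default_spectra):
        a = compute_aquagram(default_spectra, "chemovar")
        weighted = a.values.mul(a.n, axis=0).sum() / a.n.sum()
        assert np.abs(weighted).max() < 1e-10

    def test_literal_mode_all_zero_with_warning(self, default_spectra):
        with pytest.warns(UserWarning, match="identically zero"):
            a = compute_aquagram(default_spectra, "major_class",
                                 mode="per_group_literal")
        assert np.abs(a.values.to_numpy()).max() < 1e-10

    def test_positive_scaling_invariance(self, default_spectra):
        a1 = compute_aquagram(default_spectra, "major_class")
        scaled = default_spectra.with_absorbance(3.0 * default_spectra.absorbance)
        a2 = compute_aquagram(scaled, "major_class")
        np.testing.assert_allclose(a1.values, a2.values, atol=1e-8)

    def test_offset_invariance(self, default_spectra):
        a1 = compute_aquagram(default_spectra, "major_class")
        shifted = default_spectra.with_absorbance(default_spectra.absorbance + 0.7)
        a2 = compute_aquagram(shifted, "major_class")
        np.testing.assert_allclose(a1.values, a2.values, atol=1e-8)

    def test_planted_c5_amplitude_tops_aquagram(self, default_spectra):
        # the default design plants the strongest free-water band in 621-17
        a = compute_aquagram(default_spectra, "chemovar")
        assert a.values["C5"].idxmax() == "621-17"

    def test_wavelengths_used_on_grid(self, default_spectra):
        a = compute_aquagram(default_spectra, "chemovar")
        assert set(a.wavelengths_used) <= set(default_spectra.wavelengths)
        assert list(a.values.columns) == default_registry().labels


class TestPca:
    def test_three_groups_two_nontrivial_pcs(self, default_spectra):
        a = compute_aquagram(default_spectra, "major_class")
        pca = aquagram_pca(a)
        assert pca.explained[:2].sum() == pytest.approx(100.0, abs=1e-8)

    def test_loadings_orthonormal_and_reconstruction(self, default_spectra):
        a = compute_aquagram(default_spectra, "chemovar")
        pca = aquagram_pca(a)
        L = pca.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        M = a.values.to_numpy()
        recon = pca.scores.to_numpy() @ L.T + M.mean(axis=0)
        np.testing.assert_allclose(recon, M, atol=1e-10)

    def test_duplicate_groups_identical_scores(self):
        vals = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 12)),
                            index=["a", "b", "c"],
                            columns=default_registry().labels)
        vals.loc["c"] = vals.loc["a"]
        a_dup = _aquagram_from_values(vals)
        pca = aquagram_pca(a_dup)
        np.testing.assert_allclose(pca.scores.loc["a"], pca.scores.loc["c"],
                                   atol=1e-10)

    def test_column_permutation_invariance_of_explained(self, default_spectra):
        a = compute_aquagram(default_spectra, "chemovar")
        perm = a.values[np.random.default_rng(1).permutation(a.values.columns)]
        p1 = aquagram_pca(a)
        p2 = aquagram_pca(_aquagram_from_values(perm))
        np.testing.assert_allclose(p1.explained, p2.explained, atol=1e-8)


def _aquagram_from_values(vals):
    from aquaspec.aquagram import AquagramResult
    n = pd.Series(1, index=vals.index)
    return AquagramResult(level="chemovar", mode="classic_dataset", values=vals,
                          wavelengths_used=pd.Series(dtype=float),
                          mu=pd.Series(dtype=float), sigma=pd.Series(dtype=float),
                          n=n, sample_values=vals, sample_groups=pd.Series(vals.index))


class TestCorrelations:
    def test_negated_column_r_minus_one(self, default_spectra):
        a = compute_aquagram(default_spectra, "chemovar")
        vals = a.values.copy()
        vals["C2"] = -vals["C1"]
        cm = wamacs_correlation_matrix(_aquagram_from_values(vals))
        assert cm.r.loc["C1", "C2"] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(cm.r), 1.0)
        np.testing.assert_allclose(cm.r, cm.r.T, atol=1e-12)

    def test_proportional_analyte_r_one(self, default_spectra):
        a = compute_aquagram(default_spectra, "chemovar")
        comp = CompositionTable(pd.DataFrame(
            {"x": (a.values["C5"] - a.values["C5"].min() + 0.1)},
            index=a.values.index))
        cm = composition_correlation(a, comp)
        assert cm.r.loc["C5", "x"] == pytest.approx(1.0)
        assert (cm.n == 7).all().all()

    def test_constant_analyte_reported_missing(self, default_spectra):
        a = compute_aquagram(default_spectra, "chemovar")
        comp = CompositionTable(pd.DataFrame({"x": np.ones(7)},
                                             index=a.values.index))
        cm = composition_correlation(a, comp)
        assert cm.r["x"].isna().all()

    def test_unmatched_chemovars_rejected(self, default_spectra):
        a = compute_aquagram(default_spectra, "chemovar")
        comp = CompositionTable(pd.DataFrame({"x": [1.0, 2.0, 3.0]},
                                             index=["a", "b", "c"]))
        with pytest.raises(AquagramError, match="missing"):
            composition_correlation(a, comp)

    def test_planted_coupling_recovered(self):
        cfg = default_cannabis_config(seed=11)
        cfg = planted_correlation_config(cfg, "CBGA", "C5", -0.8)
        cfg = planted_correlation_config(cfg, "CBGA", "C12", +0.8)
        s, comp, _ = simulate_spectraset(cfg)
        sa = crop_wavelengths(average_replicates(s), 1300, 1600)
        a = compute_aquagram(sa, "chemovar")
        cm = composition_correlation(a, comp)
        assert cm.r.loc["C5", "CBGA"] < -0.5
        assert cm.r.loc["C12", "CBGA"] > 0.5

    def test_solvation_band_cluster_positively_correlated(self, default_spectra):
        # C2-C4 amplitudes co-vary across chemovars by design (solvation factor)
        a = compute_aquagram(default_spectra, "chemovar")
        cm = wamacs_correlation_matrix(a)
        assert cm.r.loc["C2", "C3"] > 0.8
        assert cm.r.loc["C3", "C4"] > 0.8


class TestAnova:
    def test_identical_group_means_f_small(self, rng):
        vals = pd.DataFrame(rng.standard_normal((60, 2)), columns=["C1", "C2"])
        groups = pd.Series(["a", "b", "c"] * 20)
        out = anova_per_wamac(vals, groups)
        assert (out["p"] > 0.001).all()

    def test_two_groups_f_equals_t_squared(self, rng):
        x = rng.standard_normal(12)
        y = rng.standard_normal(10) + 0.8
        vals = pd.DataFrame({"C1": np.concatenate([x, y])})
        groups = pd.Series(["a"] * 12 + ["b"] * 10)
        out = anova_per_wamac(vals, groups)
        from scipy.stats import ttest_ind
        t = ttest_ind(x, y, equal_var=True)
        assert out.loc["C1", "F"] == pytest.approx(t.statistic ** 2, rel=1e-10)
        assert out.loc["C1", "p"] == pytest.approx(t.pvalue, rel=1e-10)

    def test_singleton_group_excluded_with_warning(self, rng):
        vals = pd.DataFrame({"C1": rng.standard_normal(7)})
        groups = pd.Series(["a", "a", "a", "b", "b", "b", "c"])
        with pytest.warns(UserWarning, match="excluded"):
            out = anova_per_wamac(vals, groups)
        assert np.isfinite(out.loc["C1", "F"])

    def test_default_design_separates_groups(self, default_spectra):
        a = compute_aquagram(default_spectra, "chemovar")
        out = anova_per_wamac(a.sample_values, a.sample_groups)
        assert (out["p"] < 0.05).sum() >= 10  # planted group structure


def test_bh_adjustment_monotone_and_bounded(rng):
    p = pd.Series(rng.uniform(size=12))
    adj = bh_adjust(p)
    assert (adj <= 1).all() and (adj >= p - 1e-12).all()
    order = p.sort_values().index
    assert adj[order].cummax().iloc[-1] == adj[order].iloc[-1]
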