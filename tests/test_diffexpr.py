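"""NB Wald testing: normalisation, dispersion, calibration, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sporoseq import diffexpr as de
from sporoseq import simulate as sim


def make_cm(counts: np.ndarray, timepoints) -> de.CountMatrix:
    cols = [f"s{j}" for j in range(counts.shape[1])]
    cdf = pd.DataFrame(counts, columns=cols,
                       index=[f"t{i}" for i in range(counts.shape[0])])
    cdf.index.name = "transcript_id"
    samples = pd.DataFrame(
        {"sample_id": cols, "experiment": "e", "strain": "s",
         "timepoint_h": list(timepoints)}
    )
    return de.CountMatrix(counts=cdf, samples=samples)


TP8 = [0, 0, 0, 6, 6, 6, 10, 10]


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 1000, size=50)
        cm = make_cm(np.tile(col[:, None], (1, 8)), TP8)
        np.testing.assert_allclose(de.size_factors(cm).to_numpy(), 1.0)

    def test_doubled_column_closed_form(self):
        """10x4 hand matrix: doubling one column doubles its factor ratio."""
        rng = np.random.default_rng(1)
        base = rng.integers(10, 500, size=(10, 1))
        mat = np.tile(base, (1, 4))
        mat[:, 3] *= 2
        cm = make_cm(mat, [0, 0, 6, 6])
        f = de.size_factors(cm)
        np.testing.assert_allclose(f.iloc[3] / f.iloc[0], 2.0)
        np.testing.assert_allclose(f.iloc[:3], f.iloc[0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_geometric_mean_is_one(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.integers(1, 2000, size=(30, 8))
        f = de.size_factors(make_cm(mat, TP8)).to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-10)

    def test_all_zero_reference_falls_back_to_totals(self, caplog):
        rng = np.random.default_rng(2)
        mat = rng.integers(0, 5, size=(20, 8))
        mat[:10, :4] = 0  # ensure no all-nonzero transcript
        mat[10:, 4:] = 0
        mat[0, :] = [0, 1, 2, 3, 4, 5, 6, 7]
        with caplog.at_level("WARNING"):
            f = de.size_factors(make_cm(mat, TP8))
        assert "falling back" in caplog.text
        assert (f > 0).all()


class TestDispersion:
    @staticmethod
    def _sim(disp_intercept, disp_slope, n=2000, reps=50, seed=3):
        design = (("e", "s", 0, reps), ("e", "s", 6, 2), ("e", "s", 10, 2))
        params = sim.CountScenarioParams(
            n_transcripts=n, frac_de=0, disp_intercept=disp_intercept,
            disp_slope=disp_slope, design=design, seed=seed,
            baseline_mean_range=(200.0, 2000.0), library_size_range=(1e6, 1e6),
        )
        counts, samples, _ = sim.generate_counts(
            [f"t{i}" for i in range(n)], params
        )
        return de.CountMatrix(counts=counts, samples=samples)

    def test_poisson_counts_give_near_zero_dispersion(self):
        cm = self._sim(1e-8, 0.0)
        est = de.estimate_dispersion(cm)
        assert est["dispersion"].median() <= 0.01

    def test_nb_dispersion_point_two_recovered(self):
        cm = self._sim(0.2, 0.0)
        est = de.estimate_dispersion(cm)
        assert 0.15 <= est["dispersion"].median() <= 0.25

    def test_constant_counts_hit_floor(self):
        mat = np.full((5, 8), 100)
        est = de.estimate_dispersion(make_cm(mat, TP8))
        assert (est["genewise"] == de.DISPERSION_FLOOR).all()

    def test_all_zero_transcript_flagged_untestable(self):
        rng = np.random.default_rng(4)
        mat = rng.integers(50, 200, size=(10, 8))
        mat[3, :] = 0
        cm = make_cm(mat, TP8)
        est = de.estimate_dispersion(cm)
        assert np.isnan(est["dispersion"].iloc[3])
        res = de.nb_wald_test(cm, (0, 6))
        assert not res["testable"].iloc[3]
        assert np.isnan(res["pvalue"].iloc[3])


class TestWaldTest:
    def test_contrast_antisymmetry(self, count_scenario):
        counts, samples, _ = count_scenario
        cm = de.CountMatrix(counts=counts, samples=samples)
        f = de.size_factors(cm)
        d = de.estimate_dispersion(cm, f)["dispersion"]
        fwd = de.nb_wald_test(cm, (0, 6), f, d)
        bwd = de.nb_wald_test(cm, (6, 0), f, d)
        np.testing.assert_allclose(
            fwd["log2fc"].to_numpy(), -bwd["log2fc"].to_numpy(), atol=1e-12
        )
        np.testing.assert_allclose(
            fwd["pvalue"].to_numpy(), bwd["pvalue"].to_numpy(), atol=1e-12
        )

    def test_low_count_filter_flags_not_drops(self):
        rng = np.random.default_rng(5)
        mat = rng.integers(100, 300, size=(10, 8))
        mat[2, :] = [1, 0, 0, 1, 0, 0, 1, 0]  # total 3 < 10
        cm = make_cm(mat, TP8)
        res = de.nb_wald_test(cm, (0, 10))
        assert len(res) == 10  # flagged, still present
        assert not res["testable"].iloc[2]

    def test_null_pvalues_roughly_uniform(self):
        params = sim.CountScenarioParams(n_transcripts=3000, frac_de=0, seed=6)
        counts, samples, _ = sim.generate_counts(
            [f"t{i}" for i in range(3000)], params
        )
        cm = de.CountMatrix(counts=counts, samples=samples)
        res = de.nb_wald_test(cm, (0, 10))
        pv = res["pvalue"].dropna()
        # coarse uniformity: deciles populated within a factor of two
        hist, _ = np.histogram(pv, bins=10, range=(0, 1))
        assert hist.min() > len(pv) / 20


class TestMaxIntervalAssignment:
    @staticmethod
    def results_from(pvals, lfcs):
        rows = []
        labels = [de.contrast_label(c) for c in de.CONTRASTS]
        for tid, (ps, fs) in enumerate(zip(pvals, lfcs)):
            for lab, p, f in zip(labels, ps, fs):
                rows.append(
                    {"transcript_id": f"t{tid}", "contrast": lab, "log2fc": f,
                     "se": 0.1, "pvalue": p, "testable": True}
                )
        return pd.DataFrame(rows).set_index("transcript_id")

    def test_no_significant_contrast_excluded(self):
        res = self.results_from([(0.5, 0.5, 0.5)], [(1.0, 1.0, 1.0)])
        assert len(de.max_interval_assignment(res)) == 0

    def test_max_abs_lfc_wins_with_direction(self):
        res = self.results_from([(0.01, 0.001, 0.02)], [(1.0, -2.0, 0.5)])
        tab = de.max_interval_assignment(res)
        assert tab.loc["t0", "best_contrast"] == "6-10h"
        assert tab.loc["t0", "direction"] == "down"
        assert tab.loc["t0", "log2fc"] == -2.0

    def test_only_significant_contrasts_compete(self):
        # largest |lfc| is not significant; the significant one wins
        res = self.results_from([(0.01, 0.5, 0.5)], [(1.0, -5.0, 4.0)])
        tab = de.max_interval_assignment(res)
        assert tab.loc["t0", "best_contrast"] == "0-6h"

    def test_tie_broken_by_contrast_order(self):
        res = self.results_from([(0.01, 0.01, 0.01)], [(2.0, -2.0, 2.0)])
        tab = de.max_interval_assignment(res)
        assert tab.loc["t0", "best_contrast"] == "0-6h"

    def test_alpha_monotonicity(self, count_scenario):
        counts, samples, _ = count_scenario
        cm = de.CountMatrix(counts=counts, samples=samples)
        res = de.run_contrasts(cm)
        sets = [
            set(de.max_interval_assignment(res, de.DEParams(alpha=a)).index)
            for a in (0.005, 0.025, 0.1)
        ]
        assert sets[0] <= sets[1] <= sets[2]

    def test_bh_adjustment_shrinks_de_set(self, count_scenario):
        counts, samples, _ = count_scenario
        cm = de.CountMatrix(counts=counts, samples=samples)
        res = de.run_contrasts(cm)
        raw = de.max_interval_assignment(res, de.DEParams(adjust="none"))
        adj = de.max_interval_assignment(res, de.DEParams(adjust="BH"))
        assert set(adj.index) <= set(raw.index)


class TestFoldChange:
    @pytest.mark.parametrize(
        "lfc,expected",
        [(9.19, 584), (-6.23, 75), (6.23, 75), (0.59, 1.5), (-0.62, 1.5), (0.0, 1.0)],
    )
    def test_printed_conversions(self, lfc, expected):
        assert de.fold_change(lfc) == expected

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            de.fold_change(float("nan"))


class TestPCA:
    def test_identical_samples_identical_coordinates(self):
        rng = np.random.default_rng(7)
        col = rng.integers(1, 500, size=100)
        mat = np.tile(col[:, None], (1, 8))
        mat[:, 6:] = rng.integers(1, 500, size=(100, 2))
        coords, _ = de.pca_samples(make_cm(mat, TP8))
        np.testing.assert_allclose(
            coords.iloc[0].to_numpy(), coords.iloc[1].to_numpy(), atol=1e-8
        )

    def test_projection_variance_bounded(self, count_scenario):
        counts, samples, _ = count_scenario
        cm = de.CountMatrix(counts=counts, samples=samples)
        coords, var_frac = de.pca_samples(cm)
        factors = de.size_factors(cm)
        x = np.log2(counts.to_numpy() / factors.to_numpy() + 1.0)
        xt = x.T - x.T.mean(axis=0)
        assert coords.to_numpy().var(ddof=1) * 2 <= xt.var() * xt.shape[1] + 1e-9
        assert 0 < var_frac.sum() <= 1.0 + 1e-12

    def test_time_effect_orders_samples(self, count_scenario):
        from scipy import stats

        counts, samples, _ = count_scenario
        cm = de.CountMatrix(counts=counts, samples=samples)
        coords, _ = de.pca_samples(cm)
        tp = cm.timepoints.to_numpy()
        rho = max(
            abs(stats.spearmanr(coords["PC1"], tp).statistic),
            abs(stats.spearmanr(coords["PC2"], tp).statistic),
        )
        assert rho > 0.9

    def test_deterministic_sign_convention(self, count_scenario):
        counts, samples, _ = count_scenario
        cm = de.CountMatrix(counts=counts, samples=samples)
        c1, _ = de.pca_samples(cm)
        c2, _ = de.pca_samples(cm)
        pd.testing.assert_frame_equal(c1, c2)

    def test_requires_three_samples(self):
        mat = np.random.default_rng(8).integers(1, 100, size=(20, 2))
        cm = make_cm(mat, [0, 0])
        with pytest.raises(ValueError):
            de.pca_samples(cm)
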