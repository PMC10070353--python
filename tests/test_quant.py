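"""Impurity correction, ratio computation, aggregation and normalization."""

import numpy as np
import pytest

from psmkit import quant
from psmkit.types import PlexDesign, QuantMatrix
from tests.conftest import make_psm


def random_impurity(rng, design):
    rows = {
        ch: tuple(np.round(rng.uniform(0, 4, 4), 2)) for ch in design.channels
    }
    return quant.build_impurity_matrix(rows, design)


class TestBuildImpurityMatrix:
    def test_zero_impurities_give_identity(self, tmt10_design):
        rows = {ch: (0, 0, 0, 0) for ch in tmt10_design.channels}
        m = quant.build_impurity_matrix(rows, tmt10_design)
        np.testing.assert_array_equal(m.matrix, np.eye(10))

    def test_three_channel_plus_one(self):
        design = PlexDesign("p", ("a", "b", "c"))
        rows = {"a": (0, 0, 5.0, 0), "b": (0, 0, 0, 0), "c": (0, 0, 0, 0)}
        m = quant.build_impurity_matrix(rows, design)
        np.testing.assert_allclose(m.matrix[:, 0], [0.95, 0.05, 0.0])
        np.testing.assert_allclose(m.matrix[:, 1], [0, 1, 0])

    def test_column_sums_conserve_in_plex_mass(self, rng, tmt10_design):
        """Column sum equals 1 minus the out-of-plex spill."""
        rows = {
            ch: tuple(np.round(rng.uniform(0, 3, 4), 2))
            for ch in tmt10_design.channels
        }
        m = quant.build_impurity_matrix(rows, tmt10_design)
        for j, ch in enumerate(tmt10_design.channels):
            spill = sum(
                pct / 100
                for off, pct in zip(quant.COA_OFFSETS, rows[ch])
                if not (0 <= j + off < 10)
            )
            assert m.matrix[:, j].sum() == pytest.approx(1 - spill)

    def test_excessive_impurity_errors(self, tmt10_design):
        rows = {ch: (0, 0, 0, 0) for ch in tmt10_design.channels}
        rows["126"] = (30, 30, 30, 30)
        with pytest.raises(ValueError, match=">= 100%"):
            quant.build_impurity_matrix(rows, tmt10_design)


class TestCorrectReporters:
    def test_identity_matrix_is_noop(self, tmt10_design):
        rows = {ch: (0, 0, 0, 0) for ch in tmt10_design.channels}
        m = quant.build_impurity_matrix(rows, tmt10_design)
        observed = np.arange(10.0) * 100
        corrected, clamped = quant.correct_reporters(observed, m)
        np.testing.assert_allclose(corrected, observed)
        assert not clamped

    def test_forward_mix_round_trip(self, rng, tmt10_design):
        """Correcting a forward-mixed vector recovers the truth exactly."""
        m = random_impurity(rng, tmt10_design)
        for _ in range(20):
            x = rng.uniform(10, 1e6, 10)
            corrected, clamped = quant.correct_reporters(m.matrix @ x, m)
            np.testing.assert_allclose(corrected, x, rtol=1e-10)
            assert not clamped

    def test_cramer_matches_generic_solver(self, rng):
        """Cramer's-rule solution equals numpy.linalg.solve on random
        diagonally dominant systems."""
        for n in (10, 16):
            for _ in range(10):
                m = rng.uniform(0, 0.05, (n, n))
                np.fill_diagonal(m, rng.uniform(0.85, 1.0, n))
                m /= np.maximum(m.sum(axis=0), 1.0)
                impurity = quant.ImpurityMatrix(
                    tuple(str(i) for i in range(n)), m
                )
                observed = rng.uniform(0, 1e5, n)
                expected = np.linalg.solve(m, observed)
                corrected, _ = quant.correct_reporters(observed, impurity)
                np.testing.assert_allclose(
                    corrected, np.maximum(expected, 0), rtol=1e-9, atol=1e-9
                )

    def test_conservation_for_closed_matrix(self, rng):
        """Column-stochastic impurities conserve total signal."""
        design = PlexDesign("p", tuple("abcde"))
        m = np.eye(5) * 0.9
        for j in range(5):
            m[(j + 1) % 5, j] = 0.1  # wrap spill: columns sum to 1
        impurity = quant.ImpurityMatrix(design.channels, m)
        x = rng.uniform(1, 100, 5)
        corrected, _ = quant.correct_reporters(x, impurity)
        assert corrected.sum() == pytest.approx(x.sum(), rel=1e-9)


class TestPsmQuantFilter:
    def test_boundary_values_usable(self):
        psm = make_psm(tmt_labeled=True, purity_pct=50.0, delta_fr_score=0.0)
        assert quant.psm_quant_filter(psm)

    @pytest.mark.parametrize(
        "overrides",
        [dict(purity_pct=49.9), dict(delta_fr_score=-0.1),
         dict(tmt_labeled=False)],
    )
    def test_exclusions(self, overrides):
        assert not quant.psm_quant_filter(make_psm(**overrides))


class TestPsmLogRatios:
    def test_equal_channels_zero_under_both_policies(self):
        v = np.full(4, 7.0)
        for policy, ref in (("per-psm-median", None), ("reference-channel", 0)):
            ratios, flagged = quant.psm_log_ratios(v, policy, ref)
            np.testing.assert_allclose(ratios, 0)
            assert not flagged

    def test_reference_channel_ratio(self):
        ratios, _ = quant.psm_log_ratios(
            np.array([100.0, 200.0]), "reference-channel", 0
        )
        assert ratios[1] == pytest.approx(1.0)

    def test_median_policy(self):
        ratios, _ = quant.psm_log_ratios(np.array([50.0, 100.0, 200.0]))
        np.testing.assert_allclose(ratios, [-1, 0, 1])

    def test_zero_intensity_missing_not_minus_inf(self):
        ratios, _ = quant.psm_log_ratios(np.array([0.0, 100.0, 100.0]))
        assert np.isnan(ratios[0]) and np.isfinite(ratios[1:]).all()

    def test_all_zero_flagged(self):
        ratios, flagged = quant.psm_log_ratios(np.zeros(3))
        assert flagged and np.isnan(ratios).all()


class TestAggregate:
    def test_even_count_median(self):
        m = quant.aggregate_feature_ratios(
            {"F": [np.array([1.0]), np.array([3.0])]}, ("c",)
        )
        assert m.values[0, 0] == 2.0 and m.ratio_counts[0, 0] == 2

    def test_median_robust_to_outlier(self):
        m = quant.aggregate_feature_ratios(
            {"F": [np.array([1.0]), np.array([2.0]), np.array([9.0])]}, ("c",)
        )
        assert m.values[0, 0] == 2.0

    def test_random_groupings_match_direct_median(self, rng):
        channels = ("a", "b", "c")
        data = {}
        for f in range(10):
            vectors = rng.normal(0, 1, (int(rng.integers(1, 8)), 3))
            vectors[rng.random(vectors.shape) < 0.2] = np.nan
            data[f"F{f}"] = list(vectors)
        m = quant.aggregate_feature_ratios(data, channels)
        for i, fid in enumerate(m.feature_ids):
            stacked = np.array(data[fid])
            for c in range(3):
                col = stacked[:, c]
                col = col[~np.isnan(col)]
                if len(col):
                    assert m.values[i, c] == pytest.approx(np.median(col))
                else:
                    assert np.isnan(m.values[i, c])


class TestQuantReportingFilter:
    def matrix(self, counts):
        n = len(counts)
        return QuantMatrix(
            tuple(f"P{i}" for i in range(n)), ("a", "b"),
            np.zeros((n, 2)), np.array(counts),
        )

    def test_single_unique_peptide_dropped(self):
        m = self.matrix([[3, 3]])
        support = {"P0": {"pep1": (True, 3)}}
        out = quant.quant_reporting_filter(m, support)
        assert out.feature_ids == ()

    def test_two_supported_peptides_kept(self):
        m = self.matrix([[2, 3]])
        support = {"P0": {"pep1": (True, 2), "pep2": (True, 3)}}
        out = quant.quant_reporting_filter(m, support)
        assert out.feature_ids == ("P0",)

    def test_empty_matrix_stays_empty(self):
        m = QuantMatrix((), ("a", "b"), np.empty((0, 2)),
                        np.empty((0, 2), dtype=int))
        out = quant.quant_reporting_filter(m, {})
        assert out.feature_ids == ()


class TestMedianMadNormalize:
    def random_matrix(self, rng, n=40, c=6, missing=0.1):
        values = rng.normal(rng.uniform(-2, 2, c), rng.uniform(0.5, 2, c),
                            (n, c))
        values[rng.random((n, c)) < missing] = np.nan
        return QuantMatrix(
            tuple(f"F{i}" for i in range(n)),
            tuple(f"c{j}" for j in range(c)),
            values, np.ones((n, c), dtype=int),
        )

    def test_postconditions(self, rng):
        for _ in range(10):
            m = self.random_matrix(rng)
            out, flagged = quant.median_mad_normalize(m)
            assert flagged == []
            mads = []
            for c in range(len(out.channels)):
                col = out.values[:, c]
                col = col[~np.isnan(col)]
                assert np.median(col) == pytest.approx(0, abs=1e-12)
                mads.append(np.median(np.abs(col)))
            np.testing.assert_allclose(mads, mads[0], rtol=1e-9)

    def test_idempotent(self, rng):
        m = self.random_matrix(rng)
        once, _ = quant.median_mad_normalize(m)
        twice, _ = quant.median_mad_normalize(once)
        np.testing.assert_allclose(
            once.values, twice.values, rtol=1e-12, atol=1e-12, equal_nan=True
        )

    def test_sparse_channel_centered_only_and_flagged(self, rng):
        values = rng.normal(0, 1, (10, 2))
        values[2:, 1] = np.nan  # channel 1 has 2 values
        m = QuantMatrix(("F%d" % i for i in range(10)), ("a", "b"),
                        values, np.ones((10, 2), dtype=int))
        out, flagged = quant.median_mad_normalize(m)
        assert flagged == ["b"]
        col = out.values[:2, 1]
        assert np.median(col) == pytest.approx(0, abs=1e-12)


class TestSaavConsistency:
    def test_clean_separation_kept(self):
        row = np.array([0.1, -0.1, 0.0, 0.05, 3.0, 3.2])
        mask = np.array([False] * 4 + [True] * 2)
        assert quant.saav_patient_consistency(row, mask)

    def test_high_non_carrier_drops(self):
        row = np.array([0.1, -0.1, 3.1, 0.05, 3.0, 3.2])
        mask = np.array([False] * 4 + [True] * 2)
        assert not quant.saav_patient_consistency(row, mask)

    def test_low_carrier_drops(self):
        row = np.array([0.1, -0.1, 0.0, 0.05, 0.0, 3.2])
        mask = np.array([False] * 4 + [True] * 2)
        assert not quant.saav_patient_consistency(row, mask)

    def test_no_carriers_errors(self):
        with pytest.raises(ValueError, match="no carrier"):
            quant.saav_patient_consistency(np.zeros(3), np.zeros(3, bool))
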