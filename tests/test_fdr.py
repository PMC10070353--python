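"""Target-decoy estimation, autovalidation and subset FDR control."""

import numpy as np
import pytest

from psmkit import fdr
from psmkit.profiles import HLA_I, PTM_OME
from tests.conftest import make_psm


def brute_force_autovalidate(psms, target, decoy_correction=2):
    """Independent restatement: plain loops over every observed pair."""
    scores = sorted({p.score for p in psms})
    deltas = sorted({p.delta_rank_score for p in psms})
    best = None
    for s in scores:
        for d in deltas:
            acc = [p for p in psms if p.score >= s and p.delta_rank_score >= d]
            n_t = sum(1 for p in acc if not p.is_decoy)
            n_d = len(acc) - n_t
            if n_t == 0 or not ((n_d + decoy_correction) / n_t <= target):
                continue
            key = (-n_t, n_d, s, d)
            if best is None or key < best[0]:
                best = (key, (s, d, n_t, n_d))
    return None if best is None else best[1]


def brute_force_grid_search(psms, bcs_grid, score_grid, target):
    best = None
    for b in bcs_grid:
        for s in score_grid:
            acc = [p for p in psms if p.bcs >= b and p.score >= s]
            n_t = sum(1 for p in acc if not p.is_decoy)
            n_d = len(acc) - n_t
            if n_t == 0 or not (n_d / n_t < target):
                continue
            key = (-n_t, bcs_grid.index(b), score_grid.index(s))
            if best is None or key < best[0]:
                best = (key, (b, s, n_t))
    return None if best is None else best[1]


def random_psms(rng, n, n_score_values=40, n_delta_values=30, decoy_p=0.35):
    score_lattice = np.round(rng.uniform(3, 18, n_score_values), 2)
    delta_lattice = np.round(rng.uniform(0, 5, n_delta_values), 2)
    psms = []
    for i in range(n):
        decoy = rng.random() < decoy_p
        # decoys concentrate at low scores so feasible regions exist
        w = rng.integers(0, n_score_values // (3 if decoy else 1))
        psms.append(
            make_psm(
                spectrum_id=f"S{i:05d}",
                score=float(np.sort(score_lattice)[w]),
                delta_rank_score=float(rng.choice(delta_lattice)),
                bcs=float(np.round(rng.uniform(0, 12), 1)),
                is_decoy=bool(decoy),
            )
        )
    return psms


class TestEstimateFdr:
    def test_no_decoys_is_zero(self):
        psms = [make_psm(spectrum_id=str(i)) for i in range(100)]
        assert fdr.estimate_fdr(psms) == 0.0

    def test_direct_ratio(self):
        psms = [make_psm(spectrum_id=str(i)) for i in range(199)]
        psms.append(make_psm(spectrum_id="d", is_decoy=True))
        assert fdr.estimate_fdr(psms) == pytest.approx(1 / 199)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="no accepted PSMs"):
            fdr.estimate_fdr([])

    def test_decoys_without_targets_errors(self):
        with pytest.raises(ValueError, match="no targets"):
            fdr.estimate_fdr([make_psm(is_decoy=True)])

    def test_threshold_sweep_matches_counting(self, rng):
        """D/T after any threshold equals brute-force counting there."""
        psms = random_psms(rng, 400)
        for s in np.linspace(3, 18, 7):
            acc = [p for p in psms if p.score >= s]
            n_d = sum(1 for p in acc if p.is_decoy)
            n_t = len(acc) - n_d
            if n_t:
                assert fdr.estimate_fdr(acc) == n_d / n_t

    def test_monotonicity_of_threshold_counts(self, rng):
        """Raising a threshold never increases accepted targets or decoys."""
        psms = random_psms(rng, 300)
        prev_t, prev_d = np.inf, np.inf
        for s in np.linspace(0, 20, 15):
            acc = [p for p in psms if p.score >= s]
            n_d = sum(1 for p in acc if p.is_decoy)
            n_t = len(acc) - n_d
            assert n_t <= prev_t and n_d <= prev_d
            prev_t, prev_d = n_t, n_d


class TestAutovalidate:
    def test_no_decoys_accepts_everything(self):
        psms = [
            make_psm(spectrum_id=str(i), score=5 + (i % 10))
            for i in range(300)
        ]
        threshold_sets, accepted = fdr.autovalidate(psms)
        assert len(accepted) == 300
        (ts,) = [t for t in threshold_sets if t.feasible]
        assert ts.achieved_fdr_estimate == 0.0
        assert ts.n_accepted_targets == 300

    def test_matches_exhaustive_enumeration(self, rng):
        """Accepted set equals the brute-force optimum over all pairs."""
        for _ in range(4):
            psms = random_psms(rng, 500)
            buckets = (fdr.BucketSpec((2,), "run", 0.05),)
            threshold_sets, accepted = fdr.autovalidate(psms, buckets)
            oracle = brute_force_autovalidate(psms, 0.05)
            (ts,) = threshold_sets
            assert oracle is not None and ts.feasible
            s, d, n_t, n_d = oracle
            assert (ts.min_score, ts.min_delta_rank) == (s, d)
            assert (ts.n_accepted_targets, ts.n_accepted_decoys) == (n_t, n_d)
            expected = {
                p.spectrum_id
                for p in psms
                if p.score >= s and p.delta_rank_score >= d
            }
            assert {p.spectrum_id for p in accepted} == expected

    def test_per_run_scoping_is_independent(self, rng):
        """Union acceptance equals concatenation of per-run optima."""
        psms = random_psms(rng, 400)
        for i, p in enumerate(psms):
            p.run_id = f"run{i % 2}"
        buckets = (fdr.BucketSpec((2,), "run", 0.05),)
        _, accepted = fdr.autovalidate(psms, buckets)
        per_run = []
        for run in ("run0", "run1"):
            _, acc = fdr.autovalidate(
                [p for p in psms if p.run_id == run], buckets
            )
            per_run.extend(acc)
        assert {p.spectrum_id for p in accepted} == {
            p.spectrum_id for p in per_run
        }

    def test_infeasible_scope_flagged_not_relaxed(self):
        psms = [
            make_psm(spectrum_id=f"t{i}", score=10.0) for i in range(5)
        ] + [make_psm(spectrum_id=f"d{i}", score=11.0, is_decoy=True)
             for i in range(5)]
        threshold_sets, accepted = fdr.autovalidate(
            psms, (fdr.BucketSpec((2,), "run", 0.008),)
        )
        assert accepted == []
        assert not threshold_sets[0].feasible

    def test_order_invariance(self, rng):
        psms = random_psms(rng, 300)
        _, acc1 = fdr.autovalidate(psms, (fdr.BucketSpec((2,), "run", 0.05),))
        shuffled = list(psms)
        rng.shuffle(shuffled)
        _, acc2 = fdr.autovalidate(
            shuffled, (fdr.BucketSpec((2,), "run", 0.05),)
        )
        assert {p.spectrum_id for p in acc1} == {p.spectrum_id for p in acc2}


class TestFixedSubsetThresholds:
    def test_boundary_semantics(self):
        keeper = make_psm(score=7.0, spi_pct=50.0, mass_error_ppm=-4.9,
                          bcs=5.0, sequence="ACDEFGHIK")
        assert fdr.apply_fixed_subset_thresholds([keeper], HLA_I) == [keeper]

    def test_ppm_bound_is_strict(self):
        psm = make_psm(mass_error_ppm=5.0)
        assert fdr.apply_fixed_subset_thresholds([psm], HLA_I) == []

    def test_hla1_length_window(self):
        psm = make_psm(sequence="ACDEFGHIKLMNP")  # 13-mer
        assert fdr.apply_fixed_subset_thresholds([psm], HLA_I) == []
        assert fdr.apply_fixed_subset_thresholds([psm], PTM_OME) == [psm]


class TestSubsetGridSearch:
    def test_clean_class_keeps_grid_minima(self):
        psms = [make_psm(spectrum_id=str(i), score=10, bcs=6)
                for i in range(200)]
        thresholds, retained = fdr.subset_grid_search(
            psms, [4, 5, 6], [7, 8, 9]
        )
        assert thresholds.feasible
        assert (thresholds.min_bcs, thresholds.min_score) == (4, 7)
        assert len(retained) == 200

    def test_all_decoy_class_infeasible(self):
        psms = [make_psm(spectrum_id=str(i), is_decoy=True) for i in range(50)]
        thresholds, retained = fdr.subset_grid_search(psms, [4], [7])
        assert not thresholds.feasible and retained == []

    def test_empty_class_infeasible(self):
        thresholds, retained = fdr.subset_grid_search([], [4], [7])
        assert not thresholds.feasible and retained == []

    def test_matches_exhaustive_enumeration(self, rng):
        bcs_grid = [float(b) for b in range(0, 13)]
        score_grid = [float(s) for s in np.arange(3, 18, 0.5)]
        for _ in range(4):
            psms = random_psms(rng, 300)
            thresholds, retained = fdr.subset_grid_search(
                psms, bcs_grid, score_grid, 0.05
            )
            oracle = brute_force_grid_search(psms, bcs_grid, score_grid, 0.05)
            if oracle is None:
                assert not thresholds.feasible
                continue
            b, s, n_t = oracle
            assert (thresholds.min_bcs, thresholds.min_score) == (b, s)
            assert thresholds.n_retained_targets == n_t


class TestRunSubsetFdr:
    def test_all_canonical_passes_through(self):
        psms = [make_psm(spectrum_id=str(i)) for i in range(20)]
        accepted, per_class = fdr.run_subset_fdr(psms, {})
        assert accepted == psms and per_class == {}

    def test_unknown_class_errors(self):
        psms = [make_psm(class_label="nuORF:lncRNA")]
        with pytest.raises(ValueError, match="nuORF:lncRNA"):
            fdr.run_subset_fdr(psms, {})

    def test_noisy_class_tightened_clean_class_kept(self, rng):
        clean = [
            make_psm(spectrum_id=f"c{i}", score=12.0, bcs=8.0,
                     class_label="nuORF:uORF")
            for i in range(300)
        ]
        noisy = [
            make_psm(
                spectrum_id=f"n{i}",
                score=float(np.round(rng.uniform(7, 14), 1)),
                bcs=float(np.round(rng.uniform(4, 10), 1)),
                class_label="nuORF:lncRNA",
                is_decoy=(i % 10 == 0),
            )
            for i in range(300)
        ]
        profiles = {"nuORF:uORF": PTM_OME, "nuORF:lncRNA": PTM_OME}
        accepted, per_class = fdr.run_subset_fdr(clean + noisy, profiles)
        assert per_class["nuORF:uORF"].min_bcs == PTM_OME.min_bcs
        assert per_class["nuORF:uORF"].min_score == PTM_OME.min_score
        tightened = per_class["nuORF:lncRNA"]
        assert (not tightened.feasible) or (
            tightened.min_bcs > PTM_OME.min_bcs
            or tightened.min_score > PTM_OME.min_score
        )

    def test_order_invariance(self, rng):
        psms = random_psms(rng, 200)
        for i, p in enumerate(psms):
            p.class_label = "nuORF:lncRNA" if i % 3 else "canonical"
        profiles = {"nuORF:lncRNA": PTM_OME}
        accepted1, _ = fdr.run_subset_fdr(psms, profiles)
        shuffled = list(psms)
        rng.shuffle(shuffled)
        accepted2, _ = fdr.run_subset_fdr(shuffled, profiles)
        assert {p.spectrum_id for p in accepted1} == {
            p.spectrum_id for p in accepted2
        }
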