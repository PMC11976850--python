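"""Dictionary construction: masses, envelopes, merging, calibration,
search windows, and the decoy mutation rules."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from swaps.io import EvidenceRecord
from swaps.library import (CalibrationStats, RESIDUE_COMPOSITIONS, AlignmentError,
                           assign_search_windows, compute_calibration_stats,
                           compute_isotope_envelope, generate_decoys,
                           load_mutation_map, lowess_rt_alignment, merge_libraries,
                           monoisotopic_mass, peptide_composition, PrecursorCandidate)

# toy mutation map used throughout so no test depends on the shipped default
TOY_MAP = {r: r for r in RESIDUE_COMPOSITIONS}
TOY_MAP.update({"E": "D", "D": "E", "I": "V", "V": "I", "K": "R", "R": "K"})


def _rec(seq="PEPTIDEK", charge=2, intensity=1e5, source="experiment", **kw):
    defaults = dict(rt_obs=10.0, rt_start=9.9, rt_end=10.1, im_center=1.0,
                    im_length=0.07)
    defaults.update(kw)
    return EvidenceRecord(seq, charge, intensity=intensity, source=source, **defaults)


def _cand(seq="PEPTIDEK", charge=2, cid=0, rt_pred=10.0, im_center=1.0):
    return PrecursorCandidate(
        id=cid, modified_sequence=seq, charge=charge, is_decoy=False, pair_id=cid,
        envelope=compute_isotope_envelope(seq, charge), rt_pred=rt_pred,
        rt_window=(rt_pred - 0.5, rt_pred + 0.5), im_center=im_center,
        im_window=(im_center - 0.1, im_center + 0.1))


class TestComposition:
    @pytest.mark.parametrize("seq,mass", [
        ("G", 75.03203), ("GG", 132.05349), ("PEPTIDE", 799.35997)])
    def test_monoisotopic_masses(self, seq, mass):
        assert monoisotopic_mass(seq) == pytest.approx(mass, abs=1e-4)

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(ValueError, match="B"):
            peptide_composition("PEBTIDE")

    def test_unknown_modification_named_in_error(self):
        with pytest.raises(ValueError, match="phos"):
            peptide_composition("PEPS[phos]K")

    def test_modifications_shift_composition(self):
        base = peptide_composition("PMPTIDE")
        ox = peptide_composition("PM[ox]PTIDE")
        assert ox["O"] == base["O"] + 1

    def test_mass_agrees_with_pyteomics_oracle_on_random_tryptic(self):
        from pyteomics import mass as pm

        rng = np.random.default_rng(11)
        residues = list(RESIDUE_COMPOSITIONS)
        for _ in range(200):
            n = int(rng.integers(6, 25))
            seq = "".join(rng.choice(residues, n)) + str(rng.choice(["K", "R"]))
            assert monoisotopic_mass(seq) == pytest.approx(
                pm.calculate_mass(sequence=seq), abs=1e-4)


class TestEnvelope:
    def test_mono_mz(self):
        env = compute_isotope_envelope("PEPTIDE", 2)
        assert env.mono_mz == pytest.approx(400.6873, abs=1e-3)

    def test_isotope_spacing_close_to_neutron_over_charge(self):
        env = compute_isotope_envelope("PEPTIDE", 1)
        gaps = np.diff(env.mzs)
        # nominal isotope gaps cluster around 1.00335/z; fine structure may
        # split one nucleon into adjacent bins (tiny gaps)
        big = gaps[gaps > 0.5]
        assert np.all(np.abs(big - 1.00335) < 0.01)

    def test_min_abundance_cut_keeps_at_least_two_peaks(self):
        env = compute_isotope_envelope("PEPTIDE", 1, min_abundance=0.01)
        assert len(env.peaks) >= 2
        assert (env.abundances > 0.01).all()

    def test_abundances_not_renormalized(self):
        env = compute_isotope_envelope("PEPTIDE", 2, min_abundance=0.01)
        assert env.total_abundance() < 1.0
        assert env.total_abundance() > 0.9

    def test_matches_pyteomics_enumeration_on_binned_abundances(self):
        from pyteomics import mass as pm

        ref: dict[int, float] = {}
        # the enumeration oracle drops isotopes below 5e-4 elemental
        # abundance (2H, 17O), which the convolution keeps; tolerance
        # covers that deficit (~1% absolute for a peptide this size)
        for comp, ab in pm.isotopologues("PEPTIDEK", report_abundance=True,
                                         overall_threshold=1e-6):
            mz = (pm.calculate_mass(composition=comp) + 2 * 1.00727646677) / 2
            b = int(np.floor(mz / 0.01))
            ref[b] = ref.get(b, 0.0) + ab
        env = compute_isotope_envelope("PEPTIDEK", 2)
        for b, ab in zip(env.bins, env.abundances):
            assert ab == pytest.approx(ref[int(b)], abs=1.2e-2)
        # the monoisotopic bin involves no rare isotopes: tight agreement
        assert env.abundances[0] == pytest.approx(ref[int(env.bins[0])], abs=1e-3)


class TestMerge:
    def test_duplicate_keeps_max_intensity(self):
        merged = merge_libraries([_rec(intensity=1e5)],
                                 [_rec(intensity=2e5, source="reference")])
        assert len(merged) == 1
        assert merged[0].intensity == 2e5
        assert merged[0].source == "both"

    def test_disjoint_keys_concatenate(self):
        exp = [_rec("AAAAK", 2), _rec("CCCCK", 2), _rec("DDDDK", 2)]
        ref = [_rec("EEEEK", 2, source="reference"), _rec("FFFFK", 2, source="reference")]
        assert len(merge_libraries(exp, ref)) == 5

    def test_tie_prefers_experiment_source(self):
        merged = merge_libraries([_rec(intensity=1e5, rt_obs=10.0)],
                                 [_rec(intensity=1e5, rt_obs=20.0, rt_start=19.9,
                                       rt_end=20.1, source="reference")])
        assert len(merged) == 1
        assert merged[0].rt_obs == 10.0  # experiment's RT coordinates win

    def test_idempotent(self):
        merged = merge_libraries([_rec(), _rec("AAAAK", 3)], [])
        again = merge_libraries(merged, [])
        assert [(m.modified_sequence, m.charge, m.intensity) for m in merged] == \
               [(m.modified_sequence, m.charge, m.intensity) for m in again]


class TestLowess:
    def test_identity_pairs_give_identity_map(self):
        pairs = [(x, x) for x in np.linspace(1, 30, 50)]
        mapping = lowess_rt_alignment(pairs)
        assert np.max(np.abs(mapping.residuals)) < 1e-6

    def test_constant_shift_recovered(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 100, 500)
        pairs = list(zip(x, x + 2.0 + rng.normal(0, 0.05, 500)))
        mapping = lowess_rt_alignment(pairs)
        lo, hi = np.percentile(x, [10, 90])
        grid = np.linspace(lo, hi, 50)
        assert np.max(np.abs(mapping(grid) - (grid + 2.0))) < 0.05

    def test_single_valued_under_nonmonotone_noise(self):
        rng = np.random.default_rng(6)
        x = np.linspace(0, 10, 60)
        pairs = list(zip(x, x + rng.normal(0, 2.0, 60)))
        mapping = lowess_rt_alignment(pairs)
        out = mapping(np.array([3.0, 3.0]))
        assert out[0] == out[1]

    def test_too_few_points_raises_with_advice(self):
        with pytest.raises(AlignmentError, match="prediction"):
            lowess_rt_alignment([(1.0, 1.0)] * 10)


class TestCalibration:
    def test_zero_residuals(self):
        s = compute_calibration_stats([(1.0, 1.0)] * 10, [(1.0, 1.0)] * 10, [0.07] * 10)
        assert s.delta_rt95 == 0.0

    def test_constant_residuals(self):
        s = compute_calibration_stats([(1.1, 1.0)] * 10, [], [0.07] * 10)
        assert s.delta_rt95 == pytest.approx(0.1)

    def test_linear_interpolation_percentile(self):
        # residuals 0.01..1.00: the 95th percentile interpolates between the
        # 95th and 96th order statistics at fractional rank 0.95*(n-1)+1
        pairs = [(0.0, -(i + 1) / 100.0) for i in range(100)]
        s = compute_calibration_stats(pairs, [], [0.07])
        expected = 0.95 + 0.05 * 0.01
        assert s.delta_rt95 == pytest.approx(expected, abs=1e-12)

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            compute_calibration_stats([], [], [])


class TestSearchWindows:
    def test_paper_style_rt_window_width(self):
        # delta RT95 of 0.8 min yields a 1.6 min search window
        c = _cand(rt_pred=20.0)
        out = assign_search_windows([c], CalibrationStats(0.8, 0.0, 0.0))
        assert out[0].rt_window == pytest.approx((19.2, 20.8))
        assert out[0].rt_window[1] - out[0].rt_window[0] == pytest.approx(1.6)

    def test_im_window_formula(self):
        c = _cand(im_center=1.00)
        out = assign_search_windows([c], CalibrationStats(0.8, 0.047, 0.072),
                                    im_mode="predicted")
        assert out[0].im_window == pytest.approx((0.917, 1.083))

    def test_zero_delta_degenerates_to_point(self):
        c = _cand(rt_pred=20.0)
        out = assign_search_windows([c], CalibrationStats(0.0, 0.0, 0.0))
        assert out[0].rt_window == (20.0, 20.0)

    def test_missing_prediction_excluded(self):
        c = _cand()
        c.rt_pred = float("nan")
        assert assign_search_windows([c], CalibrationStats(0.1, 0.0, 0.0)) == []

    @given(st.floats(0.01, 2.0), st.floats(0.01, 2.0))
    def test_widening_deltas_never_shrinks_windows(self, d1, d2):
        lo, hi = sorted([d1, d2])
        c = _cand(rt_pred=20.0)
        w_lo = assign_search_windows([c], CalibrationStats(lo, lo, lo))[0]
        w_hi = assign_search_windows([c], CalibrationStats(hi, hi, hi))[0]
        assert w_hi.rt_window[0] <= w_lo.rt_window[0]
        assert w_hi.rt_window[1] >= w_lo.rt_window[1]
        assert w_hi.im_window[0] <= w_lo.im_window[0]
        assert w_hi.im_window[1] >= w_lo.im_window[1]


class TestDecoys:
    def test_two_round_mutation_on_composition_conserving_round1(self):
        # round 1 mutates positions 2 and second-to-last: PEPTIDE -> PDPTIEE;
        # the E<->D swap conserves elemental composition, so round 2 fires at
        # the third-to-last position: PDPTIEE -> PDPTVEE (delta -CH2)
        t = _cand("PEPTIDE", 2)
        decoys = generate_decoys([t], TOY_MAP)
        assert len(decoys) == 1
        assert decoys[0].modified_sequence == "PDPTVEE"
        assert monoisotopic_mass("PDPTVEE") - monoisotopic_mass("PEPTIDE") == \
            pytest.approx(-14.01565, abs=1e-4)
        assert decoys[0].charge == t.charge
        assert decoys[0].pair_id == t.id

    def test_round2_skipped_when_mass_shifts(self):
        # K->R in round 1 shifts the mass far beyond the closeness tolerance
        t = _cand("PKPTIDKE", 2)
        decoys = generate_decoys([t], TOY_MAP)
        # round 1: positions 2 and -2 -> PRPTIDRE; mass differs -> no round 2
        assert decoys[0].modified_sequence == "PRPTIDRE"

    def test_decoy_colliding_with_target_removed(self):
        t1 = _cand("PEPTIDE", 2, cid=0)
        t2 = _cand("PDPTVEE", 2, cid=1)  # equals t1's would-be decoy
        decoys = generate_decoys([t1, t2], TOY_MAP)
        assert all(d.pair_id != 0 for d in decoys)

    def test_short_sequences_get_no_decoy(self):
        assert generate_decoys([_cand("AKR", 2)], TOY_MAP) == []

    def test_pair_id_bijection_and_invariants(self):
        rng = np.random.default_rng(2)
        residues = list(RESIDUE_COMPOSITIONS)
        targets = []
        for i in range(30):
            seq = "".join(rng.choice(residues, int(rng.integers(6, 15)))) + "K"
            targets.append(_cand(seq, int(rng.choice([2, 3])), cid=i))
        decoys = generate_decoys(targets, load_mutation_map())
        pair_ids = [d.pair_id for d in decoys]
        assert len(set(pair_ids)) == len(pair_ids)
        by_id = {t.id: t for t in targets}
        for d in decoys:
            t = by_id[d.pair_id]
            assert d.charge == t.charge
            assert len(d.modified_sequence) == len(t.modified_sequence)
            assert d.is_decoy
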