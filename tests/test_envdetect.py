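"""Envelope detection, feature computation and candidate merging."""

import numpy as np
import pytest

from ntdms.chemcore import PROTON_MASS, averagine_formula, isotope_distribution
from ntdms.deconv import cwt_pick_peaks
from ntdms.envdetect import (
    EnvelopeCandidate,
    compute_envelope_features,
    graph_select,
    merge_candidates,
    thrash_scan,
)
from ntdms.msio import CentroidPeak, ProfileSpectrum
from ntdms.synthgen import render_profile


def _envelope(mass, z, inten, psf, lo=None, hi=None, step=0.001, noise=0.3, seed=0, extra=()):
    dist = isotope_distribution(averagine_formula(mass), 40)
    mz0 = (mass + z * PROTON_MASS) / z
    lo = mz0 - 3 if lo is None else lo
    hi = mz0 + 12 if hi is None else hi
    species = [(mass, z, inten, dist)] + list(extra)
    return render_profile(
        species, (lo, hi), step, psf, noise_sigma=noise,
        rng=np.random.default_rng(seed),
    )


class TestThrashScan:
    def test_clean_2plus_envelope_recovered(self, psf):
        s = _envelope(2000.0, 2, 100.0, psf)
        cands = thrash_scan(s, charge_max=6, psf=psf, max_iter=20)
        assert cands
        best = max(cands, key=lambda c: c.total_intensity)
        assert best.charge == 2
        assert abs(best.monoisotopic_mass - 2000.0) < 5e-6 * 2000.0

    def test_flat_noise_yields_nothing(self, psf):
        grid = np.arange(1000.0, 1010.0, 0.001)
        y = np.abs(np.random.default_rng(0).normal(0, 1.0, len(grid)))
        s = ProfileSpectrum(mz=grid, intensity=y)
        assert thrash_scan(s, charge_max=6, psf=psf, max_iter=50) == []

    def test_threshold_runs_are_not_nested(self, psf):
        # two overlapping envelopes: iterative subtraction means the strict
        # run's envelope set is not a subset of the relaxed run's
        s = _envelope(
            3000.0, 3, 100.0, psf, noise=0.2,
            extra=[(3001.5, 3, 60.0, isotope_distribution(averagine_formula(3001.5), 40))],
        )
        loose = thrash_scan(s, fit_thresholds=(0.60,), charge_max=6, psf=psf, max_iter=20)
        strict = thrash_scan(s, fit_thresholds=(0.90,), charge_max=6, psf=psf, max_iter=20)
        loose_keys = {(c.charge, round(c.monoisotopic_mass, 1)) for c in loose}
        strict_keys = {(c.charge, round(c.monoisotopic_mass, 1)) for c in strict}
        union = thrash_scan(s, charge_max=6, psf=psf, max_iter=20)
        union_keys = {(c.charge, round(c.monoisotopic_mass, 1)) for c in union}
        assert union_keys >= loose_keys or union_keys >= strict_keys
        assert loose_keys != strict_keys or len(union_keys) >= len(loose_keys)

    def test_invalid_charge_max_rejected(self, psf):
        s = _envelope(2000.0, 2, 100.0, psf)
        with pytest.raises(ValueError):
            thrash_scan(s, charge_max=0, psf=psf)


class TestGraphSelect:
    def _centroids(self, spectrum, psf):
        return cwt_pick_peaks(spectrum, snr_min=5.0, psf=psf)

    def test_two_disjoint_envelopes_both_selected(self, psf):
        d1 = isotope_distribution(averagine_formula(2000.0), 40)
        d2 = isotope_distribution(averagine_formula(3600.0), 40)
        s = render_profile(
            [(2000.0, 2, 100.0, d1), (3600.0, 3, 80.0, d2)],
            (995.0, 1215.0), 0.001, psf, noise_sigma=0.2,
            rng=np.random.default_rng(1),
        )
        cands = graph_select(self._centroids(s, psf), charge_max=6)
        masses = sorted(round(c.monoisotopic_mass) for c in cands)
        assert 2000 in masses and 3600 in masses

    def test_no_centroid_used_twice(self, psf):
        d1 = isotope_distribution(averagine_formula(2400.0), 40)
        s = render_profile(
            [(2400.0, 2, 100.0, d1)], (1198, 1208), 0.001, psf,
            noise_sigma=0.2, rng=np.random.default_rng(2),
        )
        peaks = self._centroids(s, psf)
        cands = graph_select(peaks, charge_max=8)
        pk_mz = np.array([p.mz for p in peaks])
        used = []
        for c in cands:
            for pmz, _i, _a in c.peaks:
                k = int(np.argmin(np.abs(pk_mz - pmz)))
                used.append(k)
        assert len(used) == len(set(used))

    def test_conflicting_charge_hypotheses_resolve_to_one(self, psf):
        # sparse 2+ envelope: the 4+ hypothesis shares every peak and must lose
        d = isotope_distribution(averagine_formula(2400.0), 40)
        s = render_profile(
            [(2400.0, 2, 100.0, d)], (1198, 1208), 0.001, psf,
            noise_sigma=0.1, rng=np.random.default_rng(3),
        )
        cands = graph_select(self._centroids(s, psf), charge_max=8)
        in_window = [c for c in cands if 1199 < c.mz < 1206]
        assert len(in_window) == 1
        assert in_window[0].charge == 2

    def test_empty_input(self):
        assert graph_select([], charge_max=4) == []


class TestFeatures:
    def test_isolated_clean_envelope(self, psf):
        s = _envelope(2000.0, 2, 100.0, psf, noise=0.0)
        cands = thrash_scan(s, charge_max=4, psf=psf, max_iter=10)
        c = max(cands, key=lambda c: c.total_intensity)
        f = compute_envelope_features(c, s, psf)
        assert f.interference > 0.9
        assert f.missing_peak_fraction < 0.2
        assert f.pearson_r > 0.999
        assert -1 <= f.pearson_r <= 1

    def test_interference_with_equal_coeluter(self, psf):
        # a second species of equal total intensity inside the envelope span
        d = isotope_distribution(averagine_formula(2000.0), 40)
        coel = isotope_distribution(averagine_formula(2000.47), 40)
        s = render_profile(
            [(2000.0, 2, 100.0, d), (2000.47, 2, 100.0, coel)],
            (997, 1008), 0.001, psf, noise_sigma=0.0,
        )
        cands = thrash_scan(s, fit_thresholds=(0.5,), charge_max=4, psf=psf, max_iter=5)
        c = max(cands, key=lambda c: c.total_intensity)
        f = compute_envelope_features(c, s, psf)
        assert 0.3 < f.interference < 0.75

    def test_missing_isotopologues_detected(self, psf):
        d = isotope_distribution(averagine_formula(3000.0), 40)
        keep = d.abundances >= 0.01 * d.abundances.max()
        masses = d.masses[keep]
        ab = d.abundances[keep] / d.abundances[keep].max()
        z = 2
        peaks = [
            ((m + z * PROTON_MASS) / z, 100.0 * a, a)
            for i, (m, a) in enumerate(zip(masses, ab))
            if i % 2 == 0  # delete every odd isotopologue
        ]
        c = EnvelopeCandidate(
            monoisotopic_mass=float(masses[0]), charge=z, peaks=peaks,
            apex_mz=peaks[0][0], apex_intensity=100.0,
            total_intensity=sum(p[1] for p in peaks), fit=0.9,
        )
        s = _envelope(3000.0, 2, 100.0, psf)
        f = compute_envelope_features(c, s, psf)
        assert 0.3 < f.missing_peak_fraction < 0.7

    def test_envelope_outside_spectrum_rejected(self, psf):
        c = EnvelopeCandidate(
            monoisotopic_mass=9000.0, charge=2, peaks=[(4501.0, 10.0, 1.0)],
            apex_mz=4501.0, apex_intensity=10.0, total_intensity=10.0, fit=0.9,
        )
        s = _envelope(2000.0, 2, 100.0, psf)
        with pytest.raises(ValueError):
            compute_envelope_features(c, s, psf)


def _cand(mass, z, fit, detector):
    return EnvelopeCandidate(
        monoisotopic_mass=mass, charge=z, peaks=[(mass / z, 10.0, 1.0)],
        apex_mz=mass / z, apex_intensity=10.0, total_intensity=10.0,
        fit=fit, detectors=frozenset({detector}),
    )


class TestMergeCandidates:
    def test_same_envelope_from_both_detectors(self):
        merged = merge_candidates(
            [[_cand(2000.0, 2, 0.9, "thrash")], [_cand(2000.000004, 2, 0.8, "graph")]],
            mass_tol_ppm=5.0,
        )
        assert len(merged) == 1
        assert merged[0].detectors == {"thrash", "graph"}
        assert merged[0].fit == 0.9  # representative is the better fit

    def test_10ppm_apart_with_3ppm_tol_stay_separate(self):
        m = 2000.0
        merged = merge_candidates(
            [[_cand(m, 2, 0.9, "a"), _cand(m * (1 + 10e-6), 2, 0.8, "b")]],
            mass_tol_ppm=3.0,
        )
        assert len(merged) == 2

    def test_idempotent(self):
        cands = [
            _cand(2000.0, 2, 0.9, "a"),
            _cand(2000.000004, 2, 0.7, "b"),
            _cand(3000.0, 3, 0.8, "a"),
        ]
        once = merge_candidates([cands], 5.0)
        twice = merge_candidates([once], 5.0)
        assert [(c.monoisotopic_mass, c.charge) for c in once] == [
            (c.monoisotopic_mass, c.charge) for c in twice
        ]
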