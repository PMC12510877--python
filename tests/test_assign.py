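"""Hierarchical terminal-ion assignment, variants, termini and recalibration."""

import numpy as np
import pytest

from ntdms.assign import (
    AssignmentState,
    assign_unmodified_terminals,
    assign_variant_ions,
    discover_termini,
    evaluate_fit,
    recalibrate_linear,
)
from ntdms.chemcore import (
    PROTON_MASS,
    Proteoform,
    builtin_modifications,
    enumerate_terminal_ions,
)
from ntdms.recipes import _synthetic_envelope, recalibration_benchmark
from ntdms.synthgen import VARIANT_OFFSETS, random_sequence


@pytest.fixture(scope="module")
def protein():
    return Proteoform(random_sequence(120, 21))


def _state(protein, picks, drift_ppm=0.0, mods=None, variants=()):
    """Envelopes for chosen (series, index, z) ions, optionally with variants."""
    ions = {
        (i.series, i.index): i for i in enumerate_terminal_ions(protein, ("b", "y"))
    }
    envs = []
    for series, index, z in picks:
        ion = ions[(series, index)]
        m = ion.neutral_mass * (1 + drift_ppm * 1e-6)
        envs.append(_synthetic_envelope(ion, z, m, protein))
        for vname in variants:
            mv = (ion.neutral_mass + VARIANT_OFFSETS[vname]) * (1 + drift_ppm * 1e-6)
            envs.append(_synthetic_envelope(ion, z, mv, protein, intensity=30.0))
    return AssignmentState(proteoform=protein, envelopes=envs, series=("b", "y"))


class TestEvaluateFit:
    def test_threshold_boundary(self, protein):
        ions = enumerate_terminal_ions(protein, ("y",))
        ion = ions[20]
        env = _synthetic_envelope(ion, 2, ion.neutral_mass * (1 + 2e-6), protein)
        good = evaluate_fit(env, ion.neutral_mass, None, 0.75, 3.0)
        assert good.decision == "auto-accept"
        # degrade the fit below threshold: decision may not auto-accept
        bad_peaks = [(mz, inten * (1 + 0.6 * (-1) ** i), a) for i, (mz, inten, a) in enumerate(env.peaks)]
        env_bad = type(env)(
            monoisotopic_mass=env.monoisotopic_mass, charge=env.charge,
            peaks=bad_peaks, apex_mz=env.apex_mz, apex_intensity=env.apex_intensity,
            total_intensity=env.total_intensity, fit=0.5,
        )
        worse = evaluate_fit(env_bad, ion.neutral_mass, None, 0.75, 3.0)
        assert worse.fit_score < good.fit_score
        if worse.fit_score < 0.75:
            assert worse.decision != "auto-accept"


class TestTerminalAssignment:
    def test_clean_ions_assigned(self, protein):
        picks = [("b", k, 2) for k in range(10, 30, 4)] + [("y", k, 3) for k in range(20, 60, 7)]
        state = _state(protein, picks, drift_ppm=2.0)
        state = assign_unmodified_terminals(state, tol_ppm=10.0)
        assert len(state.assignments) == len(picks)
        assert not state.envelopes

    def test_no_envelope_double_assigned(self, protein):
        picks = [("b", 15, 2), ("y", 40, 3)]
        state = _state(protein, picks)
        state = assign_unmodified_terminals(state, tol_ppm=10.0)
        env_ids = [id(a.envelope) for a in state.assignments]
        assert len(env_ids) == len(set(env_ids))

    def test_review_queue_not_auto_accepted(self, protein):
        picks = [("y", 30, 2)]
        state = _state(protein, picks, drift_ppm=15.0)  # outside 10 ppm
        state = assign_unmodified_terminals(state, tol_ppm=10.0)
        assert len(state.assignments) == 0


class TestVariants:
    def test_planted_variants_assigned_and_tagged(self, protein):
        picks = [("y", k, 2) for k in (20, 30, 40)]
        state = _state(protein, picks, variants=("dehydration",))
        state = assign_unmodified_terminals(state, tol_ppm=10.0)
        state = assign_variant_ions(state, tol_ppm=3.0)
        variants = [a for a in state.assignments if a.variant]
        assert len(variants) == 3
        assert all(a.variant == "dehydration" for a in variants)
        assert all(a.offset_da == pytest.approx(-18.010565, abs=1e-5) for a in variants)

    def test_no_planted_variants_no_false_hits(self, protein):
        picks = [("y", k, 2) for k in (22, 33, 44)]
        state = _state(protein, picks)
        state = assign_unmodified_terminals(state, tol_ppm=10.0)
        state = assign_variant_ions(state, tol_ppm=3.0)
        assert sum(1 for a in state.assignments if a.variant) == 0

    def test_sodiated_assigned_as_adduct(self, protein):
        picks = [("b", 25, 2)]
        state = _state(protein, picks, variants=("sodiation",))
        state = assign_unmodified_terminals(state, tol_ppm=10.0)
        state = assign_variant_ions(state, tol_ppm=3.0)
        variants = [a for a in state.assignments if a.variant]
        assert [a.variant for a in variants] == ["sodiation"]

    def test_requires_prior_assignment(self, protein):
        state = _state(protein, [("y", 20, 2)])
        with pytest.raises(ValueError):
            assign_variant_ions(state)


class TestRecalibration:
    def test_exact_linear_drift_removed(self):
        r = recalibration_benchmark(3, noise_ppm_sd=0.0)
        assert r["rms_ppm_after"] < 0.1

    def test_drift_parameters_recovered_within_5pct(self):
        r = recalibration_benchmark(4)
        assert r["slope_rel_error"] < 0.05
        assert r["intercept_rel_error"] < 0.05

    def test_outlier_dropped_after_calibration(self, protein):
        picks = [("y", k, 2) for k in range(10, 90, 4)]
        state = _state(protein, picks, drift_ppm=1.0)
        state = assign_unmodified_terminals(state, tol_ppm=10.0)
        # corrupt one mid-list assignment: 8 ppm post-calibration error
        bad = state.assignments[len(state.assignments) // 2]
        bad.observed_mz *= 1 + 8e-6
        state = recalibrate_linear(state, fine_tol_ppm=3.0)
        assert state.stage_counters["recalibration_dropped"] == 1
        assert bad not in state.assignments

    def test_idempotent_on_calibrated_data(self, protein):
        picks = [("y", k, 2) for k in range(15, 55, 5)]
        state = _state(protein, picks, drift_ppm=2.0)
        state = assign_unmodified_terminals(state, tol_ppm=10.0)
        state = recalibrate_linear(state, fine_tol_ppm=3.0)
        a1 = state.calibration
        state = recalibrate_linear(state, fine_tol_ppm=3.0)
        a2 = state.calibration
        assert abs(a2[0] - a1[0]) < 1e-6
        assert abs(a2[1] - a1[1]) < 1e-9

    def test_too_few_assignments_noop(self, protein):
        state = _state(protein, [("y", 20, 2)])
        state = assign_unmodified_terminals(state, tol_ppm=10.0)
        cal_before = state.calibration
        state = recalibrate_linear(state)
        assert state.calibration == cal_before


class TestDiscoverTermini:
    def test_c_terminal_truncation_found(self):
        seq = random_sequence(250, 31)
        trunc = Proteoform(seq, truncation=(1, 197))
        ions = enumerate_terminal_ions(trunc, ("b", "y"))
        rng = np.random.default_rng(1)
        masses = np.array(
            [i.neutral_mass for i in ions if rng.random() < 0.35]
        )
        res = discover_termini(masses, seq, tol_ppm=5.0, max_trim=80)
        c_hits = [r for r in res if r[0] == "C"]
        assert c_hits
        assert any(r[1] == 197 for r in c_hits[:2])

    def test_untruncated_only_zero_offset(self):
        seq = random_sequence(150, 32)
        ions = enumerate_terminal_ions(Proteoform(seq), ("b", "y"))
        rng = np.random.default_rng(2)
        masses = np.array([i.neutral_mass for i in ions if rng.random() < 0.3])
        res = discover_termini(masses, seq, tol_ppm=5.0, max_trim=60)
        for terminus, idx, mod, off, ev in res:
            assert abs(off) < 1e-6 or ev >= 0.01 or (
                (terminus == "N" and idx == 1) or (terminus == "C" and idx == 150)
            )

    def test_acetylated_n_terminus_hypothesis(self):
        seq = random_sequence(150, 33)
        acetyl = next(m for m in builtin_modifications() if m.name == "acetyl")
        p = Proteoform(seq, n_term_mod=acetyl)
        ions = enumerate_terminal_ions(p, ("b",))
        masses = np.array([i.neutral_mass for i in ions[5:40]])
        res = discover_termini(
            masses, seq, terminal_mods=[acetyl], tol_ppm=5.0, max_trim=40
        )
        top = res[0]
        assert top[0] == "N" and top[1] == 1 and top[2] == "acetyl"
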