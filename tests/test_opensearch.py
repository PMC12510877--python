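"""Poisson E-values, offset scans, internal fragments, decoy FDR, localization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ntdms.chemcore import ElementalFormula, Proteoform, RESIDUE_MASS, enumerate_terminal_ions, formula_mass
from ntdms.opensearch import (
    DECOY_FORMULAS,
    continuous_offset_scan,
    estimate_fdr,
    internal_fragment_search,
    localize_modification,
    multinotch_scan,
    poisson_evalue,
    resolve_degenerate,
)
from ntdms.synthgen import (
    internal_fragment_dataset,
    planted_offset_dataset,
    random_sequence,
)


def brute_force_evalue(k, lam, n):
    return lam**k * math.exp(-lam) / math.factorial(k) * n


class TestPoissonEvalue:
    @pytest.mark.parametrize(
        "k,lam,n,expected",
        [
            (0, 1.0, 100, 100 * math.exp(-1)),
            (6, 2.0, 1000, 2**6 * math.exp(-2) / 720 * 1000),
            (10, 0.5, 500, 8.161308109783107e-08),
        ],
    )
    def test_known_values(self, k, lam, n, expected):
        assert poisson_evalue(k, lam, n) == pytest.approx(expected, rel=1e-10)

    @given(
        k=st.integers(0, 20),
        lam=st.floats(0.01, 20.0),
        n=st.integers(1, 100_000),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_factorial_formula(self, k, lam, n):
        assert poisson_evalue(k, lam, n) == pytest.approx(
            brute_force_evalue(k, lam, n), rel=1e-12
        )

    def test_strictly_decreasing_beyond_lambda(self):
        lam = 2.5
        vals = [poisson_evalue(k, lam, 100) for k in range(3, 15)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError):
            poisson_evalue(3, 0.0, 10)


class TestContinuousScan:
    def test_planted_phospho_offset_recovered(self):
        observed, theo, _ = planted_offset_dataset(5)
        scan = continuous_offset_scan(observed, theo, 0.0, 200.0, 3.0, 0.01)
        hits = [s for s in scan.significant if abs(s[0] - 79.96633) < 0.05]
        assert len(hits) == 1
        off, k, ev = hits[0]
        assert k >= 10
        assert ev < 1e-6

    def test_lambda_is_mean_match_count(self):
        observed, theo, _ = planted_offset_dataset(6)
        scan = continuous_offset_scan(observed, theo, 0.0, 150.0, 3.0)
        assert scan.lam == pytest.approx(scan.k.mean())
        assert scan.n == len(scan.offsets)

    def test_broad_range_requires_multinotch(self):
        with pytest.raises(ValueError, match="multinotch"):
            continuous_offset_scan(np.array([1000.0]), np.array([900.0]), -100.0, 6000.0)

    def test_empty_theoretical_rejected(self):
        with pytest.raises(ValueError):
            continuous_offset_scan(np.array([1000.0]), np.array([]), 0.0, 10.0)

    def test_negative_offsets_handled(self):
        seq = random_sequence(150, 41)
        theo = np.array(
            [i.neutral_mass for i in enumerate_terminal_ions(Proteoform(seq), ("y",))]
        )
        rng = np.random.default_rng(3)
        pick = rng.choice(len(theo), 10, replace=False)
        observed = theo[pick] - 18.010565
        scan = continuous_offset_scan(observed, theo, -40.0, 40.0, 3.0)
        hits = [s for s in scan.significant if abs(s[0] + 18.010565) < 0.02]
        assert len(hits) == 1


class TestMultinotch:
    def test_truncation_notch_significant(self):
        seq = random_sequence(250, 42)
        res = np.array([RESIDUE_MASS[a] for a in seq])
        prefix = np.concatenate([[0.0], np.cumsum(res)])
        # protein truncated at residue 197: y ions all shifted by -suffix loss
        loss = prefix[250] - prefix[197]
        theo = np.array(
            [i.neutral_mass for i in enumerate_terminal_ions(Proteoform(seq), ("y",))]
        )
        rng = np.random.default_rng(4)
        observed = theo[rng.choice(len(theo), 25, replace=False)] - loss
        notches = [
            (f"C{250 - t}", -float(prefix[250] - prefix[250 - t])) for t in range(0, 80)
        ]
        scan = multinotch_scan(observed, notches, theo, 3.0, 0.01)
        sig_labels = {
            scan.labels[i]
            for i in np.flatnonzero(scan.evalues < 0.01)
        }
        assert "C197" in sig_labels

    def test_all_zero_counts_degenerate_lambda(self):
        notches = [("a", 10.0), ("b", 20.0), ("c", 30.0)]
        scan = multinotch_scan(np.array([5000.0]), notches, np.array([100.0]), 3.0)
        assert np.all(scan.k == 0)
        assert np.all(scan.evalues == 3.0)  # E = n in the lambda -> 0 limit
        assert scan.significant == []

    def test_duplicate_notch_masses_rejected(self):
        with pytest.raises(ValueError, match="ambiguous|duplicate"):
            multinotch_scan(
                np.array([1000.0]),
                [("a", 10.0), ("b", 10.0 + 1e-9)],
                np.array([900.0]),
                3.0,
            )


class TestInternalFragments:
    def test_planted_sets_recovered_with_low_fdr(self):
        seq, observed, labels = internal_fragment_dataset(7)
        sets, assignments, scan_n, _ = internal_fragment_search(observed, seq, 3.0, 0.01)
        shared = {s.shared_index for s in sets if s.shared_side == "N"}
        assert {40, 90, 150} <= shared
        n_false = sum(1 for a in assignments if labels[a.observed_index] is None)
        assert n_false / len(assignments) <= 0.07

    def test_unfiltered_search_has_high_fdr(self):
        seq, observed, labels = internal_fragment_dataset(7)
        _s, assignments, _n, _c = internal_fragment_search(
            observed, seq, 3.0, 0.01, apply_filter=False
        )
        n_false = sum(1 for a in assignments if labels[a.observed_index] is None)
        assert n_false / len(assignments) > 0.30

    def test_no_unassigned_masses_empty_result(self):
        seq = random_sequence(60, 44)
        sets, assignments, _n, _c = internal_fragment_search(np.array([]), seq)
        assert sets == [] and assignments == []

    def test_each_observed_mass_assigned_once(self):
        seq, observed, _labels = internal_fragment_dataset(8)
        _s, assignments, _n, _c = internal_fragment_search(observed, seq, 3.0, 0.01)
        idx = [a.observed_index for a in assignments]
        assert len(idx) == len(set(idx))


class TestResolveDegenerate:
    def test_evidenced_site_wins(self):
        cands = [
            (0, 40, 80, "N", 2.0),
            (0, 55, 95, "N", 0.5),
        ]
        chosen = resolve_degenerate(cands, evidenced_sites={40})
        assert chosen[1] == 40

    def test_smaller_ppm_error_wins(self):
        cands = [(0, 40, 80, "N", 1.1), (0, 41, 81, "N", 2.0)]
        assert resolve_degenerate(cands, set())[4] == 1.1

    def test_full_tie_shorter_fragment_deterministic(self):
        cands = [(0, 40, 90, "N", 1.0), (0, 50, 80, "N", 1.0)]
        first = resolve_degenerate(cands, set())
        assert (first[1], first[2]) == (50, 80)
        assert resolve_degenerate(list(reversed(cands)), set()) == first


class TestFdr:
    def _notched_setup(self, seed):
        seq, observed, labels = internal_fragment_dataset(seed)
        res = np.array([RESIDUE_MASS[a] for a in seq])
        prefix = np.concatenate([[0.0], np.cumsum(res)])
        b_theo = prefix[1 : len(seq)]
        notches = [
            (f"N{i}", -float(prefix[i - 1])) for i in range(2, len(seq) - 3)
        ]
        return observed, notches, b_theo

    def test_default_decoys_are_the_four_formulas(self):
        assert DECOY_FORMULAS == ("H5", "H5O2", "H7O9", "H9O3")
        masses = [formula_mass(ElementalFormula.parse(f)) for f in DECOY_FORMULAS]
        assert masses[0] == pytest.approx(5 * 1.00782503207, abs=1e-6)

    def test_zero_decoy_matches_zero_fdr(self):
        observed = np.array([5000.0, 6000.0])
        theo = np.array([5000.0, 6000.0])
        notches = [("a", 0.0), ("b", 500.0)]
        rep = estimate_fdr(observed, notches, theo, tol_ppm=0.5)
        assert rep.fdr_unfiltered == 0.0
        assert rep.fdr_filtered == 0.0

    def test_estimate_tracks_truth_within_factor_two(self):
        pooled_est, pooled_true = [], []
        for seed in (11, 12, 13, 14):
            seq, observed, labels = internal_fragment_dataset(seed)
            res = np.array([RESIDUE_MASS[a] for a in seq])
            prefix = np.concatenate([[0.0], np.cumsum(res)])
            b_theo = prefix[1 : len(seq)]
            notches = [(f"N{i}", -float(prefix[i - 1])) for i in range(2, len(seq) - 3)]
            rep = estimate_fdr(observed, notches, b_theo, 3.0, 0.01)
            _s, assignments, _n, _c = internal_fragment_search(observed, seq, 3.0, 0.01)
            n_false = sum(1 for a in assignments if labels[a.observed_index] is None)
            pooled_est.append(rep.fdr_filtered)
            pooled_true.append(n_false / max(len(assignments), 1))
        est, true = np.mean(pooled_est), np.mean(pooled_true)
        assert est <= max(2 * true, 0.02)
        assert true <= 0.07

    def test_zero_target_matches_undefined(self):
        rep = estimate_fdr(
            np.array([123.456]), [("a", 0.0)], np.array([50_000.0]), 1.0
        )
        assert rep.fdr_unfiltered is None
        assert "undefined" in rep.note


class TestLocalization:
    def _y_setup(self, n=599, site=493, k_mod_min=107, k_unmod_max=102):
        seq = random_sequence(n, 49, force={site: "C"})
        theo = np.array(
            [i.neutral_mass for i in enumerate_terminal_ions(Proteoform(seq), ("y",))]
        )
        offset = 238.22966
        modified = theo[np.array([k_mod_min, 130, 150]) - 1] + offset
        return theo, offset, modified, n

    def test_interval_contains_site_excludes_neighbor(self):
        theo, offset, modified, n = self._y_setup()
        loc = localize_modification(
            modified, n, theo, offset, "C", unmodified_indices=[20, 50, 102], tol_ppm=3.0
        )
        lo, hi = loc.interval
        assert lo <= 493 <= hi
        assert not (lo <= 499 <= hi)

    def test_all_ions_modified_interval_reaches_terminus(self):
        theo, offset, modified, n = self._y_setup()
        loc = localize_modification(
            modified, n, theo, offset, "C", unmodified_indices=[], tol_ppm=3.0
        )
        assert loc.interval[1] == n

    def test_no_modified_ions_empty_map(self):
        theo, offset, _m, n = self._y_setup()
        loc = localize_modification(
            np.array([1234.5]), n, theo, offset, "C", unmodified_indices=[50], tol_ppm=3.0
        )
        assert loc.interval is None
        assert loc.modified_indices == []
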