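"""Hierarchical first-pass assignment of terminal ions with internal recalibration.

Unmodified terminal ions are matched first at a low-stringency tolerance
(analyzers drift), each match validated by fitting the ion's theoretical
isotope pattern to the envelope; accepted ions are removed from the pool and
then serve as internal calibrants.  Common fragmentation side products —
dehydrated, deamidated and sodiated forms — are then picked up at a fine
tolerance relative to the already-assigned ions, iterating until nothing new
is assignable.  A linear m/z recalibration closes the loop, dropping any
assignment that lands outside the fine tolerance afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chemcore import (
    PROTON_MASS,
    Modification,
    Proteoform,
    TheoreticalIon,
    builtin_modifications,
    enumerate_terminal_ions,
)
from .envdetect import EnvelopeCandidate
from .opensearch import multinotch_scan, OffsetScanResult
from .synthgen import sequence_formula
from .chemcore import isotope_distribution, RESIDUE_MASS, WATER

VARIANT_OFFSETS = {
    "dehydration": -WATER,
    "deamidation": 0.98401587,
    "sodiation": 21.98194425,
}

_SERIES_ORDER = {"b": 0, "y": 1, "c": 2, "z": 3}


@dataclass
class Assignment:
    envelope: EnvelopeCandidate
    ion: TheoreticalIon
    charge: int
    theoretical_mz: float
    observed_mz: float
    error_ppm: float
    error_mda: float
    fit_score: float
    stage: str
    offset_da: float = 0.0
    variant: str | None = None


@dataclass
class FitResult:
    fit_score: float
    scale: float
    error_ppm: float
    error_mda: float
    decision: str  # auto-accept | review | reject


@dataclass
class AssignmentState:
    proteoform: Proteoform
    envelopes: list[EnvelopeCandidate]
    series: tuple[str, ...] = ("b", "y")
    assignments: list[Assignment] = field(default_factory=list)
    review_queue: list[Assignment] = field(default_factory=list)
    calibration: tuple[float, float] = (0.0, 0.0)  # corrected = mz - (a + b*mz)
    stage_counters: dict = field(default_factory=dict)

    def corrected_mz(self, mz: float) -> float:
        a, b = self.calibration
        return mz - (a + b * mz)

    def corrected_mass(self, e: EnvelopeCandidate) -> float:
        mz = (e.monoisotopic_mass + e.charge * PROTON_MASS) / e.charge
        return self.corrected_mz(mz) * e.charge - e.charge * PROTON_MASS

    def unassigned_masses(self) -> np.ndarray:
        return np.array([self.corrected_mass(e) for e in self.envelopes])


def evaluate_fit(
    envelope: EnvelopeCandidate,
    ion_mass: float,
    distribution=None,
    fit_threshold: float = 0.75,
    tol_ppm: float = 3.0,
    observed_mass: float | None = None,
) -> FitResult:
    """Fit a theoretical isotope pattern to an envelope's member peaks.

    Auto-accept requires both the goodness-of-fit and the mass-error
    thresholds; envelopes failing either go to the review queue rather than
    being silently assigned.
    """
    obs_mass = envelope.monoisotopic_mass if observed_mass is None else observed_mass
    err = obs_mass - ion_mass
    err_ppm = err / ion_mass * 1e6
    obs = np.array([p[1] for p in envelope.peaks])
    if distribution is not None:
        z = envelope.charge
        theo_mz = (distribution.masses + z * PROTON_MASS) / z
        theo_ab = distribution.abundances / distribution.abundances.max()
        matched = np.zeros(len(obs))
        for ei, (pmz, pint, _pa) in enumerate(envelope.peaks):
            t = int(np.argmin(np.abs(theo_mz - pmz)))
            matched[ei] = theo_ab[t]
        theo = matched
    else:
        theo = np.array([p[2] for p in envelope.peaks])
    denom = float(theo @ theo)
    scale = float(obs @ theo / denom) if denom > 0 else 0.0
    fit = max(0.0, 1.0 - np.abs(obs - scale * theo).sum() / obs.sum()) if obs.sum() else 0.0
    if fit >= fit_threshold and abs(err_ppm) <= tol_ppm:
        decision = "auto-accept"
    elif fit >= 0.5 * fit_threshold and abs(err_ppm) <= 2 * tol_ppm:
        decision = "review"
    else:
        decision = "reject"
    return FitResult(fit, scale, err_ppm, err * 1000.0, decision)


def _ion_distribution_cache(p: Proteoform):
    cache: dict[tuple, object] = {}

    def get(ion: TheoreticalIon, extra_mass: float = 0.0):
        key = (ion.series, ion.index, round(extra_mass, 4))
        if key not in cache:
            seq = p.active_sequence
            sub = seq[: ion.index] if ion.terminus == "N" else seq[-ion.index :]
            f = sequence_formula(sub, water=ion.terminus == "C")
            cache[key] = isotope_distribution(f, n_peaks=60)
        return cache[key]

    return get


def discover_termini(
    masses: np.ndarray,
    sequence: str,
    terminal_mods: list[Modification] | None = None,
    series: tuple[str, ...] = ("b", "y"),
    tol_ppm: float = 10.0,
    evalue_threshold: float = 0.01,
    max_trim: int | None = None,
) -> list[tuple[str, int, str | None, float, float]]:
    """Rank candidate termini by a successive-residue multinotch scan.

    Notches are cumulative residue losses from each end of the precursor
    sequence (optionally shifted by hypothesised terminal modifications such
    as acetylation); each significant notch names a candidate cleavage.
    Returns (terminus, residue index of the new terminus, mod name, offset,
    E value), best first.  Index 1 with offset 0 denotes the unprocessed
    terminus.
    """
    n = len(sequence)
    if n < 10:
        raise ValueError("sequence too short for termini discovery")
    res = np.array([RESIDUE_MASS[aa] for aa in sequence])
    prefix = np.concatenate([[0.0], np.cumsum(res)])
    trim = min(max_trim if max_trim is not None else n // 2, n - 10)
    mods = [None] + list(terminal_mods or [])
    out = []
    p_full = Proteoform(sequence)
    # trimming the N terminus shifts every N-terminal (b/c) ion by -loss;
    # trimming the C terminus shifts every C-terminal (y/z) ion likewise
    for terminus, ion_series in (("N", "b"), ("C", "y")):
        theo = np.array(
            [
                i.neutral_mass
                for i in enumerate_terminal_ions(p_full, (ion_series,))
            ]
        )
        for mod in mods:
            shift = mod.delta_mass if mod is not None else 0.0
            notches = []
            for t in range(0, trim):
                if terminus == "N":
                    loss = prefix[t]
                    label = f"N{t + 1}"  # new N-terminal start residue
                else:
                    loss = prefix[n] - prefix[n - t]
                    label = f"C{n - t}"  # new C-terminal end residue
                notches.append((label, -float(loss) + shift))
            scan = multinotch_scan(
                masses, notches, theo, tol_ppm, evalue_threshold
            )
            for off, k, ev in scan.significant:
                t_idx = int(np.argmin(np.abs(scan.offsets - off)))
                out.append(
                    (
                        terminus,
                        int(scan.labels[t_idx][1:]),
                        mod.name if mod is not None else None,
                        float(off),
                        float(ev),
                    )
                )
    out.sort(key=lambda r: r[4])
    return out


def assign_unmodified_terminals(
    state: AssignmentState,
    tol_ppm: float = 10.0,
    fit_threshold: float = 0.75,
    stage: str = "terminal",
) -> AssignmentState:
    """First-pass matching of unmodified terminal ions at coarse tolerance.

    Degenerate matches resolve to the smaller |ppm| error, then the lower
    cleavage index, then series order b < y < c < z.
    """
    ions = enumerate_terminal_ions(state.proteoform, state.series)
    dist_of = _ion_distribution_cache(state.proteoform)
    theo_masses = np.array([i.neutral_mass for i in ions])
    order = np.argsort(theo_masses)
    sorted_masses = theo_masses[order]
    remaining = []
    n_assigned = 0
    for e in state.envelopes:
        m = state.corrected_mass(e)
        tol = tol_ppm * 1e-6 * m
        i, j = np.searchsorted(sorted_masses, [m - tol, m + tol])
        cands = []
        for s in range(i, j):
            ion = ions[order[s]]
            err_ppm = (m - ion.neutral_mass) / ion.neutral_mass * 1e6
            cands.append((abs(err_ppm), ion.index, _SERIES_ORDER[ion.series], ion, err_ppm))
        if not cands:
            remaining.append(e)
            continue
        cands.sort(key=lambda c: (round(c[0], 9), c[1], c[2]))
        _aerr, _idx, _so, ion, err_ppm = cands[0]
        fr = evaluate_fit(
            e, ion.neutral_mass, dist_of(ion), fit_threshold, tol_ppm,
            observed_mass=m,
        )
        theo_mz = ion.mz(e.charge)
        a = Assignment(
            envelope=e,
            ion=ion,
            charge=e.charge,
            theoretical_mz=theo_mz,
            observed_mz=(m + e.charge * PROTON_MASS) / e.charge,
            error_ppm=fr.error_ppm,
            error_mda=fr.error_mda,
            fit_score=fr.fit_score,
            stage=stage,
        )
        if fr.decision == "auto-accept":
            state.assignments.append(a)
            n_assigned += 1
        else:
            if fr.decision == "review":
                state.review_queue.append(a)
            remaining.append(e)
    state.envelopes = remaining
    state.stage_counters[stage] = n_assigned
    return state


def assign_variant_ions(
    state: AssignmentState,
    variants: dict[str, float] | None = None,
    tol_ppm: float = 3.0,
    fit_threshold: float = 0.75,
    max_rounds: int = 5,
) -> AssignmentState:
    """Assign dehydrated/deamidated/sodiated forms of already-assigned ions.

    Offsets are searched relative to assigned ions, corrected by the current
    systematic mass-error estimate, and the cycle repeats until no further
    products can be assigned.
    """
    if variants is None:
        variants = VARIANT_OFFSETS
    if not state.assignments:
        raise ValueError("variant search needs at least one prior assignment")
    for round_no in range(max_rounds):
        base = {
            (a.ion.series, a.ion.index): a
            for a in state.assignments
            if a.variant is None
        }
        sys_ppm = float(np.median([a.error_ppm for a in state.assignments]))
        new = 0
        remaining = []
        for e in state.envelopes:
            m = state.corrected_mass(e)
            best = None
            for (series, index), a in base.items():
                for vname, voff in variants.items():
                    expect = a.ion.neutral_mass + voff
                    expect_obs = expect * (1 + sys_ppm * 1e-6)
                    err = (m - expect_obs) / expect * 1e6
                    if abs(err) <= tol_ppm:
                        if best is None or abs(err) < abs(best[0]):
                            best = (err, vname, voff, a)
            if best is None:
                remaining.append(e)
                continue
            err, vname, voff, parent = best
            ion = replace(parent.ion)
            a = Assignment(
                envelope=e,
                ion=ion,
                charge=e.charge,
                theoretical_mz=(parent.ion.neutral_mass + voff + e.charge * PROTON_MASS) / e.charge,
                observed_mz=(m + e.charge * PROTON_MASS) / e.charge,
                error_ppm=(m - (parent.ion.neutral_mass + voff)) / (parent.ion.neutral_mass + voff) * 1e6,
                error_mda=(m - (parent.ion.neutral_mass + voff)) * 1000.0,
                fit_score=e.fit,
                stage=f"variant-r{round_no + 1}",
                offset_da=voff,
                variant=vname,
            )
            state.assignments.append(a)
            new += 1
        state.envelopes = remaining
        state.stage_counters[f"variant-r{round_no + 1}"] = new
        if new == 0:
            break
    return state


def recalibrate_linear(
    state: AssignmentState, fine_tol_ppm: float = 3.0
) -> AssignmentState:
    """Least-squares linear m/z recalibration from current assignments.

    Fits observed-vs-theoretical m/z error as a + b*mz, applies the
    correction to assignments and remaining envelopes, and drops assignments
    whose post-calibration error exceeds the fine tolerance back into the
    unassigned pool.  RMS ppm error never increases.
    """
    if len(state.assignments) < 2:
        import logging

        logging.getLogger("ntdms").warning(
            "recalibration skipped: need >= 2 assignments"
        )
        return state
    obs = np.array([a.observed_mz for a in state.assignments])
    theo = np.array([a.theoretical_mz for a in state.assignments])
    err = obs - theo
    rms_before = float(np.sqrt(np.mean((err / theo * 1e6) ** 2)))
    # mass errors are ppm-scale, i.e. their sd grows with m/z: weight the
    # linear fit accordingly (polyfit weights multiply residuals)
    b, a = np.polyfit(obs, err, 1, w=1.0 / obs)
    a0, b0 = state.calibration
    # compose with any existing calibration: corrections add in first order
    state.calibration = (a0 + a, b0 + b)
    kept, dropped = [], []
    for asg in state.assignments:
        mz_cor = asg.observed_mz - (a + b * asg.observed_mz)
        theo_mz = asg.theoretical_mz
        ppm = (mz_cor - theo_mz) / theo_mz * 1e6
        asg.observed_mz = mz_cor
        asg.error_ppm = ppm
        asg.error_mda = (mz_cor - theo_mz) * asg.charge * 1000.0
        if abs(ppm) > fine_tol_ppm:
            dropped.append(asg)
        else:
            kept.append(asg)
    state.assignments = kept
    state.envelopes.extend(d.envelope for d in dropped)
    rms_after = float(
        np.sqrt(np.mean([a_.error_ppm**2 for a_ in kept])) if kept else 0.0
    )
    state.stage_counters["recalibration_dropped"] = len(dropped)
    state.stage_counters["rms_ppm_before"] = rms_before
    state.stage_counters["rms_ppm_after"] = rms_after
    return state
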