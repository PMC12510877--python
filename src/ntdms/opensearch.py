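"""Fragment-level open searches with Poisson E-value statistics.

A mass offset Delta is applied to every theoretical terminal ion and the
number of unassigned observed masses matching the shifted set is counted.
Under the null (no coherently modified ion set) the count k at an offset is
Poisson with expectation lambda, the mean match count across the whole scan;
the E value

    E = lambda**k * exp(-lambda) / k! * n

(n = number of offsets evaluated) is the expected number of offsets showing
at least this surprising a count, so E < 0.01 is the working significance
cut.  The same statistic drives the quasi-continuous scan (small
modifications), the multinotch scan (termini, internal-fragment sets, i.e.
"modifications" that are backbone losses) and the decoy-offset FDR
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .chemcore import ElementalFormula, RESIDUE_MASS, formula_mass

DECOY_FORMULAS = ("H5", "H5O2", "H7O9", "H9O3")


def poisson_evalue(k: int, lam: float, n: int) -> float:
    """E value = n * Poisson pmf(k; lambda), computed in log space."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    logp = k * np.log(lam) - lam - gammaln(k + 1)
    return float(n * np.exp(logp))


def _evalues(k: np.ndarray, lam: float, n: int) -> np.ndarray:
    if lam <= 0:
        # degenerate all-zero scan: pmf(0; 0) = 1
        return np.where(k == 0, float(n), 0.0)
    logp = k * np.log(lam) - lam - gammaln(k + 1)
    return n * np.exp(logp)


@dataclass
class OffsetScanResult:
    """Match counts, Poisson expectation and E-values over an offset grid/notch list."""

    offsets: np.ndarray
    k: np.ndarray
    lam: float
    n: int
    evalues: np.ndarray
    significant: list = field(default_factory=list)  # (offset, k, evalue) after collapsing
    labels: list | None = None  # notch labels, when applicable

    def significant_offsets(self) -> np.ndarray:
        return np.array([s[0] for s in self.significant])


def _match_count_per_offset_grid(
    observed: np.ndarray, theo: np.ndarray, grid: np.ndarray, tol_ppm: float
) -> np.ndarray:
    """k(Delta) = number of observed masses matching any shifted theoretical ion.

    Each (observed, theoretical) pair contributes the offset interval
    [d - tol, d + tol] with d = observed - theoretical and tol the ppm window
    on the observed mass; intervals of one observed ion are merged so an ion
    counts once per offset.  Counting is by interval-coverage difference
    arrays, linear in pairs.
    """
    lo, hi = grid[0], grid[-1]
    step = grid[1] - grid[0] if len(grid) > 1 else 1.0
    diff = np.zeros(len(grid) + 1)
    theo_sorted = np.sort(theo)
    for m in observed:
        tol = tol_ppm * 1e-6 * abs(m)
        i, j = np.searchsorted(theo_sorted, [m - hi - tol, m - lo + tol])
        if j <= i:
            continue
        deltas = m - theo_sorted[i:j][::-1]  # ascending
        starts = deltas - tol
        ends = deltas + tol
        # merge overlapping intervals of this ion
        merged_s, merged_e = [starts[0]], [ends[0]]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        for s, e in zip(merged_s, merged_e):
            a = int(np.ceil((s - lo) / step))
            b = int(np.floor((e - lo) / step)) + 1
            a = max(a, 0)
            b = min(b, len(grid))
            if b > a:
                diff[a] += 1
                diff[b] -= 1
    return np.cumsum(diff[:-1])


def continuous_offset_scan(
    observed: np.ndarray,
    theoretical: np.ndarray,
    lo: float,
    hi: float,
    tol_ppm: float = 3.0,
    evalue_threshold: float = 0.01,
    oversampling: int = 4,
) -> OffsetScanResult:
    """Quasi-continuous offset scan over [lo, hi] Da.

    The grid step is the ppm tolerance at the median theoretical mass divided
    by the oversampling factor (sliding-window oversampling of the offset
    domain).  Adjacent significant grid points are collapsed to the local
    match-count maximum and the reported offset is refined to the median
    matched-mass delta, so sub-tolerance (mDa-level) offset annotation is
    meaningful.
    """
    theoretical = np.asarray(theoretical, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(theoretical) == 0:
        raise ValueError("empty theoretical ion set")
    if hi - lo > 5000.0:
        raise ValueError(
            "continuous scans are limited to ranges <= 5000 Da; use the "
            "multinotch search for broader offsets"
        )
    step = np.median(theoretical) * tol_ppm * 1e-6 / oversampling
    grid = np.arange(lo, hi + step, step)
    k = _match_count_per_offset_grid(observed, theoretical, grid, tol_ppm)
    lam = float(k.mean())
    n = len(grid)
    ev = _evalues(k, lam, n)
    sig_mask = ev < evalue_threshold
    significant = []
    if sig_mask.any():
        idx = np.flatnonzero(sig_mask)
        splits = np.flatnonzero(np.diff(idx) > 1)
        for run in np.split(idx, splits + 1):
            best = run[np.argmax(k[run])]
            refined = _refine_offset(observed, theoretical, grid[best], tol_ppm)
            significant.append((refined, int(k[best]), float(ev[best])))
    return OffsetScanResult(
        offsets=grid, k=k, lam=lam, n=n, evalues=ev, significant=significant
    )


def _refine_offset(observed, theoretical, delta, tol_ppm) -> float:
    """Median matched-mass delta at a candidate offset."""
    theo_sorted = np.sort(theoretical)
    deltas = []
    for m in observed:
        tol = tol_ppm * 1e-6 * abs(m)
        i, j = np.searchsorted(theo_sorted, [m - delta - tol, m - delta + tol])
        if j > i:
            cand = m - theo_sorted[i:j]
            deltas.append(cand[np.argmin(np.abs(cand - delta))])
    return float(np.median(deltas)) if deltas else float(delta)


def match_observed(observed, theoretical, delta, tol_ppm):
    """Indices of observed masses matching any theoretical + delta, with best theo index."""
    theo_sorted_idx = np.argsort(theoretical)
    theo_sorted = np.asarray(theoretical)[theo_sorted_idx]
    hits = []
    for oi, m in enumerate(observed):
        tol = tol_ppm * 1e-6 * abs(m)
        i, j = np.searchsorted(theo_sorted, [m - delta - tol, m - delta + tol])
        if j > i:
            errs = np.abs(m - delta - theo_sorted[i:j])
            best = i + int(np.argmin(errs))
            hits.append((oi, int(theo_sorted_idx[best]), float(m - theo_sorted[best])))
    return hits


def multinotch_scan(
    observed: np.ndarray,
    notches: list[tuple[str, float]],
    theoretical: np.ndarray,
    tol_ppm: float = 3.0,
    evalue_threshold: float = 0.01,
) -> OffsetScanResult:
    """Discrete-notch variant of the offset scan, same statistical contract.

    ``notches`` are (label, offset Da) pairs, e.g. successive-residue
    cumulative masses for termini discovery or backbone-loss masses for
    internal-fragment sets.  lambda is the mean match count across notches
    and n the notch count.
    """
    if not notches:
        raise ValueError("notch list is empty")
    labels = [l for l, _ in notches]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate notch labels")
    offs = np.array([m for _, m in notches], dtype=float)
    order = np.argsort(offs)
    med_tol = tol_ppm * 1e-6 * max(np.median(np.abs(observed)) if len(observed) else 0.0, 1.0)
    if np.any(np.diff(offs[order]) < med_tol):
        raise ValueError("notch masses closer than the matching tolerance are ambiguous")
    observed = np.asarray(observed, dtype=float)
    theoretical = np.asarray(theoretical, dtype=float)
    k = np.zeros(len(offs), dtype=int)
    for ni, delta in enumerate(offs):
        k[ni] = len(match_observed(observed, theoretical, delta, tol_ppm))
    lam = float(k.mean())
    n = len(offs)
    ev = _evalues(k, lam, n)
    significant = [
        (float(offs[i]), int(k[i]), float(ev[i]))
        for i in np.flatnonzero(ev < evalue_threshold)
    ]
    return OffsetScanResult(
        offsets=offs, k=k, lam=lam, n=n, evalues=ev, significant=significant,
        labels=labels,
    )


@dataclass
class InternalAssignment:
    observed_index: int
    start: int  # 1-based first residue
    end: int  # 1-based last residue
    shared_side: str  # 'N' or 'C'
    error_ppm: float


@dataclass
class InternalFragmentSet:
    shared_side: str
    shared_index: int  # 1-based residue at the shared cleavage
    evalue: float
    members: list[InternalAssignment] = field(default_factory=list)


def _prefix_masses(seq: str) -> np.ndarray:
    res = np.array([RESIDUE_MASS[aa] for aa in seq])
    return np.concatenate([[0.0], np.cumsum(res)])


def internal_fragment_search(
    observed: np.ndarray,
    sequence: str,
    tol_ppm: float = 3.0,
    evalue_threshold: float = 0.01,
    evidenced_sites: set[int] | None = None,
    apply_filter: bool = True,
) -> tuple[list[InternalFragmentSet], list[InternalAssignment], OffsetScanResult, OffsetScanResult]:
    """Shared-termini internal-fragment discovery via two multinotch scans.

    Internal b/y-type fragments spanning residues [i, j] are residue-sum
    masses; a set sharing the N-side cleavage before residue i appears as the
    backbone-loss notch -prefix(i-1) applied to terminal b ions (and
    symmetrically for shared C-side sets against y ions).  With
    ``apply_filter`` only sets with E < threshold yield assignments — the
    shared-termini filter; without it every notch's matches are assigned,
    which is the uncontrolled search used for comparison.
    """
    seq = sequence
    n = len(seq)
    prefix = _prefix_masses(seq)
    from .chemcore import WATER

    b_theo = prefix[1:n]  # b_i = prefix i
    y_theo = (prefix[n] - prefix[: n - 1])[::-1] + WATER  # y_1 .. y_{n-1}

    # shared-N sets: internal [i, j] = b_j - prefix(i-1); notch label = start residue i
    notches_N = [(f"N{i}", -float(prefix[i - 1])) for i in range(2, n - 3)]
    scan_N = multinotch_scan(observed, notches_N, b_theo, tol_ppm, evalue_threshold)
    # shared-C sets: internal [i, j] = y_{n-i+1} - water - suffix(j+1..n); notch = end residue j
    notches_C = [
        (f"C{j}", -float(prefix[n] - prefix[j]) - WATER) for j in range(4, n - 1)
    ]
    scan_C = multinotch_scan(observed, notches_C, y_theo, tol_ppm, evalue_threshold)

    sets: list[InternalFragmentSet] = []
    candidates: dict[int, list[tuple]] = {}

    def collect(scan, side):
        for ni, (label, delta) in enumerate(zip(scan.labels, scan.offsets)):
            ev = float(scan.evalues[ni])
            significant = ev < evalue_threshold
            if apply_filter and not significant:
                continue
            site = int(label[1:])
            theo = b_theo if side == "N" else y_theo
            hits = match_observed(observed, theo, delta, tol_ppm)
            if not hits:
                continue
            fs = InternalFragmentSet(shared_side=side, shared_index=site, evalue=ev)
            for oi, ti, dmass in hits:
                if side == "N":
                    start, end = site, ti + 1  # b index ti+1 -> last residue
                else:
                    start, end = n - (ti + 1) + 1, site
                if end <= start:
                    continue
                theo_mass = (prefix[end] - prefix[start - 1]) + (0.0)
                err_ppm = (observed[oi] - theo_mass) / theo_mass * 1e6
                cand = (oi, start, end, side, err_ppm, significant)
                candidates.setdefault(oi, []).append(cand)
                fs.members.append(
                    InternalAssignment(oi, start, end, side, err_ppm)
                )
            if fs.members:
                sets.append(fs)

    collect(scan_N, "N")
    collect(scan_C, "C")

    assignments: list[InternalAssignment] = []
    for oi, cands in candidates.items():
        chosen = resolve_degenerate(cands, evidenced_sites or set())
        assignments.append(
            InternalAssignment(chosen[0], chosen[1], chosen[2], chosen[3], chosen[4])
        )
    if apply_filter:
        sets = [s for s in sets if s.evalue < evalue_threshold]
    return sets, assignments, scan_N, scan_C


def resolve_degenerate(candidates: list[tuple], evidenced_sites: set[int]):
    """Deterministic priority among degenerate internal-fragment candidates.

    (1) a shared cleavage site already evidenced by an assigned terminal ion
    wins; (2) then the smaller |ppm error|; (3) then the shorter fragment.
    """
    if not candidates:
        raise ValueError("no candidates")

    def key(c):
        _oi, start, end, side, err_ppm = c[:5]
        site = start if side == "N" else end
        return (
            0 if site in evidenced_sites else 1,
            round(abs(err_ppm), 9),
            end - start,
            start,
            side,
        )

    return sorted(candidates, key=key)[0]


@dataclass
class FdrReport:
    decoy_formulas: tuple
    per_notch_target: np.ndarray
    per_notch_decoy_mean: np.ndarray
    fdr_unfiltered: float | None
    fdr_filtered: float | None
    note: str = ""


def estimate_fdr(
    observed: np.ndarray,
    notches: list[tuple[str, float]],
    theoretical: np.ndarray,
    tol_ppm: float = 3.0,
    evalue_threshold: float = 0.01,
    decoy_formulas: tuple = DECOY_FORMULAS,
) -> FdrReport:
    """Decoy-offset FDR for a multinotch search.

    Unfiltered: mean over notches (with >= 1 target match) of the
    decoy/target match ratio, averaged over decoy formulas.  Filtered: the
    mean decoy match count per notch times the number of significant target
    notches, divided by the target matches within those notches.  Both are
    capped at 1.
    """
    target = multinotch_scan(observed, notches, theoretical, tol_ppm, evalue_threshold)
    decoy_ks = []
    for f in decoy_formulas:
        dm = formula_mass(ElementalFormula.parse(f))
        shifted = np.asarray(theoretical, dtype=float) + dm
        scan = multinotch_scan(observed, notches, shifted, tol_ppm, evalue_threshold)
        decoy_ks.append(scan.k)
    decoy_ks = np.array(decoy_ks, dtype=float)
    tk = target.k.astype(float)
    per_notch_decoy_mean = decoy_ks.mean(axis=0)

    if tk.sum() == 0:
        return FdrReport(
            tuple(decoy_formulas), tk, per_notch_decoy_mean, None, None,
            note="zero target matches: FDR undefined",
        )
    nonzero = tk > 0
    ratios = decoy_ks[:, nonzero] / tk[nonzero]
    fdr_unfiltered = float(min(1.0, ratios.mean()))

    sig = target.evalues < evalue_threshold
    n_sig = int(sig.sum())
    target_in_sig = tk[sig].sum()
    if n_sig == 0 or target_in_sig == 0:
        fdr_filtered = 0.0 if decoy_ks.sum() == 0 else None
        note = "no significant notches" if n_sig == 0 else ""
    else:
        expected_false = per_notch_decoy_mean.mean() * n_sig
        fdr_filtered = float(min(1.0, expected_false / target_in_sig))
        note = ""
    return FdrReport(
        tuple(decoy_formulas), tk, per_notch_decoy_mean, fdr_unfiltered, fdr_filtered,
        note=note,
    )


@dataclass
class LocalizationMap:
    """Per-cleavage modification evidence and the implied residue interval."""

    terminus: str  # which terminal series carried the evidence
    modified_indices: list  # ion indices assigned with the offset
    unmodified_indices: list
    interval: tuple[int, int] | None  # 1-based inclusive residue interval


def localize_modification(
    observed: np.ndarray,
    sequence_length: int,
    terminal_masses: np.ndarray,
    offset: float,
    terminus: str,
    unmodified_indices: list[int],
    tol_ppm: float = 3.0,
) -> LocalizationMap:
    """Smallest residue interval containing a significant modification.

    ``terminal_masses[i]`` is the unmodified theoretical mass of the ion with
    cleavage index i+1 for the stated terminus; ions matching mass + offset
    are modified.  For C-terminal ions the modification lies between the
    smallest modified index's span start and the largest unmodified index
    that is still smaller than it (symmetrically for N-terminal ions).
    """
    hits = match_observed(observed, terminal_masses, offset, tol_ppm)
    modified = sorted({ti + 1 for _oi, ti, _d in hits})
    unmod = sorted(set(unmodified_indices))
    if not modified:
        return LocalizationMap(terminus, [], unmod, None)
    k_min = min(modified)
    n = sequence_length
    below = [k for k in unmod if k < k_min]
    if terminus == "C":
        lowerb = n - k_min + 1
        upperb = n - max(below) if below else n
        interval = (lowerb, upperb)
    else:
        upperb = k_min
        lowerb = max(below) + 1 if below else 1
        interval = (lowerb, upperb)
    return LocalizationMap(terminus, modified, unmod, interval)
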