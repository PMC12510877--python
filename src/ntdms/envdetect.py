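"""Candidate isotopic-envelope detection and per-envelope feature computation.

Two complementary detectors are run over each spectrum: an iterative
subtract-and-continue detector working on the profile (averagine fitting with
charge from local isotopologue spacing, applied at several goodness-of-fit
thresholds because iterative subtraction makes threshold runs non-nesting),
and a graph-style detector that scores (peak, charge) envelope hypotheses on
a centroided spectrum and selects a best non-conflicting subset.  Candidates
from both are clustered by mass and each surviving envelope gets the
seven-feature vector used downstream by the veto classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chemcore import PROTON_MASS, averagine_formula, isotope_distribution
from .deconv import PsfModel
from .msio import CentroidPeak, ProfileSpectrum

NEUTRON_SPACING = 1.00286  # mean aggregated-isotopologue spacing, Da


@dataclass
class EnvelopeCandidate:
    """A putative fragment ion: charge, monoisotopic mass and member peaks."""

    monoisotopic_mass: float
    charge: int
    peaks: list  # (observed m/z, observed intensity, theoretical abundance)
    apex_mz: float
    apex_intensity: float
    total_intensity: float
    fit: float
    detectors: frozenset = field(default_factory=frozenset)

    @property
    def mz(self) -> float:
        return (self.monoisotopic_mass + self.charge * PROTON_MASS) / self.charge


@dataclass
class FeatureVector:
    """The per-envelope quality features used for supervised filtering."""

    snr: float
    fit_score: float
    interference: float
    missing_peak_fraction: float
    isotopologue_errors_mda: list
    chi2_stat: float
    chi2_p: float
    pearson_r: float
    pearson_p: float

    def as_array(self, charge: int, intensity: float) -> np.ndarray:
        """Training features: the seven scores plus charge and log-intensity."""
        errs = np.abs(self.isotopologue_errors_mda) if len(self.isotopologue_errors_mda) else [0.0]
        return np.array(
            [
                self.snr,
                self.fit_score,
                self.interference,
                self.missing_peak_fraction,
                float(np.mean(errs)),
                float(np.max(errs)),
                self.chi2_stat,
                self.pearson_r,
                float(charge),
                float(np.log1p(max(intensity, 0.0))),
            ]
        )


FEATURE_NAMES = [
    "snr",
    "fit_score",
    "interference",
    "missing_peak_fraction",
    "mean_abs_error_mda",
    "max_abs_error_mda",
    "chi2_stat",
    "pearson_r",
    "charge",
    "log_intensity",
]


def modal_peak_intensity(s: ProfileSpectrum) -> float:
    """Modal local-maximum intensity: the noise estimate for fragment spectra."""
    y = s.intensity
    if len(y) < 3:
        return float(max(y.max(), 1e-30)) if len(y) else 1e-30
    loc = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1
    vals = y[loc]
    vals = vals[vals > 0]
    if len(vals) == 0:
        return 1e-30
    logv = np.log10(vals)
    hist, edges = np.histogram(logv, bins=max(10, int(np.sqrt(len(vals)))))
    k = int(np.argmax(hist))
    return float(10 ** (0.5 * (edges[k] + edges[k + 1])))


_TEMPLATE_CACHE: dict[int, tuple] = {}


def _averagine_template(mass: float, min_abundance: float = 0.01):
    """Cached averagine template; masses quantised to 1% bins (template shape
    varies slowly with mass, so this costs < 0.01 Da of model error)."""
    key = int(round(np.log(max(mass, 50.0)) / np.log(1.01)))
    hit = _TEMPLATE_CACHE.get(key)
    if hit is None:
        m_rep = float(np.exp(key * np.log(1.01)))
        dist = isotope_distribution(averagine_formula(m_rep), n_peaks=120)
        keep = dist.abundances >= min_abundance * dist.abundances.max()
        offsets = dist.masses[keep] - dist.masses[0]
        hit = (offsets, dist.abundances[keep], int(np.argmax(dist.abundances[keep])))
        _TEMPLATE_CACHE[key] = hit
    return hit


def _estimate_charge(mz: np.ndarray, inten: np.ndarray, apex_idx: int, charge_max: int) -> int | None:
    """Charge from the autocorrelation of the +-1.2 Th window around the apex."""
    lo, hi = mz[apex_idx] - 1.2, mz[apex_idx] + 1.2
    i, j = np.searchsorted(mz, [lo, hi])
    x = inten[i:j]
    if len(x) < 8:
        return None
    dx = np.median(np.diff(mz[i:j]))
    xc = x - x.mean()
    ac = np.correlate(xc, xc, mode="full")[len(xc) - 1 :]
    if ac[0] <= 0:
        return None
    best_z, best_score = None, 0.05
    for z in range(1, charge_max + 1):
        lag = NEUTRON_SPACING / z / dx
        if lag < 1.5 or lag >= len(ac) - 1:
            continue
        k = int(np.floor(lag))
        frac = lag - k
        val = (1 - frac) * ac[k] + frac * ac[k + 1]
        score = val / ac[0]
        if score > best_score + 1e-9:
            best_z, best_score = z, score
    return best_z


def _local_peak(mz, inten, target, tol):
    i, j = np.searchsorted(mz, [target - tol, target + tol])
    if j <= i:
        return None, 0.0
    k = i + int(np.argmax(inten[i:j]))
    return float(mz[k]), float(inten[k])


def _fit_template(
    mz, inten, mono_mass, charge, offsets, theo, tol
) -> tuple[float, float, list, np.ndarray]:
    """Least-squares scale + bounded residual fit of an averagine template."""
    obs = np.zeros(len(theo))
    obs_mz = np.full(len(theo), np.nan)
    for t in range(len(theo)):
        target = (mono_mass + offsets[t] + charge * PROTON_MASS) / charge
        pmz, pint = _local_peak(mz, inten, target, tol)
        if pmz is not None:
            obs_mz[t], obs[t] = pmz, pint
    if obs.sum() <= 0:
        return 0.0, 0.0, [], np.array([], dtype=int)
    scale = float(obs @ theo / (theo @ theo))
    fit = max(0.0, 1.0 - np.abs(obs - scale * theo).sum() / obs.sum())
    matched = np.flatnonzero(np.isfinite(obs_mz))
    peaks = [(obs_mz[t], obs[t], theo[t]) for t in matched]
    return fit, scale, peaks, matched


def _snap_mono(mono0, charge, offsets, theo, peaks, matched) -> float:
    """Monoisotopic mass by centroid alignment to the template lattice.

    The abundance-weighted mean position of the observed peaks is compared
    with the template's weighted mean offset over the same matched bins;
    the implied continuous mono mass is snapped to the isotopologue lattice
    anchored at ``mono0``, sidestepping the off-by-one-neutron ambiguity of
    apex-based alignment on heavy ions.
    """
    if len(peaks) == 0:
        return mono0
    obs_mass = np.array([p[0] * charge - charge * PROTON_MASS for p in peaks])
    w = np.array([p[1] for p in peaks])
    mo_obs = float(np.average(obs_mass, weights=w))
    mo_t = float(np.average(offsets[matched], weights=theo[matched]))
    mono_float = mo_obs - mo_t
    k = int(round((mono0 - mono_float) / NEUTRON_SPACING))
    mono = mono0 - k * NEUTRON_SPACING
    # refine from every matched isotopologue's implied mono position
    # (a peak at mono0 + offsets[t] sits k neutrons further from mono)
    implied = obs_mass - offsets[matched] - k * NEUTRON_SPACING
    good = np.abs(implied - mono) < 0.4
    if good.any():
        mono = float(np.average(implied[good], weights=w[good]))
    return mono


def thrash_scan(
    s: ProfileSpectrum,
    fit_thresholds: tuple = (0.60, 0.70, 0.80, 0.90),
    charge_max: int = 12,
    psf: PsfModel | None = None,
    max_iter: int = 500,
) -> list[EnvelopeCandidate]:
    """Iterative most-intense-peak envelope detection at several fit thresholds.

    Per threshold: take the most intense unexplained peak, estimate the
    charge from local isotopologue spacing, fit the averagine envelope for
    the implied mass and, if the fit clears the threshold, record the
    candidate and subtract its fitted profile before continuing.  The runs
    are unioned with duplicates merged; because subtraction reorders what is
    "most intense", a strict-threshold run is not a subset of a relaxed one.
    """
    if charge_max < 1:
        raise ValueError("charge_max must be >= 1")
    if list(fit_thresholds) != sorted(fit_thresholds):
        raise ValueError("fit thresholds must be sorted ascending")
    if psf is None:
        psf = PsfModel.from_resolution()
    mz = s.mz
    # capped so sparse spectra (few local maxima) still yield their apexes
    noise_floor = min(3.0 * modal_peak_intensity(s), 0.3 * float(s.intensity.max()))
    all_runs: list[list[EnvelopeCandidate]] = []
    for thr in fit_thresholds:
        working = s.intensity.copy()
        found: list[EnvelopeCandidate] = []
        for _ in range(max_iter):
            apex = int(np.argmax(working))
            if working[apex] <= noise_floor:
                break
            apex_mz = mz[apex]
            sigma = float(psf.sigma(apex_mz))
            z = _estimate_charge(mz, working, apex, charge_max)
            cand = None
            scale = 0.0
            if z is not None:
                approx_mass = max((apex_mz - PROTON_MASS) * z, 50.0)
                offsets, theo, j0 = _averagine_template(approx_mass)
                tol = max(2 * sigma, 0.25 * NEUTRON_SPACING / z)
                mono0 = approx_mass - offsets[j0]
                fit, scale, peaks, matched = _fit_template(
                    mz, working, mono0, z, offsets, theo, tol
                )
                if peaks:
                    mono = _snap_mono(mono0, z, offsets, theo, peaks, matched)
                    if abs(mono - mono0) > 0.3:
                        fit, scale, peaks, matched = _fit_template(
                            mz, working, mono, z, offsets, theo, tol
                        )
                        mono = _snap_mono(mono, z, offsets, theo, peaks, matched)
                    if fit >= thr and len(peaks) >= 2:
                        obs_mz = np.array([p[0] for p in peaks])
                        obs_i = np.array([p[1] for p in peaks])
                        cand = EnvelopeCandidate(
                            monoisotopic_mass=mono,
                            charge=z,
                            peaks=peaks,
                            apex_mz=float(obs_mz[int(np.argmax(obs_i))]),
                            apex_intensity=float(obs_i.max()),
                            total_intensity=float(obs_i.sum()),
                            fit=fit,
                            detectors=frozenset({"thrash"}),
                        )
            if cand is not None:
                found.append(cand)
                # subtract the fitted Gaussian profile of every isotopologue
                for (pmz, _pint, ptheo) in cand.peaks:
                    amp = ptheo * scale
                    i, j = np.searchsorted(mz, [pmz - 4 * sigma, pmz + 4 * sigma])
                    if j > i:
                        working[i:j] -= amp * np.exp(
                            -0.5 * ((mz[i:j] - pmz) / sigma) ** 2
                        )
                np.clip(working, 0.0, None, out=working)
            else:
                # unexplainable apex: blank it so the scan can proceed
                i, j = np.searchsorted(mz, [apex_mz - 3 * sigma, apex_mz + 3 * sigma])
                working[i : max(j, i + 1)] = 0.0
        all_runs.append(found)
    merged = merge_candidates(all_runs, mass_tol_ppm=5.0)
    return merged


def graph_select(
    peaks: list[CentroidPeak],
    charge_max: int = 12,
    tol_ppm: float = 10.0,
    min_matched: int = 3,
) -> list[EnvelopeCandidate]:
    """Graph-style envelope selection from a centroided spectrum.

    Every (peak, charge) pair seeds an averagine envelope hypothesis; each
    hypothesis gets an additive score rewarding matched-peak count, intensity
    agreement and m/z agreement.  A best non-conflicting set (no centroid
    explained twice) is then chosen greedily by score, which is the weighted
    interval-scheduling behaviour specialised to shared peaks.
    """
    if not peaks:
        return []
    pk_mz = np.array([p.mz for p in peaks])
    pk_int = np.array([p.intensity for p in peaks])
    hypotheses = []
    for pi in range(len(peaks)):
        for z in range(1, charge_max + 1):
            approx_mass = (pk_mz[pi] - PROTON_MASS) * z
            if approx_mass < 100:
                continue
            offsets, theo, j0 = _averagine_template(approx_mass)
            mono = approx_mass - offsets[j0]
            tol = max(tol_ppm * 1e-6 * pk_mz[pi], 2e-4)
            matched_idx, obs, obs_mz, theo_m = [], [], [], []
            for t in range(len(theo)):
                target = (mono + offsets[t] + z * PROTON_MASS) / z
                i, j = np.searchsorted(pk_mz, [target - tol, target + tol])
                if j <= i:
                    continue
                k = i + int(np.argmax(pk_int[i:j]))
                matched_idx.append(k)
                obs.append(pk_int[k])
                obs_mz.append(pk_mz[k])
                theo_m.append((t, target))
            need = min(min_matched, max(2, int((theo >= 0.2 * theo.max()).sum())))
            if len(set(matched_idx)) < need or pi not in matched_idx:
                continue
            obs = np.array(obs)
            theo_sel = np.array([theo[t] for t, _ in theo_m])
            scale = float(obs @ theo_sel / (theo_sel @ theo_sel))
            score = 0.0
            for k, o, (t, target), om in zip(matched_idx, obs, theo_m, obs_mz):
                mz_term = 1.0 - abs(om - target) / tol
                int_term = 1.0 - min(
                    1.0, abs(o - scale * theo[t]) / max(o, scale * theo[t])
                )
                score += np.sqrt(o) * (0.4 + 0.3 * mz_term + 0.3 * int_term)
            peaks_list = [
                (om, o, theo[t]) for (t, _), om, o in zip(theo_m, obs_mz, obs)
            ]
            matched_bins = np.array([t for t, _ in theo_m], dtype=int)
            mono_ref = _snap_mono(mono, z, offsets, theo, peaks_list, matched_bins)
            fit = max(0.0, 1.0 - np.abs(obs - scale * theo_sel).sum() / obs.sum())
            hypotheses.append(
                (
                    score,
                    EnvelopeCandidate(
                        monoisotopic_mass=mono_ref,
                        charge=z,
                        peaks=peaks_list,
                        apex_mz=float(obs_mz[int(np.argmax(obs))]),
                        apex_intensity=float(obs.max()),
                        total_intensity=float(obs.sum()),
                        fit=fit,
                        detectors=frozenset({"graph"}),
                    ),
                    frozenset(matched_idx),
                )
            )
    hypotheses.sort(key=lambda h: (-h[0], h[1].charge, h[1].monoisotopic_mass))
    used: set[int] = set()
    selected: list[EnvelopeCandidate] = []
    for _score, cand, pk_set in hypotheses:
        if pk_set & used:
            continue
        used |= pk_set
        selected.append(cand)
    selected.sort(key=lambda c: c.monoisotopic_mass)
    return selected


def compute_envelope_features(
    e: EnvelopeCandidate,
    s: ProfileSpectrum,
    psf: PsfModel | None = None,
    noise_level: float | None = None,
) -> FeatureVector:
    """The seven quality features of an envelope against its parent spectrum.

    ``noise_level`` (the spectrum's modal peak intensity) may be precomputed
    once per spectrum and passed in when scoring many envelopes.
    """
    if psf is None:
        psf = PsfModel.from_resolution()
    if not e.peaks:
        raise ValueError("envelope has no member peaks")
    pk_mz = np.array([p[0] for p in e.peaks])
    if pk_mz.min() < s.mz[0] - 1 or pk_mz.max() > s.mz[-1] + 1:
        raise ValueError("envelope lies outside the spectrum range")
    obs = np.array([p[1] for p in e.peaks])
    theo = np.array([p[2] for p in e.peaks])
    scale = float(obs @ theo / (theo @ theo)) if theo.any() else 0.0
    fit = max(0.0, 1.0 - np.abs(obs - scale * theo).sum() / obs.sum()) if obs.sum() else 0.0

    if noise_level is None:
        noise_level = modal_peak_intensity(s)
    snr = e.apex_intensity / noise_level

    sigma = float(psf.sigma(e.apex_mz))
    span_lo, span_hi = pk_mz.min() - 3 * sigma, pk_mz.max() + 3 * sigma
    _smz, sint = s.slice(span_lo, span_hi)
    total_in_span = float(sint.sum())
    dx = np.median(np.diff(s.mz)) if len(s.mz) > 1 else 1.0
    model_area = scale * theo.sum() * np.sqrt(2 * np.pi) * sigma / dx
    interference = min(1.0, model_area / total_in_span) if total_in_span > 0 else 0.0

    # expected isotopologues >= 1% for the implied averagine mass
    offsets, theo_full, _ = _averagine_template(max(e.monoisotopic_mass, 50.0))
    expected_mz = (e.monoisotopic_mass + offsets + e.charge * PROTON_MASS) / e.charge
    tol = max(2 * sigma, 0.25 * NEUTRON_SPACING / e.charge)
    present = np.array(
        [np.any(np.abs(pk_mz - m) <= tol) for m in expected_mz]
    )
    missing_fraction = float(1.0 - present.mean())

    errors_mda = []
    for pmz in pk_mz:
        t = int(np.argmin(np.abs(expected_mz - pmz)))
        errors_mda.append((pmz - expected_mz[t]) * e.charge * 1000.0)

    exp_counts = np.maximum(scale * theo, 1e-12)
    chi2_stat = float(((obs - scale * theo) ** 2 / exp_counts).sum())
    dof = max(len(obs) - 1, 1)
    chi2_p = float(stats.chi2.sf(chi2_stat, dof))
    if len(obs) >= 3 and np.std(obs) > 0 and np.std(theo) > 0:
        r, p = stats.pearsonr(theo, obs)
    else:
        r, p = (1.0, 0.0) if len(obs) >= 2 else (0.0, 1.0)
    return FeatureVector(
        snr=float(snr),
        fit_score=float(fit),
        interference=float(interference),
        missing_peak_fraction=missing_fraction,
        isotopologue_errors_mda=errors_mda,
        chi2_stat=chi2_stat,
        chi2_p=chi2_p,
        pearson_r=float(np.clip(r, -1, 1)),
        pearson_p=float(p),
    )


def merge_candidates(
    lists: list[list[EnvelopeCandidate]], mass_tol_ppm: float = 5.0
) -> list[EnvelopeCandidate]:
    """Single-linkage clustering on (charge, mass); best-fit representative kept."""
    flat = [c for sub in lists for c in sub]
    if not flat:
        return []
    out: list[EnvelopeCandidate] = []
    by_charge: dict[int, list[EnvelopeCandidate]] = {}
    for c in flat:
        by_charge.setdefault(c.charge, []).append(c)
    for z, group in sorted(by_charge.items()):
        group.sort(key=lambda c: c.monoisotopic_mass)
        cluster = [group[0]]
        for c in group[1:]:
            prev = cluster[-1]
            tol = mass_tol_ppm * 1e-6 * prev.monoisotopic_mass
            if c.monoisotopic_mass - prev.monoisotopic_mass <= tol:
                cluster.append(c)
            else:
                out.append(_cluster_representative(cluster))
                cluster = [c]
        out.append(_cluster_representative(cluster))
    out.sort(key=lambda c: (c.monoisotopic_mass, c.charge))
    return out


def _cluster_representative(cluster: list[EnvelopeCandidate]) -> EnvelopeCandidate:
    best = max(cluster, key=lambda c: c.fit)
    detectors = frozenset().union(*(c.detectors for c in cluster))
    return EnvelopeCandidate(
        monoisotopic_mass=best.monoisotopic_mass,
        charge=best.charge,
        peaks=best.peaks,
        apex_mz=best.apex_mz,
        apex_intensity=best.apex_intensity,
        total_intensity=best.total_intensity,
        fit=best.fit,
        detectors=detectors,
    )
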