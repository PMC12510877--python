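"""Ground-truth simulator for native top-down fragment spectra.

Synthesizes FT-style profile MS2 spectra with planted isotopic envelopes —
terminal sequence ions, their common variants (dehydration, deamidation,
sodiation), modified-fragment subsets at known mass offsets, internal
fragments sharing terminal cleavage sites, averagine-shaped artifact
envelopes and harmonic ghosts — plus linear calibration drift and additive
noise.  Every planted species is recorded so detection, assignment, open
search and quantification can be scored against known truth.

The default acquisition regime emulates an FT analyzer at resolving power
240,000 at m/z 200 with profile spectra exported over m/z 800-4000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _pmass

from .chemcore import (
    PROTON_MASS,
    WATER,
    ElementalFormula,
    IsotopicDistribution,
    Modification,
    Proteoform,
    builtin_modifications,
    enumerate_terminal_ions,
    isotope_distribution,
    averagine_formula,
    RESIDUE_MASS,
)
from .deconv import PsfModel
from .msio import ProfileSpectrum

_MODS = {m.name: m for m in builtin_modifications()}

VARIANT_OFFSETS = {
    "dehydration": -WATER,
    "deamidation": 0.98401587,
    "sodiation": 21.98194425,
}


def sequence_formula(seq: str, water: bool = False) -> ElementalFormula:
    """Elemental composition of a residue stretch (optionally plus water)."""
    comp: dict[str, int] = {}
    for aa in seq:
        for el, n in _pmass.std_aa_comp[aa].items():
            comp[el] = comp.get(el, 0) + n
    if water:
        comp["H"] = comp.get("H", 0) + 2
        comp["O"] = comp.get("O", 0) + 1
    return ElementalFormula(comp)


@dataclass
class TruthIon:
    """One planted envelope and its identity."""

    kind: str  # terminal | variant | modified | internal | artifact
    series: str | None
    index: int | None
    charge: int
    modification: str | None
    neutral_mass: float  # theoretical neutral mass (no drift)
    observed_mass: float  # mass actually rendered (drift + mass noise)
    intensity: float
    span: tuple[int, int] | None = None  # residue interval for internals

    @property
    def is_real(self) -> bool:
        return self.kind != "artifact"


@dataclass
class GroundTruth:
    ions: list[TruthIon]
    drift: tuple[float, float]  # observed_mz = mz + a + b * mz
    mixture_fractions: dict = field(default_factory=dict)
    proteoform: Proteoform | None = None


@dataclass
class SimulationSpec:
    """Study conditions for one simulated fragment spectrum."""

    proteoform: Proteoform
    series: tuple[str, ...] = ("b", "y")
    n_sites: int = 45  # backbone cleavage sites observed
    asp_enhanced: bool = True  # D|X cleavage propensity boost
    site_probabilities: tuple | None = None  # overrides the per-site model
    charge_max: int = 10
    mz_range: tuple[float, float] = (800.0, 4000.0)
    grid_step: float = 0.001
    resolution: float = 240_000.0
    variant_rates: dict = field(
        default_factory=lambda: {"dehydration": 0.15, "deamidation": 0.1, "sodiation": 0.1}
    )
    internal_rate: float = 0.0
    internal_shared_sites: tuple[int, ...] = ()
    modified_site: int | None = None  # residue carrying the PTM mixture
    modified_species: dict = field(default_factory=dict)  # mod name -> fraction
    modified_min_index: int | None = None  # smallest C-terminal index carrying the mod
    forced_sites: tuple[int, ...] = ()  # cleavage sites always observed
    drift: tuple[float, float] = (0.0, 0.0)
    mass_error_ppm_sd: float = 0.3
    base_intensity: float = 100.0
    noise_sigma: float = 1.0
    n_artifacts: int = 25
    seed: int = 0


def render_profile(
    ions: list[tuple[float, int, float, IsotopicDistribution | None]],
    mz_range: tuple[float, float],
    grid_step: float,
    psf: PsfModel,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ProfileSpectrum:
    """Render (neutral mass, charge, intensity, distribution) species on a grid.

    Each isotopologue becomes a Gaussian of the PSF width; ``intensity`` is
    the apex height of the most abundant isotopologue.  ``distribution``
    defaults to the averagine pattern for the mass.
    """
    lo, hi = mz_range
    grid = np.arange(lo, hi, grid_step)
    out = np.zeros_like(grid)
    for neutral_mass, z, inten, dist in ions:
        if dist is None:
            dist = isotope_distribution(averagine_formula(neutral_mass), n_peaks=80)
        ab = dist.abundances / dist.abundances.max()
        offsets = dist.masses - dist.masses[0]
        for off, a in zip(offsets, ab):
            if a < 0.005:
                continue
            mz = (neutral_mass + off + z * PROTON_MASS) / z
            if not (lo < mz < hi):
                continue
            sigma = float(psf.sigma(mz))
            i, j = np.searchsorted(grid, [mz - 5 * sigma, mz + 5 * sigma])
            if j > i:
                out[i:j] += inten * a * np.exp(-0.5 * ((grid[i:j] - mz) / sigma) ** 2)
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        out += np.abs(rng.normal(0.0, noise_sigma, len(grid)))
    return ProfileSpectrum(mz=grid, intensity=out)


def _site_probabilities(seq: str, asp_enhanced: bool) -> np.ndarray:
    p = np.ones(len(seq) - 1)
    if asp_enhanced:
        for i in range(len(seq) - 1):
            if seq[i] == "D":
                p[i] *= 4.0
            if seq[i + 1] == "P":
                p[i] *= 2.0
    return p / p.sum()


def _ion_distribution(p: Proteoform, series: str, index: int, extra: Modification | None = None):
    seq = p.active_sequence
    if series in ("b", "c"):
        sub = seq[:index]
        water = series == "c"  # c = b + NH3; handled via mass, pattern approx below
    else:
        sub = seq[-index:]
        water = True
    f = sequence_formula(sub, water=water)
    if extra is not None and extra.formula is not None:
        f = f + extra.formula
    return isotope_distribution(f, n_peaks=80)


def _choose_charge(mass: float, rng: np.random.Generator, mz_range, charge_max: int) -> int | None:
    lo, hi = mz_range
    feasible = [
        z
        for z in range(1, charge_max + 1)
        if lo + 2 < (mass + z * PROTON_MASS) / z < hi - 2
    ]
    if not feasible:
        return None
    # favour mid-window m/z, as charge reduction of native precursors does
    weights = np.array(
        [1.0 / (1.0 + abs((mass + z * PROTON_MASS) / z - 0.5 * (lo + hi)) / 800.0) for z in feasible]
    )
    return int(rng.choice(feasible, p=weights / weights.sum()))


def simulate_fragment_spectrum(spec: SimulationSpec) -> tuple[ProfileSpectrum, GroundTruth]:
    """Draw cleavage sites, charges and variants; render the profile spectrum."""
    rng = np.random.default_rng(spec.seed)
    p = spec.proteoform
    seq = p.active_sequence
    n = len(seq)
    if spec.site_probabilities is not None:
        probs = np.asarray(spec.site_probabilities, dtype=float)
        if probs.sum() <= 0:
            raise ValueError("zero cleavage probability everywhere")
        probs = probs / probs.sum()
    else:
        probs = _site_probabilities(seq, spec.asp_enhanced)
    n_sites = min(spec.n_sites, n - 1)
    sites = set(rng.choice(np.arange(1, n), size=n_sites, replace=False, p=probs))
    sites.update(spec.forced_sites)
    psf = PsfModel.from_resolution(spec.resolution)
    a_drift, b_drift = spec.drift

    mods = dict(spec.modified_species)
    truth_ions: list[TruthIon] = []
    render_list = []

    def plant(kind, series, index, z, mod_name, mass, inten, dist, span=None):
        ppm_err = rng.normal(0.0, spec.mass_error_ppm_sd) * 1e-6
        mz_t = (mass + z * PROTON_MASS) / z
        mz_obs = mz_t * (1 + ppm_err) + a_drift + b_drift * mz_t
        obs_mass = mz_obs * z - z * PROTON_MASS
        render_list.append((obs_mass, z, inten, dist))
        truth_ions.append(
            TruthIon(
                kind=kind,
                series=series,
                index=index,
                charge=z,
                modification=mod_name,
                neutral_mass=mass,
                observed_mass=obs_mass,
                intensity=inten,
                span=span,
            )
        )

    theo = {
        (ion.series, ion.index): ion
        for ion in enumerate_terminal_ions(p, spec.series, (1, 1))
    }
    for site in sorted(sites):
        for s in spec.series:
            index = site if s in ("b", "c") else n - site
            ion = theo.get((s, index))
            if ion is None:
                continue
            inten = spec.base_intensity * rng.lognormal(0.0, 0.8)
            is_c_side = s in ("y", "z")
            mod_rel = (
                spec.modified_site - p.span[0] + 1 if spec.modified_site is not None else None
            )
            if mod_rel is not None and not is_c_side and index >= mod_rel:
                continue  # N-terminal ions spanning the site: out of this sim's scope
            covers_mod = (
                mod_rel is not None and is_c_side and index >= (n - mod_rel + 1)
            )
            if covers_mod and mods:
                if spec.modified_min_index is not None and index < spec.modified_min_index:
                    continue
                z = _choose_charge(ion.neutral_mass + 250.0, rng, spec.mz_range, spec.charge_max)
                if z is None:
                    continue
                for mod_name, frac in mods.items():
                    mod = _MODS[mod_name]
                    dist = _ion_distribution(p, s, index, extra=mod)
                    plant(
                        "modified", s, index, z, mod_name,
                        ion.neutral_mass + mod.delta_mass, inten * frac, dist,
                    )
            else:
                z = _choose_charge(ion.neutral_mass, rng, spec.mz_range, spec.charge_max)
                if z is None:
                    continue
                dist = _ion_distribution(p, s, index)
                plant("terminal", s, index, z, None, ion.neutral_mass, inten, dist)
                for vname, rate in spec.variant_rates.items():
                    if rng.random() < rate:
                        plant(
                            "variant", s, index, z, vname,
                            ion.neutral_mass + VARIANT_OFFSETS[vname],
                            inten * rng.uniform(0.2, 0.5), dist,
                        )
                if spec.internal_rate and spec.internal_shared_sites and s in ("b", "c"):
                    # secondary y-type cleavage of the b ion at a hot site h
                    # yields the internal piece [h, index]; internals formed
                    # at the same hot site share their N-side cleavage
                    if rng.random() < spec.internal_rate:
                        hot = [h for h in spec.internal_shared_sites if h + 3 <= index]
                        if hot:
                            h = int(rng.choice(hot))
                            sub = seq[h - 1 : index]
                            f = sequence_formula(sub, water=False)
                            m_int = float(sum(RESIDUE_MASS[aa] for aa in sub))
                            zi = _choose_charge(m_int, rng, spec.mz_range, spec.charge_max)
                            if zi is not None:
                                plant(
                                    "internal", None, None, zi, None, m_int,
                                    inten * rng.uniform(0.2, 0.6),
                                    isotope_distribution(f, n_peaks=80),
                                    span=(h, index),
                                )
    # artifact envelopes: averagine impostors plus half-charge harmonic ghosts
    for _ in range(spec.n_artifacts):
        z = int(rng.integers(1, spec.charge_max + 1))
        mz = rng.uniform(*spec.mz_range)
        mass = (mz - PROTON_MASS) * z
        inten = spec.base_intensity * rng.lognormal(-1.2, 0.6)
        if rng.random() < 0.3 and z >= 2:
            z = max(1, z // 2)  # ghost at half charge: wrong spacing for its mass
        plant("artifact", None, None, z, None, mass, inten, None)

    spectrum = render_profile(
        render_list, spec.mz_range, spec.grid_step, psf, spec.noise_sigma, rng
    )
    truth = GroundTruth(
        ions=truth_ions,
        drift=spec.drift,
        mixture_fractions=dict(spec.modified_species),
        proteoform=p,
    )
    return spectrum, truth


def match_candidate_to_truth(candidate, truth: GroundTruth, tol_ppm: float = 5.0):
    """The truth record (if any) matching a detected envelope by mass+charge."""
    best, best_err = None, None
    for t in truth.ions:
        if t.charge != candidate.charge:
            continue
        err = abs(candidate.monoisotopic_mass - t.observed_mass)
        if err <= tol_ppm * 1e-6 * t.observed_mass and (best_err is None or err < best_err):
            best, best_err = t, err
    return best


def make_labeled_training_set(
    truth: GroundTruth,
    candidates,
    features,
    size: int = 150,
    tol_ppm: float = 5.0,
    seed: int = 0,
):
    """Label candidates against truth and sample a stratified subset.

    Stands in for manual labelling of a representative envelope set; the
    default subset size of 150 sits inside the 100-200 envelopes a user
    would typically review per spectrum.
    """
    from .envfilter import LabeledEnvelope

    rng = np.random.default_rng(seed)
    labeled = []
    for cand, feat in zip(candidates, features):
        t = match_candidate_to_truth(cand, truth, tol_ppm)
        labeled.append(
            LabeledEnvelope(candidate=cand, features=feat, label=bool(t is not None and t.is_real))
        )
    pos = [l for l in labeled if l.label]
    neg = [l for l in labeled if not l.label]
    n_pos = min(len(pos), size // 2)
    n_neg = min(len(neg), size - n_pos)
    n_pos = min(len(pos), size - n_neg)
    chosen = list(rng.choice(len(pos), n_pos, replace=False)) if n_pos else []
    out = [pos[i] for i in chosen]
    chosen = list(rng.choice(len(neg), n_neg, replace=False)) if n_neg else []
    out += [neg[i] for i in chosen]
    rng.shuffle(out)
    return out


# ---------------------------------------------------------------------------
# mass-list simulators for the open-search statistics (no profile rendering)
# ---------------------------------------------------------------------------


# typical vertebrate amino-acid frequencies (percent); keeps the elemental
# composition (notably sulfur content) of simulated proteins realistic
_AA_FREQ = {
    "A": 7.4, "R": 4.2, "N": 4.4, "D": 5.9, "C": 1.9, "E": 5.8, "Q": 3.7,
    "G": 7.4, "H": 2.9, "I": 3.8, "L": 7.6, "K": 7.2, "M": 1.8, "F": 4.0,
    "P": 5.0, "S": 8.1, "T": 6.2, "W": 1.3, "Y": 3.3, "V": 6.8,
}


def random_sequence(length: int, seed: int, force: dict[int, str] | None = None) -> str:
    """Reproducible random protein sequence at natural residue frequencies."""
    rng = np.random.default_rng(seed)
    letters = sorted(_AA_FREQ)
    p = np.array([_AA_FREQ[a] for a in letters])
    seq = list(rng.choice(letters, size=length, p=p / p.sum()))
    if force:
        for pos, aa in force.items():
            seq[pos - 1] = aa
    return "".join(seq)


def random_mass_list(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    return np.sort(rng.uniform(lo, hi, n))


def planted_offset_dataset(
    seed: int,
    offset: float = 79.96633,
    n_planted: int = 12,
    n_random: int = 200,
    protein_length: int = 200,
    mass_error_ppm_sd: float = 0.3,
):
    """Random masses plus a planted offset-carrying subset of terminal ions.

    Returns (observed masses, theoretical ion masses, planted mask).
    """
    rng = np.random.default_rng(seed)
    seq = random_sequence(protein_length, seed + 10_000)
    ions = enumerate_terminal_ions(Proteoform(seq), ("b", "y"))
    theo = np.array([i.neutral_mass for i in ions])
    pick = rng.choice(len(theo), size=n_planted, replace=False)
    planted = theo[pick] + offset
    planted *= 1 + rng.normal(0.0, mass_error_ppm_sd, n_planted) * 1e-6
    randoms = random_mass_list(rng, n_random, theo.min(), theo.max() + 200.0)
    observed = np.concatenate([planted, randoms])
    mask = np.zeros(len(observed), dtype=bool)
    mask[:n_planted] = True
    order = np.argsort(observed)
    return observed[order], theo, mask[order]


def internal_fragment_dataset(
    seed: int,
    protein_length: int = 300,
    shared_sites: tuple[int, ...] = (40, 90, 150),
    members_per_set: int = 12,
    n_random: int = 400,
    mass_error_ppm_sd: float = 0.3,
):
    """True internal-fragment sets sharing N-side cleavage sites, plus noise.

    Returns (sequence, observed masses, truth labels) where a label is the
    (start, end) span for a true internal ion and None for a random mass.
    """
    rng = np.random.default_rng(seed)
    seq = random_sequence(protein_length, seed + 20_000)
    res = np.array([RESIDUE_MASS[aa] for aa in seq])
    prefix = np.concatenate([[0.0], np.cumsum(res)])
    observed, labels = [], []
    for start in shared_sites:
        ends = rng.choice(
            np.arange(start + 5, protein_length), size=members_per_set, replace=False
        )
        for end in ends:
            m = prefix[end] - prefix[start - 1]  # internal b-type: plain residue sum
            m *= 1 + rng.normal(0.0, mass_error_ppm_sd) * 1e-6
            observed.append(m)
            labels.append((start, int(end)))
    lo = 500.0
    hi = prefix[-1] * 0.7
    for m in random_mass_list(rng, n_random, lo, hi):
        observed.append(float(m))
        labels.append(None)
    order = np.argsort(observed)
    observed = np.array(observed)[order]
    labels = [labels[i] for i in order]
    return seq, observed, labels


# ---------------------------------------------------------------------------
# presets: synthetic twins of the three case studies
# ---------------------------------------------------------------------------


def gat1_like_spec(seed: int = 0) -> SimulationSpec:
    """599-residue membrane-transporter twin: S-acylation mixture at Cys493.

    A cysteine at 493 carries a 16:0/18:1/18:0 acyl mixture (fractions
    0.60/0.15/0.25); a second cysteine at 499 is unmodified, so localization
    must separate the two.  C-terminal y ions covering the site appear only
    in lipidated forms; internal fragments occur at rate 0.2.
    """
    seq = random_sequence(599, 1234, force={493: "C", 499: "C"})
    return SimulationSpec(
        proteoform=Proteoform(seq),
        series=("b", "y"),
        n_sites=60,
        internal_rate=0.2,
        internal_shared_sites=(58, 120),
        forced_sites=(430, 450, 470, 485, 492, 497, 505, 520),
        modified_site=493,
        modified_species={"palmitoyl": 0.60, "oleoyl": 0.15, "stearoyl": 0.25},
        drift=(0.002, 1.0e-6),
        seed=seed,
    )


def spp1_like_spec(seed: int = 0) -> SimulationSpec:
    """Phosphoprotein twin: 298-residue mature chain, sparse phosphorylation."""
    seq = random_sequence(298, 4321, force={60: "S", 70: "S", 80: "T"})
    return SimulationSpec(
        proteoform=Proteoform(seq),
        n_sites=40,
        modified_site=70,
        modified_species={"phospho": 0.4, "unmodified": 0.6},
        seed=seed,
    )


def ace2_like_spec(seed: int = 0) -> SimulationSpec:
    """Glycoprotein twin: HexNAc/Hex5HexNAc2 offsets on N-terminal ions."""
    seq = random_sequence(400, 777, force={90: "N", 92: "S"})
    return SimulationSpec(
        proteoform=Proteoform(seq),
        n_sites=50,
        modified_site=None,
        drift=(0.001, 5.0e-7),
        seed=seed,
    )
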