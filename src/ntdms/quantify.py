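"""Relative proteoform-feature quantification from fragment-level data.

Differentially modified forms of the *same* sequence ion are compared, on
the assumption that a small modification does not change fragmentation
efficiency at that site.  Envelope-mixture fitting works directly on the raw
profile: each candidate species' isotope pattern is convolved with the
instrument's Gaussian peak shape and the superposition is fit by
non-negative least squares.  Intensities are normalised by ion charge before
fractions are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .chemcore import PROTON_MASS, IsotopicDistribution
from .deconv import PsfModel
from .msio import ProfileSpectrum


@dataclass
class Species:
    name: str
    neutral_mass: float
    charge: int
    distribution: IsotopicDistribution


@dataclass
class MixtureFit:
    species: list[str]
    abundances: np.ndarray  # charge-normalised, >= 0
    fractions: np.ndarray  # sums to 1
    residual: float
    region: tuple[float, float]


def _render_design_column(
    grid: np.ndarray, sp: Species, psf: PsfModel
) -> np.ndarray:
    col = np.zeros_like(grid)
    ab = sp.distribution.abundances / sp.distribution.abundances.sum()
    for m, a in zip(sp.distribution.masses, ab):
        if a < 1e-4:
            continue
        mz = (m + sp.charge * PROTON_MASS) / sp.charge
        sigma = float(psf.sigma(mz))
        i, j = np.searchsorted(grid, [mz - 5 * sigma, mz + 5 * sigma])
        if j > i:
            col[i:j] += a * np.exp(-0.5 * ((grid[i:j] - mz) / sigma) ** 2)
    return col


def mixture_envelope_fit(
    spectrum: ProfileSpectrum,
    species: list[Species],
    psf: PsfModel,
    region: tuple[float, float] | None = None,
) -> MixtureFit:
    """Non-negative least-squares fit of superposed species envelopes.

    The fitted amplitudes are divided by each species' charge before
    fractions are computed, so multiply-charged ions do not dominate.
    """
    if not species:
        raise ValueError("need at least one species")
    if region is None:
        mzs = [
            (sp.distribution.masses[0] + sp.charge * PROTON_MASS) / sp.charge
            for sp in species
        ] + [
            (sp.distribution.masses[-1] + sp.charge * PROTON_MASS) / sp.charge
            for sp in species
        ]
        region = (min(mzs) - 1.0, max(mzs) + 1.0)
    lo, hi = region
    i, j = np.searchsorted(spectrum.mz, [lo, hi])
    grid = spectrum.mz[i:j]
    y = spectrum.intensity[i:j]
    if len(grid) < 3:
        raise ValueError("fit region contains too few profile points")
    cols = [_render_design_column(grid, sp, psf) for sp in species]
    for a in range(len(cols)):
        if cols[a].max() <= 0:
            raise ValueError(f"species {species[a].name} does not overlap the region")
        for b in range(a + 1, len(cols)):
            ca, cb = cols[a], cols[b]
            denom = np.linalg.norm(ca) * np.linalg.norm(cb)
            if denom > 0 and float(ca @ cb) / denom > 1.0 - 1e-9:
                raise ValueError(
                    f"species {species[a].name!r} and {species[b].name!r} are "
                    "collinear in this region (identical envelopes)"
                )
    A = np.column_stack(cols)
    x, rnorm = nnls(A, y)
    norm = x / np.array([sp.charge for sp in species])
    total = norm.sum()
    fractions = norm / total if total > 0 else np.zeros_like(norm)
    return MixtureFit(
        species=[sp.name for sp in species],
        abundances=norm,
        fractions=fractions,
        residual=float(rnorm**2),
        region=region,
    )


def quantify_truncations(
    ion_intensities: dict[str, list[tuple[float, int]]]
) -> dict[str, float]:
    """Fractions of truncated forms from shared-cleavage-site ion sets.

    ``ion_intensities[form]`` lists (intensity, charge) for the set of ions
    arising from cleavage at the same site in each form.  Per-form abundance
    is the mean charge-normalised intensity; fractions are normalised to 1.
    """
    if not ion_intensities or any(len(v) == 0 for v in ion_intensities.values()):
        raise ValueError("every form needs at least one shared-site ion")
    means = {
        form: float(np.mean([inten / z for inten, z in ions]))
        for form, ions in ion_intensities.items()
    }
    total = sum(means.values())
    return {form: v / total for form, v in means.items()}


@dataclass
class SiteProfile:
    """Per cleavage site: modification-count abundances; per residue: mean count."""

    site_abundances: dict  # (series, index) -> {count: mean relative abundance}
    residue_mean: dict  # residue -> (mean count toward nearest terminus, sd)
    n_spectra: int


def phospho_profile(
    per_spectrum_tables: list[dict],
    sequence_length: int,
    min_spectra: int = 3,
) -> SiteProfile:
    """Average modification count between each residue and its nearest terminus.

    ``per_spectrum_tables[s][(series, index)]`` maps a modification count
    (0, 1, 2, ...) to the ion's intensity in spectrum ``s``.  Ion groups seen
    in fewer than ``min_spectra`` spectra are dropped; a state missing from a
    particular spectrum contributes abundance 0.  Per-residue means are
    intensity-weighted over the ions whose terminus-to-cleavage span covers
    the residue, with the s.d. taken across spectra.
    """
    if len(per_spectrum_tables) < min_spectra:
        raise ValueError(f"need at least {min_spectra} spectra")
    n_spec = len(per_spectrum_tables)
    groups: dict = {}
    for s, table in enumerate(per_spectrum_tables):
        for key, states in table.items():
            groups.setdefault(key, {})[s] = states
    site_abundances = {}
    site_mean_by_spectrum: dict = {}
    for key, by_spec in groups.items():
        if len(by_spec) < min_spectra:
            continue
        all_states = sorted({c for states in by_spec.values() for c in states})
        rel_by_spec = {}
        for s, states in by_spec.items():
            tot = sum(states.values())
            if tot <= 0:
                continue
            rel_by_spec[s] = {c: states.get(c, 0.0) / tot for c in all_states}
        mean_rel = {
            c: float(np.mean([rel_by_spec[s][c] for s in rel_by_spec]))
            for c in all_states
        }
        site_abundances[key] = mean_rel
        site_mean_by_spectrum[key] = {
            s: sum(c * rel for c, rel in rel.items())
            for s, rel in rel_by_spec.items()
        }
    residue_mean: dict = {}
    for r in range(1, sequence_length + 1):
        near_n = r <= sequence_length - r + 1
        per_spec_vals: dict[int, list] = {}
        weights: dict[int, list] = {}
        for (series, index), by_spec in site_mean_by_spectrum.items():
            if near_n and series in ("b", "c") and index >= r:
                covers = True
            elif (not near_n) and series in ("y", "z") and index >= sequence_length - r + 1:
                covers = True
            else:
                covers = False
            if not covers:
                continue
            for s, val in by_spec.items():
                tot_int = sum(groups[(series, index)][s].values())
                per_spec_vals.setdefault(s, []).append(val)
                weights.setdefault(s, []).append(tot_int)
        if not per_spec_vals:
            continue
        spec_means = [
            float(np.average(per_spec_vals[s], weights=weights[s]))
            for s in per_spec_vals
        ]
        residue_mean[r] = (
            float(np.mean(spec_means)),
            float(np.std(spec_means, ddof=1)) if len(spec_means) > 1 else 0.0,
        )
    return SiteProfile(
        site_abundances=site_abundances,
        residue_mean=residue_mean,
        n_spectra=n_spec,
    )
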