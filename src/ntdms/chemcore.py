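"""Elemental and residue mass bookkeeping, isotope patterns and theoretical ions.

All downstream mass arithmetic in the pipeline flows through this module:
elemental formulas (signed counts, so deltas like dehydration are
expressible), aggregated isotopic distributions, averagine modelling for
unknown fragments, proteoforms and their terminal sequence ions, and the
modification table used to annotate open-search mass offsets.

Masses are monoisotopic Da unless stated otherwise.  Element isotope masses
and abundances come from the IUPAC/NIST table shipped with pyteomics;
residue masses are the standard monoisotopic amino-acid residue masses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyteomics import mass as _pmass

PROTON_MASS = 1.007276466
WATER = 18.0105646863
NH3 = 17.0265491015
H_ATOM = 1.00782503207

# residue monoisotopic masses, the 20 standard single-letter codes (X rejected)
RESIDUE_MASS: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(-?\d*)")


class FormulaError(ValueError):
    """Unknown element symbol or malformed formula string."""


def _element_isotopes(symbol: str) -> list[tuple[int, float, float]]:
    """(nucleon number, mass, abundance) for isotopes with nonzero abundance."""
    try:
        table = _pmass.nist_mass[symbol]
    except KeyError:
        raise FormulaError(f"unknown element symbol: {symbol!r}") from None
    isos = [(n, m, ab) for n, (m, ab) in table.items() if n != 0 and ab > 0.0]
    isos.sort()
    if not isos:
        raise FormulaError(f"element {symbol!r} has no stable isotopes in the table")
    return isos


@dataclass(frozen=True)
class ElementalFormula:
    """A chemical composition with signed integer element counts."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for sym, n in self.counts.items():
            if not isinstance(n, (int, np.integer)):
                raise FormulaError(f"count for {sym} must be an integer, got {n!r}")
            _element_isotopes(sym)  # validates symbol
            if n != 0:
                clean[sym] = int(n)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse e.g. ``C16H30O`` or signed deltas like ``H-2O-1``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
            pos = m.end()
            sym, num = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        if pos != len(text):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return ElementalFormula(counts)

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula({s: n * k for s, n in self.counts.items()})

    def __str__(self) -> str:
        return "".join(
            f"{s}{n if n != 1 else ''}" for s, n in sorted(self.counts.items())
        )


def formula_mass(formula: ElementalFormula, kind: str = "mono") -> float:
    """Sum of count x atomic mass; ``kind`` is ``mono`` or ``average``.

    Monoisotopic uses the most abundant isotope of each element; negative
    counts subtract, so delta formulas evaluate to signed mass shifts.
    """
    if kind not in ("mono", "average"):
        raise ValueError(f"kind must be 'mono' or 'average', got {kind!r}")
    total = 0.0
    for sym, n in formula.counts.items():
        isos = _element_isotopes(sym)
        if kind == "mono":
            m = max(isos, key=lambda t: t[2])[1]
        else:
            m = sum(mi * ab for _, mi, ab in isos) / sum(ab for _, _, ab in isos)
        total += n * m
    return total


@dataclass(frozen=True)
class IsotopicDistribution:
    """Aggregated (nucleon-binned) isotopologue masses and abundances."""

    masses: np.ndarray  # neutral isotopologue masses, Da, strictly increasing
    abundances: np.ndarray  # sums to 1

    def __len__(self) -> int:
        return len(self.masses)

    @property
    def most_abundant_index(self) -> int:
        return int(np.argmax(self.abundances))


_MAX_BINS = 400  # generous for < ~100 kDa species; tail pruned at 1e-15


def _power_distribution(A: np.ndarray, M: np.ndarray, n: int):
    """n-fold self-convolution of (abundance, abundance*massoffset) arrays."""
    outA, outM = np.array([1.0]), np.array([0.0])
    baseA, baseM = A.copy(), M.copy()
    while n > 0:
        if n & 1:
            outA, outM = _pair_convolve(outA, outM, baseA, baseM)
        n >>= 1
        if n:
            baseA, baseM = _pair_convolve(baseA, baseM, baseA, baseM)
    return outA, outM


def _pair_convolve(A1, M1, A2, M2):
    A = np.convolve(A1, A2)
    M = np.convolve(M1, A2) + np.convolve(A1, M2)
    if len(A) > _MAX_BINS:
        A, M = A[:_MAX_BINS], M[:_MAX_BINS]
    # prune negligible tail to keep convolutions short
    keep = len(A)
    tail = np.cumsum(A[::-1])
    drop = np.searchsorted(tail, 1e-15)
    if drop > 0:
        keep = max(1, len(A) - drop)
    return A[:keep], M[:keep]


def isotope_distribution(formula: ElementalFormula, n_peaks: int = 40) -> IsotopicDistribution:
    """Aggregated isotopic distribution of ``formula`` by nucleon count.

    Abundances within each extra-nucleon bin are summed and the bin mass is
    the abundance-weighted mean, the usual aggregated-isotopologue model for
    high-resolution (but not fine-structure) FT spectra.  Truncated to
    ``n_peaks`` bins from the monoisotopic bin and renormalised to sum 1.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    for sym, n in formula.counts.items():
        if n < 0:
            raise FormulaError(
                f"negative count for {sym}: distributions are only defined for "
                "realizable molecules"
            )
    A_tot, M_tot = np.array([1.0]), np.array([0.0])
    base_mass = 0.0
    for sym, n in formula.counts.items():
        isos = _element_isotopes(sym)
        n0, m0, _ = isos[0]
        base_mass += n * m0
        width = isos[-1][0] - n0 + 1
        A = np.zeros(width)
        M = np.zeros(width)
        for ni, mi, ab in isos:
            A[ni - n0] = ab
            M[ni - n0] = ab * (mi - m0)
        A /= A.sum()
        eA, eM = _power_distribution(A, M, n)
        A_tot, M_tot = _pair_convolve(A_tot, M_tot, eA, eM)
    A_tot = A_tot[:n_peaks]
    M_tot = M_tot[:n_peaks]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_off = np.where(A_tot > 0, M_tot / np.maximum(A_tot, 1e-300), 0.0)
    masses = base_mass + mean_off
    # bins with zero abundance get nominal neutron spacing so masses increase
    zero = A_tot <= 0
    if zero.any():
        masses[zero] = base_mass + np.arange(len(A_tot))[zero] * 1.00286
    ab = A_tot / A_tot.sum()
    return IsotopicDistribution(masses=masses, abundances=ab)


# Senko averagine unit
AVERAGINE_UNIT = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
AVERAGINE_UNIT_MASS = 111.1254


def averagine_formula(target_mass: float) -> ElementalFormula:
    """Averagine composition scaled to ``target_mass``.

    Element counts are rounded from the scaled Senko unit, then the hydrogen
    count is adjusted so the monoisotopic mass lands within 0.5 Da of the
    target (standard practice for modelling unknown fragment envelopes).
    """
    if target_mass < H_ATOM:
        raise ValueError("target mass below one hydrogen atom")
    scale = target_mass / AVERAGINE_UNIT_MASS
    counts = {sym: int(round(n * scale)) for sym, n in AVERAGINE_UNIT.items()}
    counts["H"] = max(counts.get("H", 0), 1)
    f = ElementalFormula(counts)
    dm = formula_mass(f, "mono") - target_mass
    dh = int(round(dm / H_ATOM))
    counts["H"] = max(1, counts["H"] - dh)
    return ElementalFormula(counts)


@dataclass(frozen=True)
class Modification:
    """A named mass delta with a site rule (residue letters and/or terminus).

    Exactly one of ``formula``/``mass`` is authoritative; when both are given
    they must agree within 1e-6 Da.
    """

    name: str
    formula: ElementalFormula | None = None
    mass: float | None = None
    sites: str = "any"  # e.g. "C", "STY", "N-term", "C-term", "any"

    def __post_init__(self):
        if self.formula is None and self.mass is None:
            raise ValueError(f"modification {self.name!r} needs a formula or a mass")
        if self.formula is not None and self.mass is not None:
            if abs(formula_mass(self.formula, "mono") - self.mass) > 1e-6:
                raise ValueError(
                    f"modification {self.name!r}: formula mass "
                    f"{formula_mass(self.formula, 'mono'):.6f} disagrees with "
                    f"stored mass {self.mass:.6f}"
                )

    @property
    def delta_mass(self) -> float:
        if self.formula is not None:
            return formula_mass(self.formula, "mono")
        return float(self.mass)


def _mod(name, formula=None, mass=None, sites="any"):
    f = ElementalFormula.parse(formula) if formula else None
    return Modification(name=name, formula=f, mass=mass, sites=sites)


def builtin_modifications() -> list[Modification]:
    """The shipped modification table; user-extensible via TSV."""
    return [
        _mod("unmodified", mass=0.0),
        _mod("monoisotopic_error", mass=1.00286),
        _mod("phospho", "HPO3", sites="STY"),
        _mod("HexNAc", "C8H13NO5", sites="NST"),
        _mod("Hex5HexNAc2", "C46H76N2O35", sites="N"),
        _mod("palmitoyl", "C16H30O", sites="C"),
        _mod("stearoyl", "C18H34O", sites="C"),
        _mod("oleoyl", "C18H32O", sites="C"),
        _mod("acetyl", "C2H2O", sites="N-term"),
        _mod("dehydration", "H-2O-1"),
        _mod("deamidation", "H-1N-1O1", sites="NQ"),
        _mod("sodium_adduct", "H-1Na1"),
        _mod("geranylgeranyl", "C20H32", sites="C"),
    ]


def load_modification_table(path: str | Path) -> list[Modification]:
    """TSV columns: name, formula, mass, sites (formula or mass may be blank)."""
    mods = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            name = cells[idx["name"]]
            formula = cells[idx["formula"]] or None
            mass_s = cells[idx["mass"]] or None
            sites = cells[idx.get("sites", len(cells) - 1)] or "any"
            mods.append(
                Modification(
                    name=name,
                    formula=ElementalFormula.parse(formula) if formula else None,
                    mass=float(mass_s) if mass_s else None,
                    sites=sites,
                )
            )
    return mods


def annotate_offset(
    delta_mass: float, tol: float, table: list[Modification] | None = None
) -> list[Modification]:
    """Modification-table entries within ``tol`` of ``delta_mass``, best first."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if table is None:
        table = builtin_modifications()
    hits = [m for m in table if abs(m.delta_mass - delta_mass) <= tol]
    hits.sort(key=lambda m: abs(m.delta_mass - delta_mass))
    return hits


@dataclass(frozen=True)
class Proteoform:
    """A sequence plus terminal/side-chain modifications and truncation bounds.

    ``sequence`` uses 1-based residue numbering of the precursor isoform;
    ``truncation`` is the inclusive residue interval retained in the species.
    """

    sequence: str
    n_term_mod: Modification | None = None
    c_term_mod: Modification | None = None
    side_chain_mods: tuple = ()  # ((position, Modification), ...)
    truncation: tuple[int, int] | None = None

    def __post_init__(self):
        for aa in self.sequence:
            if aa not in RESIDUE_MASS:
                raise ValueError(f"unsupported residue code {aa!r}")
        start, end = self.span
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(f"truncation {self.truncation} outside sequence")
        for pos, _m in self.side_chain_mods:
            if not (start <= pos <= end):
                raise ValueError(f"side-chain modification at {pos} outside truncation")

    @property
    def span(self) -> tuple[int, int]:
        return self.truncation if self.truncation else (1, len(self.sequence))

    @property
    def active_sequence(self) -> str:
        s, e = self.span
        return self.sequence[s - 1 : e]

    def neutral_mass(self) -> float:
        m = sum(RESIDUE_MASS[aa] for aa in self.active_sequence) + WATER
        for mod in (self.n_term_mod, self.c_term_mod):
            if mod is not None:
                m += mod.delta_mass
        for _pos, mod in self.side_chain_mods:
            m += mod.delta_mass
        return m


@dataclass(frozen=True)
class TheoreticalIon:
    """One terminal sequence ion (b/y/c/z-dot series)."""

    series: str  # 'b', 'y', 'c', 'z'
    index: int  # cleavage count from the relevant terminus
    neutral_mass: float
    terminus: str  # 'N' or 'C'
    modifications: tuple = ()

    def mz(self, charge: int) -> float:
        return (self.neutral_mass + charge * PROTON_MASS) / charge

    @property
    def name(self) -> str:
        return f"{self.series}{self.index}"


# series arithmetic: b = sum(res); y = sum(res) + H2O; c = b + NH3; z-dot = y - NH3 + H
_SERIES_TERMINUS = {"b": "N", "c": "N", "y": "C", "z": "C"}
_SERIES_SHIFT = {"b": 0.0, "c": NH3, "y": WATER, "z": WATER - NH3 + H_ATOM}


def enumerate_terminal_ions(
    p: Proteoform,
    series: tuple[str, ...] = ("b", "y"),
    charge_range: tuple[int, int] = (1, 1),
) -> list[TheoreticalIon]:
    """Theoretical terminal ions for each (series, cleavage index).

    Side-chain modifications contribute only when explicitly present on the
    proteoform (the open database search deliberately passes an unmodified
    one).  m/z at charge z is (M + z * 1.007276466) / z.
    """
    bad = set(series) - set(_SERIES_TERMINUS)
    if bad:
        raise ValueError(f"unknown ion series: {sorted(bad)}")
    seq = p.active_sequence
    n = len(seq)
    if n == 0:
        return []
    start, _end = p.span
    res = np.array([RESIDUE_MASS[aa] for aa in seq])
    prefix = np.concatenate([[0.0], np.cumsum(res)])
    # cumulative side-chain delta for N-terminal ions covering first i residues
    side_prefix = np.zeros(n + 1)
    for pos, mod in p.side_chain_mods:
        side_prefix[pos - start + 1 :] += mod.delta_mass
    n_mod = p.n_term_mod.delta_mass if p.n_term_mod else 0.0
    c_mod = p.c_term_mod.delta_mass if p.c_term_mod else 0.0
    ions = []
    for s in series:
        shift = _SERIES_SHIFT[s]
        for i in range(1, n):
            if _SERIES_TERMINUS[s] == "N":
                m = prefix[i] + side_prefix[i] + shift + n_mod
            else:
                m = (
                    (prefix[n] - prefix[n - i])
                    + (side_prefix[n] - side_prefix[n - i])
                    + shift
                    + c_mod
                )
            mods = tuple(
                mod
                for pos, mod in p.side_chain_mods
                if (
                    pos - start + 1 <= i
                    if _SERIES_TERMINUS[s] == "N"
                    else pos - start + 1 > n - i
                )
            )
            ions.append(
                TheoreticalIon(
                    series=s,
                    index=i,
                    neutral_mass=m,
                    terminus=_SERIES_TERMINUS[s],
                    modifications=mods,
                )
            )
    return ions


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(identifier, sequence) pairs; sequences with 'X' are rejected."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "X" in seq:
            raise ValueError(f"sequence {rec.id} contains unsupported residue 'X'")
        out.append((rec.id, seq))
    return out
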