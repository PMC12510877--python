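"""Protein isoform identification from filtered fragment masses.

Two complementary routes, matching the two fragmentation regimes of native
top-down measurements: de novo sequence tags read from mass gaps (structure-
driven cleavage along contiguous stretches) and an intact-mass-free open
database search over terminal ions (sequence-driven cleavage).  Neither
needs the precursor mass, which heterogeneous native samples rarely give.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .chemcore import Proteoform, RESIDUE_MASS, enumerate_terminal_ions

# I and L are isobaric; report a single symbol
_TAG_RESIDUES = {aa: m for aa, m in RESIDUE_MASS.items() if aa not in ("I",)}
HIGH_CONFIDENCE_TAG_LENGTH = 8

# log-odds weights for cleavage-site propensity: vibrational activation of
# native ions cleaves preferentially C-terminal to Asp/Glu and N-terminal to Pro
CLEAVAGE_WEIGHTS_LEFT = {"D": 2.0, "E": 0.7}
CLEAVAGE_WEIGHTS_RIGHT = {"P": 1.0}


@dataclass
class SequenceTag:
    residues: str  # e.g. "GA[L/I]"; bracketed pairs mark two-residue gaps
    node_masses: list[float]
    direction: str = "ambiguous"
    span: tuple[float, float] = (0.0, 0.0)

    @property
    def length(self) -> int:
        n, i = 0, 0
        while i < len(self.residues):
            if self.residues[i] == "[":
                i = self.residues.index("]", i) + 1
                n += 2
            else:
                i += 1
                n += 1
        return n

    @property
    def high_confidence(self) -> bool:
        return self.length >= HIGH_CONFIDENCE_TAG_LENGTH


def _gap_symbol(gap: float, tol: float) -> str | None:
    best, best_err = None, tol
    for aa, m in _TAG_RESIDUES.items():
        err = abs(gap - m)
        if err <= best_err:
            best, best_err = aa, err
    if best == "L":
        return "[L/I]"
    return best


def extract_tags(
    masses: np.ndarray, tol_ppm: float = 10.0, min_len: int = 3,
    allow_pairs: bool = True,
) -> list[SequenceTag]:
    """De novo sequence tags from mass gaps between fragment ions.

    A directed graph on neutral masses gets an edge when a gap equals a
    residue mass (or, bracketed, a two-residue sum) within tolerance; maximal
    paths of at least ``min_len`` residues are read out.  I/L are reported as
    one symbol since they are isobaric at any resolution.
    """
    masses = np.sort(np.asarray(masses, dtype=float))
    if len(masses) < 2:
        return []
    g = nx.DiGraph()
    pair_sums = None
    if allow_pairs:
        aas = sorted(_TAG_RESIDUES)
        pair_sums = [
            (a + b, _TAG_RESIDUES[a] + _TAG_RESIDUES[b])
            for ai, a in enumerate(aas)
            for b in aas[ai:]
        ]
    for i in range(len(masses)):
        tol = tol_ppm * 1e-6 * masses[i]
        lo = np.searchsorted(masses, masses[i] + 50.0)
        for j in range(lo, len(masses)):
            gap = masses[j] - masses[i]
            if gap > (380.0 if allow_pairs else 190.0) + tol:
                break
            sym = _gap_symbol(gap, tol)
            if sym is not None:
                g.add_edge(i, j, sym=sym, pair=False)
            elif allow_pairs:
                for name, s in pair_sums:
                    if abs(gap - s) <= tol:
                        g.add_edge(i, j, sym=f"[{name}]", pair=True)
                        break
    # maximal paths in the DAG by longest-path dynamic programming per end node
    tags: list[SequenceTag] = []
    order = list(nx.topological_sort(g))
    best: dict[int, tuple[int, int | None]] = {v: (0, None) for v in order}
    for v in order:
        for u in g.predecessors(v):
            # two-residue gaps carry a shade less weight than two single
            # steps so unambiguous readings win ties
            w = 1.99 if g.edges[u, v]["pair"] else 1
            cand = best[u][0] + w
            if cand > best[v][0]:
                best[v] = (cand, u)
    sinks = [v for v in order if g.out_degree(v) == 0 and best[v][0] >= min_len]
    seen: set[str] = set()
    for v in sorted(sinks, key=lambda v: -best[v][0]):
        path = [v]
        while best[path[-1]][1] is not None:
            path.append(best[path[-1]][1])
        path.reverse()
        if len(path) < 2:
            continue
        syms = [g.edges[path[i], path[i + 1]]["sym"] for i in range(len(path) - 1)]
        tag = "".join(syms)
        t = SequenceTag(
            residues=tag,
            node_masses=[float(masses[i]) for i in path],
            span=(float(masses[path[0]]), float(masses[path[-1]])),
        )
        if t.length >= min_len and tag not in seen:
            seen.add(tag)
            tags.append(t)
    return tags


@dataclass
class IsoformMatch:
    isoform_id: str
    description: str
    matched_count: int
    matched_ions: list = field(default_factory=list)
    propensity_score: float = 0.0
    rank: int = 0


def propensity_score(
    sequence: str,
    matched_indices_by_series: dict[str, set[int]],
    weights_left: dict[str, float] | None = None,
    weights_right: dict[str, float] | None = None,
) -> float:
    """Sum of flanking-residue log-odds over matched cleavage sites,
    normalised by log(sequence length)."""
    wl = CLEAVAGE_WEIGHTS_LEFT if weights_left is None else weights_left
    wr = CLEAVAGE_WEIGHTS_RIGHT if weights_right is None else weights_right
    n = len(sequence)
    sites: set[int] = set()
    for series, idxs in matched_indices_by_series.items():
        for i in idxs:
            sites.add(i if series in ("b", "c") else n - i)
    score = 0.0
    for s in sites:
        if 1 <= s <= n - 1:
            score += 0.5  # base credit per matched cleavage
            score += wl.get(sequence[s - 1], 0.0)
            score += wr.get(sequence[s], 0.0)
    return score / np.log(max(n, 3))


def open_database_search(
    masses: np.ndarray,
    db: list[tuple[str, Proteoform]],
    series: tuple[str, ...] = ("b", "y"),
    tol_ppm: float = 5.0,
    weights_left: dict[str, float] | None = None,
    weights_right: dict[str, float] | None = None,
) -> list[IsoformMatch]:
    """Intact-mass-free open search: count terminal-ion matches per isoform.

    No precursor-mass prefilter is applied and side-chain modifications are
    ignored, keeping the search space linear in the database.  Ranking is by
    propensity score, then matched count; ties break toward the shorter
    sequence.
    """
    if not db:
        raise ValueError("empty database")
    masses = np.sort(np.asarray(masses, dtype=float))
    results = []
    for iso_id, p in db:
        ions = enumerate_terminal_ions(p, series)
        matched: dict[str, set[int]] = {s: set() for s in series}
        matched_ions = []
        for ion in ions:
            tol = tol_ppm * 1e-6 * ion.neutral_mass
            i, j = np.searchsorted(masses, [ion.neutral_mass - tol, ion.neutral_mass + tol])
            if j > i:
                matched[ion.series].add(ion.index)
                matched_ions.append(ion)
        count = sum(len(v) for v in matched.values())
        score = propensity_score(
            p.active_sequence, matched, weights_left, weights_right
        )
        results.append(
            IsoformMatch(
                isoform_id=iso_id,
                description=iso_id,
                matched_count=count,
                matched_ions=matched_ions,
                propensity_score=score,
            )
        )
    results.sort(
        key=lambda m: (-m.propensity_score, -m.matched_count, len(_seq(db, m.isoform_id)), m.isoform_id)
    )
    for r, m in enumerate(results, start=1):
        m.rank = r
    return results


def _seq(db, iso_id):
    for i, p in db:
        if i == iso_id:
            return p.active_sequence
    return ""
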