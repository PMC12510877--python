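"""Reading/writing the plain-text formats the pipeline touches, plus run config.

Profile MS2 spectra arrive as two-column (m/z, intensity) space- or
tab-delimited text, the usual export path from vendor software.  Every stage
of the pipeline reads and writes TSV so stages compose via files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("ntdms")


class SpectrumParseError(ValueError):
    pass


@dataclass
class ProfileSpectrum:
    """Ordered (m/z, intensity) arrays representing one averaged scan."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if len(self.mz) and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if not (np.all(np.isfinite(self.mz)) and np.all(np.isfinite(self.intensity))):
            raise ValueError("spectrum contains non-finite values")

    def __len__(self) -> int:
        return len(self.mz)

    def slice(self, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
        i, j = np.searchsorted(self.mz, [lo, hi])
        return self.mz[i:j], self.intensity[i:j]


@dataclass
class CentroidPeak:
    mz: float
    intensity: float
    width_sigma: float | None = None

    def __post_init__(self):
        if self.intensity <= 0:
            raise ValueError("centroid intensity must be > 0")


@dataclass
class RunConfig:
    """User-facing knobs, defaulting to the study's standard settings.

    ``coarse_tol_ppm`` is the low-stringency tolerance for first-pass
    matching (drifting analyzers), ``fine_tol_ppm`` the post-calibration
    tolerance, ``fit_threshold`` the envelope goodness-of-fit above which an
    assignment is accepted automatically, and ``evalue_threshold`` the open
    search significance cut.
    """

    coarse_tol_ppm: float = 10.0
    fine_tol_ppm: float = 3.0
    fit_threshold: float = 0.75
    evalue_threshold: float = 0.01
    offset_lo: float = -100.0
    offset_hi: float = 1300.0
    oversampling: int = 4
    ion_series: tuple[str, ...] = ("b", "y")
    interactive: bool = False

    def __post_init__(self):
        if self.coarse_tol_ppm <= 0 or self.fine_tol_ppm <= 0:
            raise ValueError("tolerances must be > 0")
        if not (0 < self.fit_threshold <= 1):
            raise ValueError("fit_threshold must lie in (0, 1]")
        if not (0 < self.evalue_threshold < 1):
            raise ValueError("evalue_threshold must lie in (0, 1)")


def read_profile_spectrum(path: str | Path) -> ProfileSpectrum:
    """Read tab- or space-delimited two-column profile text.

    Rows are sorted by m/z; non-finite rows are dropped with a logged count.
    A single non-numeric header line is tolerated; anything else raises with
    the offending line number.
    """
    path = Path(path)
    mzs, ints = [], []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            cells = line.split()
            if not cells:
                continue
            if len(cells) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                mz, inten = float(cells[0]), float(cells[1])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric row {line.strip()!r}"
                ) from None
            if not (np.isfinite(mz) and np.isfinite(inten)):
                n_dropped += 1
                continue
            mzs.append(mz)
            ints.append(inten)
    if n_dropped:
        log.info("read_profile_spectrum: dropped %d non-finite rows", n_dropped)
    order = np.argsort(mzs, kind="stable")
    mz = np.asarray(mzs)[order]
    inten = np.asarray(ints)[order]
    # collapse exact duplicate m/z (sum intensity) so the grid is strictly increasing
    if len(mz) > 1:
        dup = np.diff(mz) == 0
        if dup.any():
            keep = np.concatenate([[True], ~dup])
            idx = np.cumsum(keep) - 1
            summed = np.zeros(keep.sum())
            np.add.at(summed, idx, inten)
            mz, inten = mz[keep], summed
    return ProfileSpectrum(mz=mz, intensity=inten, metadata={"source": str(path)})


def write_profile_spectrum(s: ProfileSpectrum, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([s.mz, s.intensity]), fmt="%.9f %.9e")


def ms1_charge_state_mass(
    peak_mzs, charge_range: tuple[int, int] = (1, 60), proton: float = 1.007276466
) -> tuple[float, int]:
    """Simple intact-mass estimate from consecutive MS1 charge-state peaks.

    ``peak_mzs`` are the apex m/z of one species' charge-state series,
    highest charge first or last (order does not matter).  For each
    hypothesis that the series covers consecutive charges ending at z, the
    implied neutral masses are computed; the hypothesis with the smallest
    relative spread wins.  Returns (mass, charge of the lowest-m/z peak).
    Full MS1 deconvolution of overlapping distributions is out of scope.
    """
    mzs = np.sort(np.asarray(peak_mzs, dtype=float))[::-1]  # ascending charge
    if len(mzs) < 2:
        raise ValueError("need at least two charge-state peaks")
    k = len(mzs)
    best = None
    for z_hi in range(charge_range[0] + k - 1, charge_range[1] + 1):
        charges = np.arange(z_hi - k + 1, z_hi + 1)
        masses = mzs * charges - charges * proton
        spread = masses.std() / masses.mean()
        if best is None or spread < best[0]:
            best = (spread, float(masses.mean()), int(z_hi))
    return best[1], best[2]


ASSIGNMENT_COLUMNS = [
    "ion",
    "series",
    "index",
    "charge",
    "theoretical_mz",
    "observed_mz",
    "error_ppm",
    "error_mda",
    "fit_score",
    "modifications",
    "offset_da",
    "stage",
]


def write_assignment_table(assignments, path: str | Path) -> None:
    """Write finalized assignments as TSV in deterministic (series, index, charge) order."""
    rows = []
    for a in assignments:
        rows.append(
            {
                "ion": f"{a.ion.series}{a.ion.index}",
                "series": a.ion.series,
                "index": a.ion.index,
                "charge": a.charge,
                "theoretical_mz": a.theoretical_mz,
                "observed_mz": a.observed_mz,
                "error_ppm": a.error_ppm,
                "error_mda": a.error_mda,
                "fit_score": a.fit_score,
                "modifications": ";".join(m.name for m in a.ion.modifications)
                if a.ion.modifications
                else "",
                "offset_da": a.offset_da,
                "stage": a.stage,
            }
        )
    df = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    if len(df):
        df = df.sort_values(["series", "index", "charge"], kind="stable")
    df.to_csv(path, sep="\t", index=False)
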