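"""Independent cross-checks for the core numerics.

The isotope-pattern oracle here deliberately avoids the production code
path: element polynomials are raised to their powers in the Fourier domain
(FFT -> complex powers -> inverse FFT), so agreement with the nucleon-bin
convolution in :mod:`ntdms.chemcore` is a genuine two-route check.
"""

from __future__ import annotations

import numpy as np

from .chemcore import ElementalFormula, _element_isotopes


def fft_isotope_abundances(formula: ElementalFormula, n_peaks: int = 40) -> np.ndarray:
    """Aggregated isotopologue abundances via frequency-domain powers."""
    size = 1
    needed = 1
    spans = []
    for sym, n in formula.counts.items():
        if n < 0:
            raise ValueError("negative counts not allowed")
        isos = _element_isotopes(sym)
        spans.append((sym, n, isos))
        needed += n * (isos[-1][0] - isos[0][0])
    while size < max(needed, n_peaks + 1):
        size *= 2
    acc = np.ones(size, dtype=complex)
    for sym, n, isos in spans:
        n0 = isos[0][0]
        p = np.zeros(size)
        for ni, _m, ab in isos:
            p[ni - n0] = ab
        p /= p.sum()
        acc *= np.fft.fft(p) ** n
    dist = np.real(np.fft.ifft(acc))
    dist = np.clip(dist, 0.0, None)[:n_peaks]
    return dist / dist.sum()
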