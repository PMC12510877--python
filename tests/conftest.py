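import numpy as np
import pytest

from ntdms.chemcore import PROTON_MASS, isotope_distribution
from ntdms.deconv import PsfModel
from ntdms.synthgen import render_profile, random_sequence, sequence_formula


@pytest.fixture(scope="session")
def psf():
    return PsfModel.from_resolution(240_000.0)


@pytest.fixture(scope="session")
def small_envelope_spectrum(psf):
    """One clean 2+ envelope of a 18-residue peptide, mono mass recorded."""
    seq = random_sequence(18, 7)
    dist = isotope_distribution(sequence_formula(seq, water=True), 30)
    mono = float(dist.masses[0])
    z = 2
    mz0 = (mono + z * PROTON_MASS) / z
    rng = np.random.default_rng(7)
    spec = render_profile(
        [(mono, z, 100.0, dist)], (mz0 - 3, mz0 + 8), 0.001, psf,
        noise_sigma=0.3, rng=rng,
    )
    return spec, mono, z, dist
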