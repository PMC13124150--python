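import numpy as np
import pytest

from specfret.spectra import Spectrum, SpectrumKind
from specfret.synth import (
    SpectraScenario,
    ToyStructureScenario,
    make_fret_dataset,
    make_helix_bundle,
)


@pytest.fixture
def grid():
    return np.arange(300.0, 501.0, 1.0)


@pytest.fixture
def gaussian_spectrum(grid):
    y = np.exp(-((grid - 420.0) ** 2) / (2 * 30.0**2))
    return Spectrum(abscissa=grid, intensity=y, kind=SpectrumKind.EMISSION,
                    excitation_nm=370.0, sample_id="gauss420")


@pytest.fixture
def clean_dataset():
    """Noise-free spectral FRET replicate with E=0.3, m=0.8, a0=0.5."""
    return make_fret_dataset(
        SpectraScenario(true_efficiency=0.3, ratio_a0_true=0.5,
                        proportionality_m=0.8, noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def toy_dimer():
    """Two-chain helix bundle with donors on both chains."""
    scenario = ToyStructureScenario(
        n_res=12,
        chain_offsets=((0.0, 0.0, 0.0), (28.0, 0.0, 0.0)),
        donor_sites=((3, "TRP"), (6, "TYR")),
        acceptor_sites=(9,),
    )
    return make_helix_bundle(scenario)


@pytest.fixture(scope="session")
def toy_dimer_pdb(toy_dimer, tmp_path_factory):
    path = tmp_path_factory.mktemp("structs") / "toy_dimer.pdb"
    toy_dimer.write_pdb(path)
    return path
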