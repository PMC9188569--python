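"""Shared fixtures: a realistic spectral signature, single-color controls,
and the RPU reference built from them (all synthetic, seeded)."""

import numpy as np
import pytest

from reacloop.cytometry import (
    PopulationSpec,
    RpuReference,
    SpectralSignature,
    StrainPopulation,
    generate_events,
    rpu_reference_from_controls,
)

# Three yeast fluorophores read through four detection channels with ~30%
# cross-talk between spectral neighbours (mCerulean/mNeonGreen overlap is
# the hard deconvolution case) and non-trivial autofluorescence.
CHANNELS = ("BLU", "GRN-B", "ORG-G", "RED")
FLUOROPHORES = ("mCerulean", "mNeonGreen", "mScarlet-I")
MATRIX = np.array(
    [
        [1.00, 0.05, 0.00],
        [0.30, 1.00, 0.02],
        [0.02, 0.30, 1.00],
        [0.00, 0.02, 0.30],
    ]
)
AUTOFLUORESCENCE = np.array([30.0, 20.0, 15.0, 10.0])

#: pTDH3-level constitutive expression in raw instrument units.
PTDH3_LEVEL = 5000.0


@pytest.fixture(scope="session")
def signature() -> SpectralSignature:
    return SpectralSignature(
        channel_names=CHANNELS,
        fluorophore_names=FLUOROPHORES,
        matrix=MATRIX,
        autofluorescence=AUTOFLUORESCENCE,
    )


@pytest.fixture(scope="session")
def single_color_controls(signature):
    controls = {}
    for fluor in FLUOROPHORES:
        strain = StrainPopulation(fluor, 1.0, fluor_logmeans={fluor: np.log(PTDH3_LEVEL)})
        spec = PopulationSpec(strains=(strain,), n_events=5000, seed=1)
        controls[fluor] = generate_events(spec, signature)[0]
    return controls


@pytest.fixture(scope="session")
def rpu_reference(single_color_controls, signature) -> RpuReference:
    return rpu_reference_from_controls(single_color_controls, signature)


@pytest.fixture(scope="session")
def competition_mixture_spec():
    """5:1 mutant:WT competition inoculum; WT carries the constitutive
    mCerulean genotype marker well above the 1 RPU threshold."""
    wt = StrainPopulation(
        "wt", 1.0 / 6.0, fluor_logmeans={"mCerulean": np.log(16000.0)}
    )
    mutant = StrainPopulation(
        "mutant", 5.0 / 6.0, fluor_logmeans={"mNeonGreen": np.log(4000.0)}
    )
    return PopulationSpec(strains=(mutant, wt), n_events=12000, seed=0)
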