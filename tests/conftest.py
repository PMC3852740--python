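import numpy as np
import pytest

import probeloc as pl
from probeloc.library import BuildingBlock


def bare_compound(logp: float, extra_pkas=()) -> pl.Compound:
    """A minimal compound with prescribed logP and extra pKas, for model tests."""
    head = BuildingBlock(
        kind="head",
        index=1,
        logp_contribution=logp / 2,
        extra_ionizable=len(extra_pkas),
        pka_values=tuple(extra_pkas),
        signature_bits=frozenset({100}),
    )
    ald = BuildingBlock(
        kind="aldehyde",
        index=1,
        logp_contribution=logp / 2,
        signature_bits=frozenset({200}),
    )
    return pl.Compound(
        head=head,
        aldehyde=ald,
        logp=logp,
        fingerprint=pl.assign_fingerprint(head, ald),
        extra_pkas=tuple(extra_pkas),
    )


@pytest.fixture(scope="session")
def cell():
    return pl.default_cell()


@pytest.fixture(scope="session")
def small_library():
    return pl.generate_library(4, 12, seed=2)


@pytest.fixture(scope="session")
def full_library():
    return pl.generate_library(8, 168, seed=11)


@pytest.fixture(scope="session")
def full_predictions(full_library):
    return pl.predict_library(full_library)


@pytest.fixture(scope="session")
def noiseless_renders():
    """Noiseless synthetic fields, three per staining class."""
    return {
        cls: [
            pl.render_image_set(cls, noise_sd=0.0, seed=seed) for seed in (1, 2, 3)
        ]
        for cls in pl.STAIN_CLASSES
    }
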