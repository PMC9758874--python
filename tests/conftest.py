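"""Shared fixtures: small ground-truthed synthetic studies.

"Noise-free" studies use exact expected read counts (no multinomial
sampling); the per-well log-normal culture-abundance variation is retained
because it is the signal the probabilistic decoder requires.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import platepool as pp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def decode_study() -> pp.SyntheticStudy:
    """Noise-free 4-plate collection for decoder-exactness checks.

    1000 strains over 384 wells gives isolation counts up to 4 while leaving
    enough definite barcodes to anchor the abundance model.
    """
    params = pp.SimParams(
        seed=2025, n_strains=1000, n_genes=60,
        exact_counts=True, reads_per_pool=500_000,
    )
    return pp.simulate_study(params, 4)


@pytest.fixture(scope="session")
def classify_params() -> pp.SimParams:
    """Noise-free pool for classifier-exactness checks.

    2000 strains over 384 wells and moderate abundance bias keep every
    barcode's isolation count within the decoder's enumeration cap, so well
    classification is limited only by the classification rules themselves.
    """
    return pp.SimParams(
        seed=7, n_strains=2000, n_genes=60, abundance_sigma=0.5,
        exact_counts=True, reads_per_pool=500_000,
    )


@pytest.fixture(scope="session")
def classify_study(classify_params) -> pp.SyntheticStudy:
    return pp.simulate_study(classify_params, 4)


def truth_wells_by_barcode(study: pp.SyntheticStudy) -> dict[str, set]:
    """Ground truth: barcode -> set of (plate index, well position)."""
    strains = {s.strain_id: s for s in study.pool}
    truth: dict[str, set] = {}
    for (p, w), sid in study.collection.occupants.items():
        for bc in strains[sid].barcodes:
            truth.setdefault(bc, set()).add((p, w))
    return truth


def trusted_placements(results: pp.DecodeResults) -> dict[str, set]:
    """Decoded barcode -> set of (plate, well) for trusted placements."""
    loc = results.location_table.located()
    placed: dict[str, set] = {}
    for row in loc.itertuples(index=False):
        placed.setdefault(row.barcode, set()).add((int(row.plate), row.well))
    return placed
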