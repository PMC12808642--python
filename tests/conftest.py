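"""Shared fixtures: generated complexes and random pigment clouds."""

from __future__ import annotations

import numpy as np
import pytest

from pigmentnet import (
    ComplexModel,
    PigmentClass,
    PigmentRecord,
    SubunitRecord,
    assign_rings,
    generate_complex,
    membrane_frame,
    monomer_double_layer,
    trimer_double_ring,
)
from pigmentnet.records import ISIA


@pytest.fixture(scope="session")
def trimer():
    """Default closed double ring: 18+25 protomers x 17 chlorophylls."""
    model, truth = generate_complex(trimer_double_ring(seed=11))
    frame = membrane_frame(model)
    assign_rings(model, frame)
    return model, truth, frame


@pytest.fixture(scope="session")
def monomer():
    """Open double layer: 6+7 protomers on a monomeric core."""
    model, truth = generate_complex(monomer_double_layer(seed=12))
    frame = membrane_frame(model)
    assign_rings(model, frame)
    return model, truth, frame


@pytest.fixture()
def small_spec():
    """Reduced complex for fast per-test generation."""
    return trimer_double_ring(
        inner_count=5, outer_count=7, chl_per_subunit=5,
        layer_allocation=(3, 2), carotenoids_per_subunit=2,
        core_count=1, core_chl_per_core=6, seed=7,
    )


def make_chlorophyll(chain: SubunitRecord, resnum: int, mg, u=(1.0, 0.0, 0.0),
                     span: float = 4.2) -> PigmentRecord:
    """Chlorophyll record with Mg at ``mg`` and dipole along ``u``."""
    mg = np.asarray(mg, dtype=float)
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u)
    return PigmentRecord(
        pigment_id=(chain.chain_id, resnum, "CLA"),
        pigment_class=PigmentClass.CHLOROPHYLL_A,
        subunit=chain, mg=mg, nb=mg - u * span / 2, nd=mg + u * span / 2,
    )


def random_chlorophyll_model(rng: np.random.Generator, n: int,
                             n_subunits: int = 8) -> ComplexModel:
    """n chlorophylls on a jittered grid (guaranteed >=3 A separation),
    random dipoles, spread over antenna subunits."""
    model = ComplexModel(name=f"random-{n}")
    subs = [SubunitRecord(chain_id=f"S{k}", role=ISIA)
            for k in range(n_subunits)]
    model.subunits = subs
    side = int(np.ceil(n ** (1 / 3)))
    cells = [(i, j, k) for i in range(side + 1) for j in range(side + 1)
             for k in range(side + 1)]
    picks = rng.choice(len(cells), size=n, replace=False)
    for idx, c in enumerate(picks):
        base = np.array(cells[c], dtype=float) * 6.0
        mg = base + rng.uniform(-1.0, 1.0, size=3)
        u = rng.normal(size=3)
        model.pigments.append(make_chlorophyll(
            subs[idx % n_subunits], 500 + idx, mg, u))
    return model
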