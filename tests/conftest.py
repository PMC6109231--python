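"""Shared fixtures: small phantoms and seeded synthetic data.

Everything is generated at run time; box sizes are kept small (32 px at
6 Å/px) so the full suite stays fast on one CPU.
"""

from __future__ import annotations

import numpy as np
import pytest

from shotgunem.synthdata import make_complex_db, make_phantom, render_particle_stack

BOX = 32
VOX = 6.0


@pytest.fixture(scope="session")
def sphere():
    return make_phantom("sphere", BOX, VOX, 120.0)


@pytest.fixture(scope="session")
def barrel():
    return make_phantom("barrel", BOX, VOX, 110.0)


@pytest.fixture(scope="session")
def capped_barrel():
    return make_phantom("capped_barrel", BOX, VOX, 108.0)


@pytest.fixture(scope="session")
def heptamer():
    return make_phantom("heptamer_ring", BOX, VOX, 100.0)


@pytest.fixture(scope="session")
def complex_db():
    return make_complex_db(n_base=8, variants_per_base=3, size_range=(6, 20), seed=11)


@pytest.fixture(scope="session")
def mixed_stack(capped_barrel, heptamer):
    """400-particle capped-barrel/heptamer mixture at SNR 1 with truth."""
    phantoms = [capped_barrel, heptamer]
    clean, _, _ = render_particle_stack(phantoms, [0.5, 0.5], 50, 0.0, 2, seed=5)
    noise = float(np.sqrt(clean.images.var(axis=(1, 2)).mean()))
    stack, labels, oris = render_particle_stack(
        phantoms, [0.5, 0.5], 400, noise, 2, seed=5
    )
    return stack, labels, oris, noise
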