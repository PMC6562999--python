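"""Pytest fixtures; pure builders/oracles live in helpers.py."""

from __future__ import annotations

import pytest

from helpers import (  # noqa: F401  (re-exported for test modules)
    make_gm,
    make_gm_from_map,
    make_mmap,
    nuclear_family,
    random_calls,
    random_loopfree_pedigree,
    roh_window_oracle,
)

# ---------------------------------------------------------------------------
# one small end-to-end dataset shared across test modules


@pytest.fixture(scope="session")
def small_config():
    from ataxmap.simulate import SimulationConfig

    return SimulationConfig(
        seed=4242,
        n_chromosomes=3,
        markers_per_chrom=120,
        n_controls=40,
        background_variant_spacing_bp=250_000,
        genotyping_error_rate=0.0,
        missing_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    from ataxmap.simulate import simulate

    return simulate(small_config)
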