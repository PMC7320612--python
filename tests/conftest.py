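from __future__ import annotations

import numpy as np
import pytest

from mxscaff import FixtureSpec, generate_fixture, scaffold_assemblies


def random_dna(rng, length, alphabet="ACGT", p=None):
    return "".join(rng.choice(list(alphabet), size=length, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A small, fast end-to-end scaffolding run with known ground truth."""
    spec = FixtureSpec(
        n_chromosomes=2,
        chrom_length=150_000,
        fragment_length_mean=12_000,
        fragment_length_sd=3_000,
        rng_seed=42,
    )
    fixture = generate_fixture(spec)
    outdir = tmp_path_factory.mktemp("small_fixture")
    paths = fixture.write(outdir)
    result = scaffold_assemblies(paths["target"], [paths["reference"]], k=20, w=100)
    return fixture, paths, result
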