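import numpy as np
import pytest

from stereoflow import (
    ChipSpec,
    LatticeCoordinate,
    MaskTable,
    SimulationParams,
    simulate_run,
    write_run,
)

#: study conditions of the standard desk-scale fixture
STANDARD_SEED = 42


def tiny_mask(cids, width=8, height=8, cid_length=None):
    """Build a MaskTable from a list of CIDs laid out row-major."""
    cid_length = cid_length or len(cids[0])
    chip = ChipSpec("tiny", width, height, cid_length)
    mask = MaskTable(chip)
    for i, cid in enumerate(cids):
        mask.add(cid, LatticeCoordinate(i % width, i // width))
    return mask


def random_cids(rng, n, length=25):
    """n distinct random CIDs."""
    out = set()
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    while len(out) < n:
        need = n - len(out)
        codes = rng.integers(0, 4, size=(need, length), dtype=np.uint8)
        out.update(bytes(bases[row]).decode() for row in codes)
    return sorted(out)


@pytest.fixture(scope="session")
def standard_sim():
    """The standard noisy fixture: 20x20 chip, 5 genes, 2,000 molecules."""
    return simulate_run(SimulationParams(seed=STANDARD_SEED))


@pytest.fixture(scope="session")
def standard_run(standard_sim, tmp_path_factory):
    """Standard fixture written to disk; returns (result, paths)."""
    outdir = tmp_path_factory.mktemp("standard_run")
    return standard_sim, write_run(standard_sim, outdir)


@pytest.fixture(scope="session")
def noiseless_sim():
    return simulate_run(
        SimulationParams(
            seed=STANDARD_SEED,
            cid_error_rate=0.0,
            mid_error_rate=0.0,
            cdna_error_rate=0.0,
        )
    )


@pytest.fixture(scope="session")
def noiseless_run(noiseless_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("noiseless_run")
    return noiseless_sim, write_run(noiseless_sim, outdir)
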