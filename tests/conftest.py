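import numpy as np
import pytest

from polypet import (BLOCKS, CYLINDRICAL, ScannerSpec, build_crystal_map)


@pytest.fixture(scope="session")
def toy_spec():
    """Small 4-sector scanner: 16 detectors/ring, 2 rings."""
    return ScannerSpec(n_sectors=4, blocks_per_sector_trans=1,
                       blocks_per_sector_axial=1,
                       crystals_per_block_trans=4, crystals_per_block_axial=2,
                       crystal_pitch_trans=10.0, crystal_pitch_axial=10.0,
                       crystal_depth=5.0)


@pytest.fixture(scope="session")
def toy_blocks(toy_spec):
    return build_crystal_map(toy_spec, BLOCKS)


@pytest.fixture(scope="session")
def toy_cyl(toy_spec):
    return build_crystal_map(toy_spec, CYLINDRICAL)


@pytest.fixture(scope="session")
def mid_spec():
    """Mid-size octagon (48 detectors/ring, 3 rings) for estimation tests
    whose symmetry classes need more crystals than the toy scanner has."""
    return ScannerSpec(n_sectors=8, blocks_per_sector_trans=1,
                       blocks_per_sector_axial=1,
                       crystals_per_block_trans=6, crystals_per_block_axial=3,
                       crystal_pitch_trans=6.0, crystal_pitch_axial=6.0,
                       crystal_depth=5.0)


@pytest.fixture(scope="session")
def mid_blocks(mid_spec):
    return build_crystal_map(mid_spec, BLOCKS)


@pytest.fixture(scope="session")
def brain_spec():
    """The octagonal brain scanner, 1 mm crystals for resolution work."""
    return ScannerSpec(crystal_depth=1.0)


@pytest.fixture(scope="session")
def brain_blocks(brain_spec):
    return build_crystal_map(brain_spec, BLOCKS)


@pytest.fixture(scope="session")
def brain_cyl(brain_spec):
    return build_crystal_map(brain_spec, CYLINDRICAL)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
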