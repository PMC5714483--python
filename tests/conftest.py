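import numpy as np
import pytest

from histscreen.simulate import SimulationConfig, simulate_experiment

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.500   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       1.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       2.000   0.000   0.000  1.00  0.00           C
ATOM      5  CA  LEU A   4       4.000   0.000   0.000  1.00  0.00           C
ATOM      6  CA  LYS A   5       8.000   0.000   0.000  1.00  0.00           C
ATOM      7  CA  VAL A   6      16.000   0.000   0.000  1.00  0.00           C
ATOM      8  CA  THR A   7      32.000   0.000   0.000  1.00  0.00           C
ATOM      9  CA  GLU A   8      64.000   0.000   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture(scope="session")
def small_config():
    """A fast-but-representative simulation: 60 mutants, 4 samples."""
    return SimulationConfig(
        n_mutants=60,
        n_samples=4,
        read_pairs_per_sample=3000,
        seq_error_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    return simulate_experiment(small_config, outdir=outdir)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def toy_pdb(tmp_path_factory):
    """Synthetic 8-residue single-chain structure on an exponential line."""
    path = tmp_path_factory.mktemp("pdb") / "toy_line.pdb"
    path.write_text(TOY_PDB)
    return path
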