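import numpy as np
import pytest

from ggcx_motion import (
    CAP_EXPR,
    CORE_EXPR,
    HELIX_EXPR,
    SyntheticTruth,
    gen_coupled_trajectory,
    gen_template,
    select,
)


@pytest.fixture(scope="session")
def template():
    return gen_template(seed=1)


@pytest.fixture(scope="session")
def selections(template):
    return {
        "core": select(template, CORE_EXPR),
        "helix": select(template, HELIX_EXPR),
        "cap": select(template, CAP_EXPR),
    }


@pytest.fixture(scope="session")
def noiseless_run(template):
    """Perfectly coupled trajectory (rho=-1, no noise) with its ground truth."""
    truth = SyntheticTruth(
        coupling_rho=-1.0, noise_sigma=0.0, core_jitter_sigma=0.0, seed=3
    )
    traj, theta_true, d_true = gen_coupled_trajectory(template, truth)
    return truth, traj, theta_true, d_true


TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60 10.00           C
ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.40 10.00           C
ATOM      3  CA  ALA A   2       3.000   0.000   0.000  1.00 10.00           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TINY_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p
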