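import numpy as np
import pandas as pd
import pytest

from sectordyn.msa_io import Alignment
from sectordyn.trajectory import Trajectory


@pytest.fixture
def toy_alignment() -> Alignment:
    """4 sequences x 6 columns; column 4 is 75% gaps."""
    return Alignment(
        seq_ids=["ref", "s1", "s2", "s3"],
        rows=["ACDEFG", "ACDE-G", "ACEE-G", "GCDE-G"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_trajectory(coords: np.ndarray, atom_names=None) -> Trajectory:
    """Trajectory from (F, N, 3) coordinates with one CA per residue."""
    n = coords.shape[1]
    meta = pd.DataFrame(
        {
            "residue_number": np.arange(1, n + 1),
            "residue_name": ["ALA"] * n,
            "atom_name": atom_names if atom_names is not None else ["CA"] * n,
        }
    )
    return Trajectory(coords=np.asarray(coords, dtype=float), atom_meta=meta)


@pytest.fixture
def fasta_file(tmp_path):
    p = tmp_path / "toy.fasta"
    p.write_text(">a\nAC-D\n>b\nACED\n")
    return p


@pytest.fixture
def stockholm_file(tmp_path):
    p = tmp_path / "toy.sto"
    p.write_text(
        "# STOCKHOLM 1.0\n"
        "seq1 AC.D\n"
        "seq2 ACED\n"
        "//\n"
    )
    return p
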