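import numpy as np
import pytest

from ppiforest.pssm_io import PSSM, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pssm(rng):
    """Random integer 6x20 PSSM."""
    return PSSM(protein_id="p1", scores=rng.integers(-7, 8, size=(6, 20)))


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "seqs.fasta"
    path.write_text(">p1 some description\nMKV\n>p2\nACDEF\nGHIKX\n")
    return path


@pytest.fixture
def ascii_pssm_file(tmp_path):
    """Hand-written PSI-BLAST -out_ascii_pssm style fixture: 3 residues,
    first row scores 1..20, with the 20 percentage columns and trailing
    statistics lines that a real file carries."""
    letters = "A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V"
    row1 = " ".join(str(v) for v in range(1, 21))
    zeros40 = " ".join(["0"] * 40)
    text = (
        "\n"
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts\n"
        f"           {letters}   {letters}\n"
        f"    1 M   {row1}  " + " ".join(["0"] * 20) + "  0.36 0.12\n"
        f"    2 K   {zeros40}  0.00 0.00\n"
        f"    3 V   {zeros40}  0.00 0.00\n"
        "\n"
        "                      K         Lambda\n"
        "Standard Ungapped    0.1347     0.3179\n"
    )
    path = tmp_path / "query.pssm"
    path.write_text(text)
    return path
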