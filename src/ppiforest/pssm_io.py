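"""Sequence and profile I/O.

Reads FASTA files, parses PSI-BLAST ASCII position-specific scoring
matrices (the ``-out_ascii_pssm`` dialect), writes/reads a plain TSV form
of a PSSM, and constructs (but never executes) PSI-BLAST command lines.

A PSSM is the T x 20 matrix of per-residue log-odds substitution scores
produced by iterative profile search: row *i* scores the mutation of
residue *i* to each of the 20 standard amino acids.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "SequenceRecord",
    "PSSM",
    "PssmParseError",
    "read_fasta",
    "parse_ascii_pssm",
    "write_pssm_tsv",
    "psiblast_command",
]

#: The 20 standard amino-acid letters in PSI-BLAST column order.
AMINO_ACIDS: tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")


class PssmParseError(ValueError):
    """Raised when a FASTA or PSSM file cannot be parsed."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein sequence over the 20 amino-acid letters (plus X/B/Z)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PSSM:
    """Position-specific scoring matrix for one protein.

    ``scores`` has one row per residue and exactly 20 columns, one per
    amino acid in ``column_order`` (PSI-BLAST file order by default).
    """

    protein_id: str
    scores: np.ndarray
    column_order: tuple[str, ...] = field(default=AMINO_ACIDS)

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM {self.protein_id!r}: expected T x 20 scores, "
                f"got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError(f"PSSM {self.protein_id!r}: zero rows")
        if len(self.column_order) != 20:
            raise ValueError("column_order must list 20 letters")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved; sequences are upper-cased with whitespace removed.
    Malformed headers or empty record bodies raise :class:`PssmParseError`
    naming the offending line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    current_id: str | None = None
    current_seq: list[str] = []
    header_line = 0

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(current_seq)
        if not seq:
            raise PssmParseError(
                f"{path}: record {current_id!r} (header at line {header_line}) "
                "has an empty sequence"
            )
        records.append(SequenceRecord(id=current_id, sequence=seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].strip() else ""
                if not current_id:
                    raise PssmParseError(f"{path}: empty FASTA header at line {lineno}")
                current_seq = []
                header_line = lineno
            else:
                if current_id is None:
                    raise PssmParseError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                current_seq.append(line.upper().replace(" ", ""))
    flush()
    if not records:
        raise PssmParseError(f"{path}: no FASTA records found")
    return records


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def parse_ascii_pssm(path: str | Path, protein_id: str | None = None) -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file (or a PSSM TSV) into a PSSM.

    The ASCII dialect carries, per residue row, a position index, the
    residue letter, 20 substitution-score columns and 20 weighted-percentage
    columns (plus two trailing floats); only the first 20 score columns are
    kept.  A bare numeric row of exactly 20 fields (the TSV form written by
    :func:`write_pssm_tsv`) is accepted as well.  Header and trailing
    statistics lines are ignored.
    """
    path = Path(path)
    pid = protein_id if protein_id is not None else path.stem
    rows: list[list[float]] = []
    column_order: tuple[str, ...] = AMINO_ACIDS

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            toks = raw.split()
            if not toks:
                continue
            # Column-letter header (ASCII dialect repeats the alphabet twice;
            # the TSV header lists it once).
            if all(len(t) == 1 and t.isalpha() for t in toks) and len(toks) in (20, 40):
                column_order = tuple(toks[:20])
                continue
            if all(_is_number(t) for t in toks):
                if len(toks) == 20:
                    rows.append([float(t) for t in toks])
                    continue
                # Trailing statistics lines (K/lambda etc.) have few fields.
                if rows and len(toks) < 20:
                    continue
                if not rows and len(toks) < 20:
                    continue
                raise PssmParseError(
                    f"{path}: line {lineno}: numeric row with {len(toks)} fields, "
                    "expected 20 score fields"
                )
            # Residue row: index, letter, then numbers.
            if (
                len(toks) >= 22
                and toks[0].lstrip("-").isdigit()
                and len(toks[1]) == 1
                and toks[1].isalpha()
            ):
                nums = toks[2:]
                if not all(_is_number(t) for t in nums):
                    raise PssmParseError(
                        f"{path}: line {lineno}: non-numeric field in residue row"
                    )
                if len(nums) not in (40, 41, 42, 20):
                    raise PssmParseError(
                        f"{path}: line {lineno}: residue row with {len(nums)} numeric "
                        "fields, expected 40 (+2 stats) or 20"
                    )
                rows.append([float(t) for t in nums[:20]])
                continue
            # Anything else (titles, blank-ish lines) is header/footer noise.
            continue

    if not rows:
        raise PssmParseError(f"{path}: no PSSM data rows found")
    return PSSM(protein_id=pid, scores=np.array(rows, dtype=float), column_order=column_order)


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_pssm_tsv(pssm: PSSM, path: str | Path) -> None:
    """Write a PSSM as TSV: a header row of the 20 letters, then one row of
    20 scores per residue.  Integer scores round-trip exactly through
    :func:`parse_ascii_pssm`; non-integer scores are written at full
    precision."""
    path = Path(path)
    lines = ["\t".join(pssm.column_order)]
    for row in pssm.scores:
        lines.append("\t".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def psiblast_command(
    seq_path: str | Path,
    db_path: str | Path,
    out_pssm: str | Path,
    evalue: float = 0.001,
    iterations: int = 3,
) -> str:
    """Build (never run) the PSI-BLAST command that would produce an ASCII
    PSSM for one query sequence.

    Defaults follow the profile-search protocol used throughout this
    pipeline: inclusion e-value 0.001 and 3 search iterations.
    """
    if not evalue > 0:
        raise ValueError(f"evalue must be positive, got {evalue}")
    if iterations < 1:
        raise ValueError(f"iterations must be >= 1, got {iterations}")
    parts = [
        "psiblast",
        "-query",
        str(seq_path),
        "-db",
        str(db_path),
        "-evalue",
        str(evalue),
        "-num_iterations",
        str(iterations),
        "-out_ascii_pssm",
        str(out_pssm),
    ]
    return " ".join(shlex.quote(p) for p in parts)
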