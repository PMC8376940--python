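"""Fixed-length protein descriptors from variable-length PSSMs.

A PSSM has one row per residue, so its shape varies from protein to
protein.  The descriptor used here is the normalized cross-product matrix

    F = P'^T P' / T,    P' = sigmoid(P)  elementwise,

a 20 x 20 summary of inter-amino-acid evolutionary covariation that is
invariant to sequence length (duplicating every row leaves F unchanged)
and to row order.  Flattened row-major it gives the 400-dimensional
vector consumed by the OLPP embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .pssm_io import PSSM

__all__ = [
    "DESCRIPTOR_DIM",
    "ProteinDescriptor",
    "PairFeature",
    "normalize_pssm",
    "pssm_descriptor",
    "make_pair_features",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "read_descriptors_tsv",
    "write_descriptors_tsv",
]

DESCRIPTOR_DIM = 400


@dataclass(frozen=True)
class ProteinDescriptor:
    """400-dimensional length-invariant summary of one protein's PSSM."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (DESCRIPTOR_DIM,):
            raise ValueError(
                f"descriptor for {self.protein_id!r} must have length "
                f"{DESCRIPTOR_DIM}, got {self.values.shape}"
            )


@dataclass(frozen=True)
class PairFeature:
    """Concatenated embeddings of a protein pair, with optional 0/1 label."""

    pair: tuple[str, str]
    values: np.ndarray
    label: int | None = None


def normalize_pssm(pssm: PSSM) -> np.ndarray:
    """Map raw log-odds scores into (0, 1) with the elementwise logistic
    function s(x) = 1 / (1 + e^-x).  Shape is preserved."""
    return expit(pssm.scores)


def pssm_descriptor(pssm: PSSM) -> ProteinDescriptor:
    """Compute the 400-dim descriptor F = P'^T P' / T, flattened row-major.

    F is symmetric as a 20 x 20 matrix with entries in (0, 1], and is
    unchanged if the PSSM is stacked with a copy of itself.
    """
    p = normalize_pssm(pssm)
    t = p.shape[0]
    f = (p.T @ p) / t
    return ProteinDescriptor(protein_id=pssm.protein_id, values=f.ravel(order="C"))


def make_pair_features(
    embeddings: Mapping[str, np.ndarray],
    pairs: Sequence[tuple[str, str, int | None]],
) -> list[PairFeature]:
    """Concatenate the two proteins' embeddings (A then B) for every pair.

    Labels are carried through untouched.  A pair id missing from
    ``embeddings`` raises ``KeyError`` naming the id.
    """
    out: list[PairFeature] = []
    for entry in pairs:
        id_a, id_b = entry[0], entry[1]
        label = entry[2] if len(entry) > 2 else None
        for pid in (id_a, id_b):
            if pid not in embeddings:
                raise KeyError(f"no embedding for protein id {pid!r}")
        values = np.concatenate(
            [np.asarray(embeddings[id_a], float), np.asarray(embeddings[id_b], float)]
        )
        out.append(PairFeature(pair=(id_a, id_b), values=values, label=label))
    return out


def read_pairs_tsv(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a pair list TSV with columns idA, idB, label (0/1).

    A header row is detected by a non-numeric third column.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: pair list needs 3 columns (idA, idB, label)")
    first = str(df.iloc[0, 2])
    if not first.lstrip("-").isdigit():
        df = df.iloc[1:]
    out = []
    for _, row in df.iterrows():
        label = int(row.iloc[2])
        if label not in (0, 1):
            raise ValueError(f"{path}: label must be 0 or 1, got {label}")
        out.append((str(row.iloc[0]), str(row.iloc[1]), label))
    return out


def write_pairs_tsv(pairs: Sequence[tuple[str, str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("idA\tidB\tlabel\n")
        for a, b, y in pairs:
            fh.write(f"{a}\t{b}\t{y}\n")


def write_descriptors_tsv(
    descriptors: Mapping[str, np.ndarray], path: str | Path
) -> None:
    """One row per protein: id followed by the descriptor entries."""
    ids = list(descriptors)
    mat = np.vstack([np.asarray(descriptors[i], float) for i in ids])
    df = pd.DataFrame(mat, index=pd.Index(ids, name="protein_id"))
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_descriptors_tsv(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {str(i): row.to_numpy(dtype=float) for i, row in df.iterrows()}
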