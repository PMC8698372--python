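"""Supervised mode: externally supplied functional-similarity matrices.

In supervised mode the correlation target is not derived from the
sequences but imposed from outside — any symmetric matrix of pairwise
functional similarities over the aligned proteins (for instance chemical
similarities of bound ligands).  The matrix is consumed as a labelled
square text table; how it was produced is the caller's business, and no
range restriction is placed on its values.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .alignment import Alignment
from .errors import FunctionalMatrixError
from .scoring import SimilarityMatrix

#: Asymmetries larger than this are treated as data errors, not noise.
SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class FunctionalSimilarityMatrix:
    """A validated symmetric matrix of pairwise functional similarities.

    May cover more proteins than a given alignment; it is subset and
    reordered to the alignment with :func:`align_to_alignment`.  Diagonal
    entries, if present in the source file, are carried but never used —
    all statistics run over off-diagonal pairs only.
    """

    labels: tuple[str, ...]
    square: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        arr = np.asarray(self.square, dtype=float)
        n = len(self.labels)
        if arr.shape != (n, n):
            raise FunctionalMatrixError(
                f"matrix shape {arr.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise FunctionalMatrixError("duplicate protein labels")
        if not np.all(np.isfinite(arr)):
            raise FunctionalMatrixError("matrix contains non-finite entries")
        asym = np.abs(arr - arr.T).max() if n else 0.0
        if asym > SYMMETRY_TOL:
            raise FunctionalMatrixError(
                f"matrix is asymmetric (max |A - A.T| = {asym:.3g})")
        object.__setattr__(self, "square", (arr + arr.T) / 2.0)


def read_functional_matrix(source: str | Path | IO[str]) -> FunctionalSimilarityMatrix:
    """Read a labelled square matrix from tab- or whitespace-delimited text.

    The first row and first column carry the protein identifiers; row and
    column identifier sets must coincide (column order may differ and is
    realigned to row order).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    try:
        df = pd.read_csv(io.StringIO(text), sep=r"\s+", index_col=0, comment="#")
    except Exception as exc:
        raise FunctionalMatrixError(f"could not parse matrix table: {exc}") from exc
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if len(rows) != len(cols) or set(rows) != set(cols):
        raise FunctionalMatrixError(
            f"matrix is not square over one protein set: {len(rows)} row labels"
            f" vs {len(cols)} column labels")
    df.columns = cols
    df = df.loc[:, rows]  # realign column order to row order
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FunctionalMatrixError("matrix contains non-numeric entries")
    return FunctionalSimilarityMatrix(labels=tuple(rows), square=values.astype(float))


def align_to_alignment(matrix: FunctionalSimilarityMatrix,
                       alignment: Alignment) -> SimilarityMatrix:
    """Subset and reorder the matrix to the alignment's protein order.

    Extra proteins in the matrix are dropped; proteins missing from it
    are an error (all of them are named).
    """
    pos = {label: i for i, label in enumerate(matrix.labels)}
    missing = [pid for pid in alignment.ids if pid not in pos]
    if missing:
        raise FunctionalMatrixError(
            f"functional matrix is missing alignment protein(s): {missing}")
    idx = np.array([pos[pid] for pid in alignment.ids])
    sub = matrix.square[np.ix_(idx, idx)]
    return SimilarityMatrix.from_square(alignment.ids, sub)
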