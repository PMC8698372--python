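"""Core SDP scoring: similarity matrices and the Spearman position score.

The method compares, for every retained alignment column, a matrix of
pairwise residue similarities at that column against a target matrix of
pairwise protein similarities.  In unsupervised mode the target is the
global sequence-similarity matrix (mean per-column substitution-matrix
similarity); in supervised mode it is an externally supplied
functional-similarity matrix.  The comparison statistic is the Spearman
rank-order correlation over the unordered off-diagonal protein pairs
(i < j), with mid-ranks for ties:

    rho_kp = corr(rank(S_kp), rank(M))

where ``S_kp`` collects, for column ``k`` and channel ``p``, the pairwise
similarities of the residues of proteins i and j (exactly 0 for any pair
involving a gap) and ``M`` is the target.  Channels are the substitution
matrix itself (reported with an empty property label) and one channel
per property scale.

Columns with more than ``gap_threshold`` gaps (default 10%) are excluded.
A column whose similarity vector is constant — e.g. a fully conserved,
gap-free column — has no rank variance and its score is *undefined*
(``None``), never coerced to a number: complete conservation is the
opposite of subfamily-specific conservation and must not masquerade as
"no correlation".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import GAP_CODE, Alignment, Column
from .errors import ScoringError
from .scales import (
    AA_INDEX,
    PropertyScale,
    SubstitutionMatrix,
    property_similarity_matrix,
)

Channel = Union[SubstitutionMatrix, PropertyScale]

#: Substitution-matrix channel label in reports (an empty property field).
SUBSTITUTION_LABEL = ""

#: Channel similarity tables are rounded to this many decimals before any
#: ranking, so that mathematically tied value differences compare equal
#: despite floating-point representation (see docs/methods.md).
TABLE_DECIMALS = 9


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise similarities over proteins; only unordered i < j pairs stored.

    The diagonal carries no information for a rank correlation and is
    excluded from every statistic, so it is not represented at all.
    ``condensed`` follows scipy's squareform ordering: (0,1), (0,2), ...
    """

    labels: tuple[str, ...]
    condensed: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        vec = np.asarray(self.condensed, dtype=float)
        n = len(self.labels)
        if vec.shape != (n * (n - 1) // 2,):
            raise ScoringError(
                f"condensed vector of length {vec.shape} does not match {n} labels")
        object.__setattr__(self, "condensed", vec)

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_square(cls, labels: Sequence[str], square: np.ndarray) -> "SimilarityMatrix":
        square = np.asarray(square, dtype=float)
        iu = np.triu_indices(len(labels), k=1)
        return cls(labels=tuple(labels), condensed=square[iu])

    def value(self, a: str, b: str) -> float:
        """Similarity of the (unordered) protein pair ``a``, ``b``."""
        i, j = self.labels.index(a), self.labels.index(b)
        if i == j:
            raise ScoringError("diagonal entries are not stored")
        if i > j:
            i, j = j, i
        n = self.n
        k = i * n - i * (i + 1) // 2 + (j - i - 1)
        return float(self.condensed[k])


@dataclass(frozen=True)
class ScoreRecord:
    """One (column, channel) score — the machine twin of a report row."""

    column: int
    reference_residue: str | None
    reference_number: int | None
    property: str  # "" means the substitution-matrix channel
    score: float | None

    @property
    def defined(self) -> bool:
        return self.score is not None


@dataclass(frozen=True)
class ScoreTable:
    """Ranked, defined-score records ready for reporting."""

    records: tuple[ScoreRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Position": [r.column for r in self.records],
                "RefResidue": [r.reference_residue or "" for r in self.records],
                "RefNumber": [r.reference_number for r in self.records],
                "Property": [r.property for r in self.records],
                "Score": [r.score for r in self.records],
            }
        )

    def to_tsv(self, dest: IO[str], decimals: int | None = 4) -> None:
        """Write the table as tab-separated text; ``decimals=None`` for full precision."""
        dest.write("Position\tRefResidue\tRefNumber\tProperty\tScore\n")
        for r in self.records:
            num = "" if r.reference_number is None else str(r.reference_number)
            res = r.reference_residue or ""
            if r.score is None:
                score = "NA"
            elif decimals is None:
                score = repr(r.score)
            else:
                score = f"{r.score:.{decimals}f}"
            dest.write(f"{r.column}\t{res}\t{num}\t{r.property}\t{score}\n")


# ---------------------------------------------------------------------------
# channel lookup tables


def channel_label(channel: Channel) -> str:
    return SUBSTITUTION_LABEL if isinstance(channel, SubstitutionMatrix) else channel.name


def _channel_table(channel: Channel) -> np.ndarray:
    """21x21 similarity lookup: residues 0..19 plus the gap code at index 20.

    Any pair involving a gap is exactly 0.  Entries are rounded to
    :data:`TABLE_DECIMALS` so mathematically tied similarities rank as ties.
    """
    if isinstance(channel, SubstitutionMatrix):
        core = channel.array
    else:
        core = property_similarity_matrix(channel)
    table = np.zeros((21, 21))
    table[:20, :20] = np.round(core, TABLE_DECIMALS)
    return table


# ---------------------------------------------------------------------------
# similarity matrices


def global_similarity_matrix(alignment: Alignment,
                             subst: SubstitutionMatrix) -> SimilarityMatrix:
    """Mean per-column substitution similarity between every protein pair.

    Every alignment column contributes: a column where either protein is
    gapped adds 0 to the sum, and the denominator is the full alignment
    length — the pairwise analogue of the per-position gap rule.
    """
    codes = alignment.codes()
    n, length = codes.shape
    iu, ju = np.triu_indices(n, k=1)
    vec = np.empty(len(iu))
    arr = subst.array
    for k, (i, j) in enumerate(zip(iu, ju)):
        ci, cj = codes[i], codes[j]
        mask = (ci != GAP_CODE) & (cj != GAP_CODE)
        vec[k] = arr[ci[mask], cj[mask]].sum() / length
    return SimilarityMatrix(labels=alignment.ids, condensed=vec)


def position_similarity_matrix(alignment_or_labels, column: Column,
                               channel: Channel) -> SimilarityMatrix:
    """Pairwise residue similarities of one column under one channel.

    ``alignment_or_labels`` supplies the protein labels (an
    :class:`Alignment` or a sequence of ids).  Any pair involving a gap
    gets exactly 0.
    """
    labels = (alignment_or_labels.ids if isinstance(alignment_or_labels, Alignment)
              else tuple(alignment_or_labels))
    if len(labels) != len(column.residues):
        raise ScoringError("column size does not match the number of labels")
    table = _channel_table(channel)
    codes = np.array([AA_INDEX.get(ch, 20) for ch in column.residues])
    codes[codes < 0] = 20
    iu, ju = np.triu_indices(len(codes), k=1)
    return SimilarityMatrix(labels=labels, condensed=table[codes[iu], codes[ju]])


# ---------------------------------------------------------------------------
# the score


def spearman_matrix_correlation(a: SimilarityMatrix,
                                b: SimilarityMatrix) -> float | None:
    """Spearman rank correlation of two similarity matrices' pair entries.

    Both condensed vectors are ranked with mid-ranks for ties, and the
    Pearson correlation of the rank vectors is returned.  ``None`` when
    either vector is constant (zero rank variance leaves the coefficient
    undefined).
    """
    if a.labels != b.labels:
        raise ScoringError("similarity matrices are over different protein sets"
                           " or orderings")
    x, y = a.condensed, b.condensed
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    rho = stats.spearmanr(x, y).statistic
    return None if np.isnan(rho) else float(rho)


def score_all(alignment: Alignment, channels: Sequence[Channel],
              target: SimilarityMatrix,
              gap_threshold: float = 0.10) -> list[ScoreRecord]:
    """Score every retained column under every channel against the target.

    Columns whose gap fraction exceeds ``gap_threshold`` yield no records
    (a fraction exactly equal to the threshold is retained).  Records with
    undefined scores are kept, flagged by ``score is None``, and excluded
    from ranking downstream.
    """
    if tuple(target.labels) != alignment.ids:
        raise ScoringError("target matrix labels do not match the alignment")
    if not 0 <= gap_threshold <= 1:
        raise ScoringError(f"gap threshold {gap_threshold} outside [0, 1]")
    if not channels:
        raise ScoringError("no channels to score")

    numbering = alignment.reference_numbering()
    retained = [k for k in range(1, alignment.length + 1)
                if alignment.gap_fraction(k) <= gap_threshold]
    if not retained:
        raise ScoringError(
            f"nothing to score: every column exceeds the {gap_threshold:.0%}"
            " gap threshold")

    records: list[ScoreRecord] = []
    for k in retained:
        col = alignment.column(k)
        for channel in channels:
            pos = position_similarity_matrix(alignment, col, channel)
            rho = spearman_matrix_correlation(pos, target)
            records.append(ScoreRecord(
                column=k,
                reference_residue=alignment.reference_residue(k),
                reference_number=numbering[k],
                property=channel_label(channel),
                score=rho,
            ))
    return records


def rank_scores(records: Iterable[ScoreRecord],
                top: int | None = None) -> ScoreTable:
    """Sort defined-score records by score (desc), then column, then property.

    Ties break toward the lower column, then the lexicographically earlier
    property label (the empty substitution-matrix label first).  Undefined
    scores are dropped from the ranking.
    """
    defined = [r for r in records if r.defined]
    defined.sort(key=lambda r: (-r.score, r.column, r.property))
    if top is not None:
        if top < 0:
            raise ScoringError("top must be non-negative")
        defined = defined[:top]
    return ScoreTable(records=tuple(defined))


def score_alignment(alignment: Alignment, channels: Sequence[Channel],
                    target: SimilarityMatrix | None = None,
                    subst: SubstitutionMatrix | None = None,
                    gap_threshold: float = 0.10,
                    top: int | None = None) -> ScoreTable:
    """End-to-end programmatic entry point.

    With ``target=None`` (unsupervised mode) the target is the global
    sequence-similarity matrix built from ``subst``; supplying a target
    switches to supervised mode.  ``subst`` must be given when the channel
    list contains no substitution matrix to build the global matrix from.
    """
    if target is None:
        if subst is None:
            subst = next((c for c in channels if isinstance(c, SubstitutionMatrix)),
                         None)
        if subst is None:
            raise ScoringError("unsupervised mode needs a substitution matrix")
        target = global_similarity_matrix(alignment, subst)
    return rank_scores(score_all(alignment, channels, target, gap_threshold), top=top)
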