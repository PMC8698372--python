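"""Synthetic alignments with planted subfamily structure.

Real test families for SDP detection are scarce, so this module builds
alignments with known ground truth: a configurable number of
subfamilies, *planted SDP columns* where each subfamily fixes its own
residue (residues chosen maximally spread along a chosen property
scale, the cleanest form of subfamily-dependent conservation), fully
conserved columns, and neutral columns of uniform residue noise.

Because the unsupervised target matrix is built from the sequences
themselves, a weak subfamily signal is also spread over a fraction of
the neutral columns (each subfamily mildly prefers its own residue
there).  Without that background the subfamily structure would live in
the planted column alone and the target matrix would be pure noise —
in real families, phylogeny pervades the whole alignment.

The background bias also encodes *which* subfamilies are close: under
divergent evolution the functional axis tracks the phylogeny, so
subfamilies whose planted residues sit close on the planted scale
should also be close in overall sequence.  Biased columns therefore
let one pair of subfamilies share a single preferred residue, with the
number of columns allocated to each pair proportional to the squared
planted-scale similarity of their SDP residues (deterministic
largest-remainder allocation).  Gaps are injected only into neutral
columns so gap handling can be tested orthogonally to the planted
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Sequence, Union

import numpy as np

from .alignment import GAP, Alignment
from .errors import SyntheticError
from .scales import (
    AMINO_ACIDS,
    PropertyScale,
    SubstitutionMatrix,
    load_builtin_scales,
    load_mclachlan,
)

#: Property label denoting the substitution-matrix channel in specs/ground truth.
SUBSTITUTION_CHANNEL = ""


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic alignment.

    Defaults produce the standard test condition: 3 subfamilies of 5
    sequences, 50 columns, one SDP planted on the Kyte-Doolittle
    hydrophobicity scale, two fully conserved columns, 5% gaps in
    neutral columns, and a weak subfamily bias over 30% of the neutral
    columns (preferred residue drawn with probability 0.6).
    """

    n_subfamilies: int = 3
    per_subfamily: int = 5
    n_columns: int = 50
    sdp_columns: tuple[tuple[int, str], ...] = ((25, "hdf_KD"),)
    conserved_columns: tuple[int, ...] = (1, 50)
    gap_rate: float = 0.05
    biased_fraction: float = 0.30
    bias_probability: float = 0.60
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sdp_columns",
                           tuple((int(c), str(p)) for c, p in self.sdp_columns))
        object.__setattr__(self, "conserved_columns",
                           tuple(int(c) for c in self.conserved_columns))
        if self.n_subfamilies < 2:
            raise SyntheticError("need at least 2 subfamilies")
        if self.per_subfamily < 2:
            raise SyntheticError("need at least 2 sequences per subfamily")
        if self.n_columns < 1:
            raise SyntheticError("need at least 1 column")
        planted = [c for c, _ in self.sdp_columns] + list(self.conserved_columns)
        if len(set(planted)) != len(planted):
            raise SyntheticError("planted column lists must be disjoint")
        out = [c for c in planted if not 1 <= c <= self.n_columns]
        if out:
            raise SyntheticError(f"planted column(s) out of range: {out}")
        for name, rate in [("gap_rate", self.gap_rate),
                           ("biased_fraction", self.biased_fraction),
                           ("bias_probability", self.bias_probability)]:
            if not 0 <= rate <= 1:
                raise SyntheticError(f"{name} must lie in [0, 1]")

    @property
    def n_sequences(self) -> int:
        return self.n_subfamilies * self.per_subfamily

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "sdp_columns" in d:
            d["sdp_columns"] = tuple(
                (int(c), str(p)) for c, p in (tuple(e) for e in d["sdp_columns"]))
        if "conserved_columns" in d:
            d["conserved_columns"] = tuple(int(c) for c in d["conserved_columns"])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise SyntheticError(f"unknown spec field(s): {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class PlantedColumn:
    """Ground truth for one planted column."""

    column: int
    kind: str  # "sdp" or "conserved"
    property: str  # scale label, or "" for the substitution channel / conserved
    residues: tuple[str, ...]  # per-subfamily for sdp, a single residue otherwise


@dataclass(frozen=True)
class GroundTruth:
    records: tuple[PlantedColumn, ...]

    @property
    def sdp_columns(self) -> tuple[int, ...]:
        return tuple(r.column for r in self.records if r.kind == "sdp")

    def to_tsv(self, dest: IO[str]) -> None:
        dest.write("column\tkind\tproperty\tresidues\n")
        for r in sorted(self.records, key=lambda r: r.column):
            dest.write(f"{r.column}\t{r.kind}\t{r.property}\t{','.join(r.residues)}\n")


def spread_residues(channel: Union[PropertyScale, SubstitutionMatrix],
                    k: int) -> tuple[str, ...]:
    """Pick ``k`` residues maximally spread under a channel's dissimilarity.

    Greedy farthest-point selection: start from the pair realising the
    maximum dissimilarity, then repeatedly add the residue with the
    largest minimum dissimilarity to those already chosen.  Ties break
    toward the canonical residue order, so selection is deterministic.
    """
    if isinstance(channel, PropertyScale):
        v = channel.as_array()
        dist = np.abs(v[:, None] - v[None, :])
        n_distinct = len(set(v.tolist()))
    else:
        arr = channel.array
        diag = np.diag(arr)
        dist = diag[:, None] + diag[None, :] - 2.0 * arr
        n_distinct = 20
    if k > n_distinct:
        raise SyntheticError(
            f"cannot spread {k} subfamilies over {n_distinct} distinct residue"
            f" values of channel {getattr(channel, 'name', '?')!r}")
    # lexicographically-first argmax pair
    i, j = divmod(int(np.argmax(dist)), 20)
    chosen = [min(i, j), max(i, j)]
    while len(chosen) < k:
        mindist = dist[:, chosen].min(axis=1)
        mindist[chosen] = -np.inf
        nxt = int(np.argmax(mindist))
        if mindist[nxt] <= 0:
            raise SyntheticError(
                f"channel {getattr(channel, 'name', '?')!r} has too few distinct"
                f" values to separate {k} subfamilies")
        chosen.append(nxt)
    return tuple(AMINO_ACIDS[c] for c in chosen)


def _cross_similarity(channel: Union[PropertyScale, SubstitutionMatrix],
                      m: str, n: str) -> float:
    if isinstance(channel, PropertyScale):
        return channel.maxdiff - abs(channel.value(m) - channel.value(n))
    return max(channel.value(m, n), 0.0)


def _largest_remainder(weights: list[float], total: int) -> list[int]:
    """Apportion ``total`` integer slots proportionally to ``weights``."""
    s = sum(weights)
    if s <= 0 or total <= 0:
        return [0] * len(weights)
    quotas = [total * w / s for w in weights]
    counts = [int(q) for q in quotas]
    leftover = total - sum(counts)
    by_frac = sorted(range(len(weights)), key=lambda i: -(quotas[i] - counts[i]))
    for i in by_frac[:leftover]:
        counts[i] += 1
    return counts


def _shared_pair_schedule(spec: SyntheticSpec,
                          channel: Union[PropertyScale, SubstitutionMatrix],
                          residues: tuple[str, ...],
                          n_biased: int) -> list[tuple[int, int] | None]:
    """Which subfamily pair (if any) shares a preferred residue, per biased column.

    Biased columns are apportioned over subfamily pairs by the cubed
    planted-scale similarity of their SDP residues, so that functionally
    close subfamilies end up close in overall sequence as well.  No pair
    takes more than 60% of the biased columns — within-subfamily
    similarity (reinforced in every biased column) must stay above any
    cross-subfamily similarity.  Unassigned columns keep fully
    independent per-subfamily preferences.
    """
    pairs = [(s, t) for s in range(spec.n_subfamilies)
             for t in range(s + 1, spec.n_subfamilies)]
    weights = [_cross_similarity(channel, residues[s], residues[t]) ** 3
               for s, t in pairs]
    cap = int(0.6 * n_biased)
    counts = [min(c, cap) for c in _largest_remainder(weights, n_biased)]
    schedule: list[tuple[int, int] | None] = []
    for pair, c in zip(pairs, counts):
        schedule.extend([pair] * c)
    schedule.extend([None] * (n_biased - len(schedule)))
    return schedule


def _spread_preferences(rng: np.random.Generator, k: int,
                        dist: np.ndarray) -> np.ndarray:
    """Draw ``k`` preferred residue indices, biased toward mutual chemical
    dissimilarity (squared min-distance sampling), so that diverged
    subfamilies prefer chemically distinct residues."""
    idx = [int(rng.integers(20))]
    while len(idx) < k:
        d = dist[:, idx].min(axis=1).astype(float)
        d[idx] = 0.0
        w = d ** 2
        if w.sum() <= 0:
            remaining = [i for i in range(20) if i not in idx]
            idx.append(int(rng.choice(remaining)))
        else:
            idx.append(int(rng.choice(20, p=w / w.sum())))
    return np.array(idx)


def generate(spec: SyntheticSpec,
             scales: Sequence[PropertyScale] | None = None,
             subst: SubstitutionMatrix | None = None,
             ) -> tuple[Alignment, GroundTruth]:
    """Build the alignment described by ``spec`` plus its ground truth.

    Deterministic under ``spec.seed``: the same spec reproduces the
    alignment text exactly.
    """
    if scales is None:
        scales = load_builtin_scales()
    if subst is None:
        subst = load_mclachlan()
    by_name = {s.name: s for s in scales}

    channels: dict[int, Union[PropertyScale, SubstitutionMatrix]] = {}
    for col, label in spec.sdp_columns:
        if label == SUBSTITUTION_CHANNEL:
            channels[col] = subst
        elif label in by_name:
            channels[col] = by_name[label]
        else:
            raise SyntheticError(f"unknown property label {label!r} for planted"
                                 f" column {col}")

    rng = np.random.default_rng(spec.seed)
    n, length = spec.n_sequences, spec.n_columns
    diag = np.diag(subst.array)
    subst_dist = diag[:, None] + diag[None, :] - 2.0 * subst.array
    subfam = np.repeat(np.arange(spec.n_subfamilies), spec.per_subfamily)
    grid = np.empty((n, length), dtype="<U1")

    planted = {c for c, _ in spec.sdp_columns} | set(spec.conserved_columns)
    neutral = [c for c in range(1, length + 1) if c not in planted]
    n_biased = int(round(spec.biased_fraction * len(neutral)))
    biased = sorted(rng.choice(neutral, size=n_biased, replace=False).tolist()) \
        if n_biased else []

    records: list[PlantedColumn] = []
    sdp_residues = {col: spread_residues(channels[col], spec.n_subfamilies)
                    for col, _ in spec.sdp_columns}
    sdp_labels = dict(spec.sdp_columns)

    # subfamily relatedness in the background follows the first planted SDP
    if spec.sdp_columns and n_biased:
        anchor = spec.sdp_columns[0][0]
        schedule = _shared_pair_schedule(spec, channels[anchor],
                                         sdp_residues[anchor], n_biased)
        schedule = [schedule[i] for i in rng.permutation(n_biased)]
    else:
        schedule = [None] * n_biased
    shared_pair = dict(zip(biased, schedule))

    aa = np.array(list(AMINO_ACIDS))
    for col in range(1, length + 1):
        idx = col - 1
        if col in sdp_residues:
            residues = sdp_residues[col]
            grid[:, idx] = [residues[s] for s in subfam]
            records.append(PlantedColumn(column=col, kind="sdp",
                                         property=sdp_labels[col],
                                         residues=residues))
        elif col in spec.conserved_columns:
            res = aa[rng.integers(20)]
            grid[:, idx] = res
            records.append(PlantedColumn(column=col, kind="conserved",
                                         property="", residues=(str(res),)))
        else:
            cells = aa[rng.integers(0, 20, size=n)]
            if col in shared_pair:
                pref_idx = _spread_preferences(rng, spec.n_subfamilies, subst_dist)
                pair = shared_pair[col]
                if pair is not None:
                    pref_idx[pair[1]] = pref_idx[pair[0]]
                prefs = aa[pref_idx]
                take_pref = rng.random(n) < spec.bias_probability
                cells = np.where(take_pref, prefs[subfam], cells)
            if spec.gap_rate > 0:
                cells = np.where(rng.random(n) < spec.gap_rate, GAP, cells)
            grid[:, idx] = cells

    ids = tuple(f"sf{s + 1:02d}_seq{t + 1:02d}"
                for s in range(spec.n_subfamilies)
                for t in range(spec.per_subfamily))
    rows = tuple("".join(grid[i]) for i in range(n))
    return Alignment(ids=ids, rows=rows), GroundTruth(records=tuple(records))
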