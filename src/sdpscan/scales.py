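"""Amino-acid property scales and the substitution matrix.

A *property scale* assigns one quantitative value to each of the 20
standard amino acids (hydrophobicity, bulkiness, secondary-structure
propensity, ...).  From a scale we derive a pairwise residue similarity

    S(m, n) = MAXdiff - |value(m) - value(n)|

where ``MAXdiff`` is the largest absolute value difference over all
residue pairs, so that ``S`` lies in ``[0, MAXdiff]`` with the maximum on
identical residues.  Because all downstream comparisons are rank-based,
the native units of each scale are irrelevant and no normalisation is
applied.

The package bundles 12 ProtScale property scales, the 5 Atchley factors
(composite axes summarising several hundred amino-acid properties), and
the McLachlan substitution matrix, all as plain-text tables under
``sdpscan/data/``.  Additional user scales in the same two-column format
plug into the identical :class:`PropertyScale` contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np

from .errors import ScaleError

#: Canonical residue order used for all array representations.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX: Mapping[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def _data_dir():
    return resources.files("sdpscan") / "data"


@dataclass(frozen=True)
class PropertyScale:
    """A named mapping from the 20 standard amino acids to real values."""

    name: str
    values: Mapping[str, float]
    description: str = ""

    def __post_init__(self) -> None:
        got = set(self.values)
        want = set(AMINO_ACIDS)
        if got != want:
            missing = sorted(want - got)
            extra = sorted(got - want)
            raise ScaleError(
                f"scale {self.name!r}: expected exactly the 20 standard amino acids"
                f" (missing {missing}, unexpected {extra})"
            )
        for aa, v in self.values.items():
            if not math.isfinite(v):
                raise ScaleError(f"scale {self.name!r}: non-finite value for {aa}")
        if self.maxdiff <= 0:
            raise ScaleError(f"scale {self.name!r}: constant scale (MAXdiff == 0)")

    @property
    def maxdiff(self) -> float:
        """Largest |value(m) - value(n)| over all residue pairs."""
        vals = [self.values[aa] for aa in AMINO_ACIDS]
        return max(vals) - min(vals)

    def value(self, aa: str) -> float:
        try:
            return float(self.values[aa])
        except KeyError:
            raise ScaleError(f"scale {self.name!r}: {aa!r} is not a standard amino acid") from None

    def as_array(self) -> np.ndarray:
        """Values in canonical :data:`AMINO_ACIDS` order."""
        return np.array([self.values[aa] for aa in AMINO_ACIDS], dtype=float)

    def transformed(self, a: float, b: float, name: str | None = None) -> "PropertyScale":
        """Return the scale with every value mapped through ``a * x + b``."""
        if a == 0:
            raise ScaleError("affine transform must have a non-zero slope")
        return PropertyScale(
            name=name or self.name,
            values={aa: a * v + b for aa, v in self.values.items()},
            description=self.description,
        )


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric 20x20 amino-acid similarity table."""

    name: str
    array: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.array, dtype=float)
        if arr.shape != (20, 20):
            raise ScaleError(f"substitution matrix {self.name!r}: shape {arr.shape} != (20, 20)")
        if not np.all(np.isfinite(arr)):
            raise ScaleError(f"substitution matrix {self.name!r}: non-finite entries")
        if not np.array_equal(arr, arr.T):
            raise ScaleError(f"substitution matrix {self.name!r}: not symmetric")
        object.__setattr__(self, "array", arr)

    def value(self, m: str, n: str) -> float:
        try:
            return float(self.array[AA_INDEX[m], AA_INDEX[n]])
        except KeyError:
            bad = m if m not in AA_INDEX else n
            raise ScaleError(f"{bad!r} is not a standard amino acid") from None


def property_similarity(scale: PropertyScale, m: str, n: str) -> float:
    """Pairwise similarity ``MAXdiff - |value(m) - value(n)|`` of two residues."""
    return scale.maxdiff - abs(scale.value(n) - scale.value(m))


def property_similarity_matrix(scale: PropertyScale) -> np.ndarray:
    """The full 20x20 similarity table of a scale, in canonical residue order.

    Symmetric, with the constant ``MAXdiff`` on the diagonal and a zero at
    the pair attaining the maximum difference.
    """
    v = scale.as_array()
    return scale.maxdiff - np.abs(v[:, None] - v[None, :])


def _parse_two_column(lines: Iterable[str], origin: str) -> dict[str, float]:
    values: dict[str, float] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ScaleError(f"{origin}, line {lineno}: expected 'residue value', got {line!r}")
        aa, txt = parts
        aa = aa.upper()
        if aa in values:
            raise ScaleError(f"{origin}, line {lineno}: duplicate entry for {aa}")
        try:
            values[aa] = float(txt)
        except ValueError:
            raise ScaleError(f"{origin}, line {lineno}: non-numeric value {txt!r}") from None
    return values


def load_scale(source: str | Path | IO[str], name: str | None = None,
               description: str = "") -> PropertyScale:
    """Load a scale from a two-column (one-letter code, value) text table.

    Lines starting with ``#`` are comments.  The file must define exactly
    the 20 standard residues.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
        origin = name or "<stream>"
    else:
        path = Path(source)
        lines = path.read_text().splitlines()
        origin = str(path)
        if name is None:
            name = path.stem
    if name is None:
        raise ScaleError("a name is required when loading a scale from a stream")
    return PropertyScale(name=name, values=_parse_two_column(lines, origin),
                         description=description)


def load_builtin_scales() -> list[PropertyScale]:
    """The 17 bundled channels: 12 ProtScale property scales + 5 Atchley factors.

    Returned in manifest order; each satisfies the :class:`PropertyScale`
    invariants (validated on construction).
    """
    data = _data_dir()
    manifest = (data / "manifest.tsv").read_text().splitlines()
    scales = []
    for raw in manifest:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            fname, label, desc = line.split("\t")
        except ValueError:
            raise ScaleError(f"manifest.tsv: malformed line {line!r}") from None
        lines = (data / fname).read_text().splitlines()
        scales.append(PropertyScale(name=label, description=desc,
                                    values=_parse_two_column(lines, fname)))
    if len(scales) != 17:
        raise ScaleError(f"expected 17 bundled scales, found {len(scales)}")
    return scales


def load_mclachlan() -> SubstitutionMatrix:
    """The bundled McLachlan amino-acid substitution matrix."""
    lines = [ln for ln in (_data_dir() / "mclachlan.tsv").read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")[1:]
    if "".join(header) != AMINO_ACIDS:
        raise ScaleError("mclachlan.tsv: unexpected residue header")
    arr = np.full((20, 20), np.nan)
    for raw in lines[1:]:
        parts = raw.split("\t")
        m = parts[0]
        if m not in AA_INDEX or len(parts) != 21:
            raise ScaleError(f"mclachlan.tsv: malformed row {raw!r}")
        arr[AA_INDEX[m], :] = [float(x) for x in parts[1:]]
    if np.isnan(arr).any():
        missing = [AMINO_ACIDS[i] for i in np.unique(np.where(np.isnan(arr))[0])]
        raise ScaleError(f"mclachlan.tsv: missing rows for {missing}")
    return SubstitutionMatrix(name="McLachlan", array=arr)
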