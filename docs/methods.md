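# Methods

## The score

An alignment column is a candidate specificity-determining position
(SDP) when its pattern of residue similarities mirrors the pairwise
similarity structure of the proteins themselves. Both structures are
expressed as vectors over the unordered protein pairs `i < j` (the
diagonal carries no information and is never stored), and compared with
a Spearman rank-order correlation using mid-ranks for ties. Rank
correlation is what makes heterogeneous property scales commensurable:
only the ordering of pairwise similarities matters, so scales enter in
their native units and are never normalised.

Per column `k` there are 18 scores, one per channel: the McLachlan
substitution matrix (the "generic chemistry" channel, reported with an
empty property label) and 17 property scales. A property channel's
pairwise residue similarity is `MAXdiff_p − |p(m) − p(n)|`, which is
symmetric, maximal (`MAXdiff_p`) on identical residues and exactly zero
on the most dissimilar pair. Pairs involving a gap score exactly 0 —
the bottom of the similarity range — rather than being dropped, and the
gap filter (below) bounds how much weight such floor values can carry.

## Targets: unsupervised and supervised

The unsupervised target `M_ij` is the mean per-column McLachlan
similarity of proteins `i` and `j`. A column where either protein is
gapped contributes 0 while remaining in the denominator (the full
alignment length), the pairwise analogue of the per-position gap rule;
the two rules are kept consistent so that heavily gapped proteins look
distant both globally and positionally. The supervised target is any
symmetric labelled matrix over the aligned proteins; its scale and
range are deliberately unrestricted because only ranks are used.
Supplying the computed `M` as a supervised target reproduces the
unsupervised result bit for bit — the two modes differ only in where
the target comes from.

## Parameters

- `gap_threshold` (default 0.10): columns whose gap fraction *exceeds*
  the threshold are excluded; a column at exactly 10% gaps is scored.
- Channels: all 18 by default; any subset selectable; user scales in
  the same two-column text format join the channel set on equal terms.
- Reference sequence (default: first row) defines the residue
  numbering used in reports; columns where the reference is gapped
  report no residue number.

## Degenerate cases

A fully conserved gap-free column has a constant similarity vector, so
its rank variance is zero and the correlation is undefined. Such scores
are reported as undefined (`NA`) and excluded from the ranking — never
coerced to 0, which would conflate "no signal" with "anti-correlated".
The same applies when the target matrix is constant. If no column
survives the gap filter the run fails with an explicit error rather
than returning an empty table.

## Numerical choices

- All accumulation is in double precision; scores live in [−1, 1].
- Channel similarity tables are rounded to 9 decimals before ranking.
  Scale values are published at ≤ 4 decimals, so distinct similarity
  values differ by far more than 1e-9, while mathematically tied
  differences (e.g. equal value gaps computed from different operands)
  can otherwise differ by ~1e-16 in floating point and would be ranked
  as distinct. Rounding restores those ties; it is also what makes
  scores exactly invariant under strictly increasing affine rescaling
  of a property scale (the invariance is checked to 1e-12 in the test
  suite). User scales with genuine structure below 1e-9 would be
  flattened; none of the bundled scales comes near that regime.
- Ranking ties in the report are broken by column (ascending), then by
  property label (ascending, empty label — the substitution channel —
  first), so output is deterministic.

## The synthetic generator

Real families with curated SDP ground truth are scarce, so testing is
anchored on generated alignments with planted structure. The default
specification: 3 subfamilies × 5 sequences, 50 columns, one SDP column
planted on the Kyte–Doolittle hydrophobicity scale, two fully conserved
columns, 5% gaps in neutral columns (a realistic alignment gap level),
and a weak subfamily bias over 30% of the neutral columns (preferred
residue taken with probability 0.6).

A planted SDP column gives each subfamily one fixed residue, the
residues chosen by greedy farthest-point selection along the planted
scale so the subfamilies are maximally separated on that property.
Because the unsupervised target is built from the sequences themselves,
subfamily identity must also leave a trace outside the planted column —
in real families phylogeny pervades the alignment. The biased columns
provide that trace, and they do so in a way that encodes *which*
subfamilies are functionally close, emulating divergent evolution where
the functional axis tracks the phylogeny:

- In each biased column, one pair of subfamilies may share a single
  preferred residue; the number of columns allotted to each pair is
  proportional (largest-remainder apportionment on the cubed
  planted-scale similarity of their SDP residues, capped at 60% of the
  biased columns per pair) so that scale-close subfamilies are
  sequence-close, deterministically.
- Preferred residues are drawn spread apart under the substitution
  matrix (squared-min-distance sampling), so unrelated subfamilies
  prefer chemically distinct residues and the block structure of the
  target stays crisp.
- Gaps and bias never touch planted or conserved columns, keeping the
  gap rules testable orthogonally to the planted signal.

Generation is exactly reproducible under a fixed seed. What the
generator does *not* emulate: indel evolution (gaps are i.i.d. noise,
not phylogenetic), within-subfamily rate variation, position-specific
residue composition, and correlated columns beyond the planted bias.
Recovery results on synthetic families therefore demonstrate that the
statistic detects the pattern it is designed for — not that it will
rank real-family SDPs with the same reliability, where alignment error
and phylogenetic confounding add noise this generator does not model.
Under the default conditions (200 generator seeds), the planted column
is the top-ranked record in ~95% of replicates and the planted property
scores at or above the median property within its column in ~100%.

## Bundled data

The 12 ProtScale scales and 5 Atchley factors are transcribed at the
precision published by their sources (provenance comments in each data
file); the exact flexibility and secondary-structure table variants
are named in the per-file headers, since property names alone are
ambiguous across the literature. The McLachlan (1972) substitution
matrix is transcribed as integers; its diagonal dominates every row.

## Known limitations

- Scores are raw correlations; no significance estimate or
  multiple-testing control is attached (with 18 channels × hundreds of
  columns, the top of the ranking should be read as a shortlist, not a
  hypothesis test).
- Columns are scored independently; covarying column pairs are not
  modelled.
- Nonstandard residues (B, J, O, U, X, Z) are demoted to gaps with a
  logged warning, which slightly inflates gap fractions in alignments
  rich in ambiguity codes.
- With small protein counts the pair vectors are short (n(n−1)/2
  entries) and tied ranks abundant, so scores are coarse; fewer than 3
  sequences are rejected outright.
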