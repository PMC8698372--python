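# sdpscan

Specificity-determining positions (SDPs) are the columns of a protein
family's multiple sequence alignment that are *differentially* conserved:
each functional subfamily fixes its own residue there, so the column
tracks what makes the subfamilies different rather than what they share.
Classical SDP detectors report where these positions are but say nothing
about *why* — which physicochemical property of the amino acids actually
varies with the functional split. `sdpscan` answers both questions at
once: it scores every alignment column for SDP behaviour and, for each
column, ranks the amino-acid properties (hydrophobicity, polarity,
secondary-structure propensity, size, charge, ...) that best explain the
subfamily-dependent pattern. It is aimed at protein-family analysts who
want mutable positions *and* a physicochemical hypothesis for the
specificity they control.

## Method

The subfamily structure of an alignment of proteins `1..N` is summarised
by a pairwise similarity matrix `M`, where `M_ij` is the mean per-column
McLachlan substitution-matrix similarity of proteins `i` and `j`
(columns where either protein is gapped contribute 0; the denominator is
the alignment length). In **supervised** mode, `M` is replaced by an
externally supplied matrix of pairwise functional similarities.

For an alignment column `k` and a property scale `p`, a position matrix
`S` holds the pairwise residue similarities at that column:

    S_ijkp = MAXdiff_p − |p(residue_ik) − p(residue_jk)|

with `MAXdiff_p` the largest value difference of scale `p` over all
residue pairs, and `S_ijkp = 0` for any pair involving a gap. For the
substitution-matrix channel, `S` is the McLachlan similarity of the two
residues instead. The SDP score of `(k, p)` is the Spearman rank
correlation over the unordered protein pairs `i < j`:

    rho_kp = corr(rank(S_kp), rank(M))        (mid-ranks for ties)

A high `rho_kp` means the residues at column `k`, viewed through
property `p`, partition the proteins the same way the family's overall
similarity (or the imposed functional classification) does. Columns with
more than 10% gaps are excluded; fully conserved columns have undefined
scores (no rank variance) and are excluded from the ranking. There are
18 channels: the substitution matrix (reported with an empty property
label) and 17 property scales (12 ProtScale scales + the 5 Atchley
factors), all bundled as plain-text tables. Users can add any scale in
the same two-column format.

## Worked example

Generate a synthetic family with a known planted SDP and score it:

```sh
sdpscan generate --seed 11 --out-prefix fam
sdpscan score --msa fam.fasta --top 8
```

The generator writes `fam.fasta` (3 subfamilies × 5 sequences, 50
columns) and a ground-truth sidecar `fam.truth.tsv` stating that column
25 is an SDP planted on the Kyte–Doolittle hydrophobicity scale
(`hdf_KD`) with subfamily residues R, I and G. The scorer prints:

```
Position	RefResidue	RefNumber	Property	Score
25	R	23	factor5	0.7344
25	R	23	hdf_KD	0.7344
25	R	23	pol_G	0.7344
25	R	23		0.7110
25	R	23	factor1	0.6337
25	R	23	hdf_Cho	0.6337
25	R	23	hdf_Eisenb	0.6337
25	R	23	betap	0.6248
```

The planted column tops the ranking, and the planted hydrophobicity
scale is among its best-scoring properties (R/I/G also separate
maximally on charge, `factor5`, and polarity, `pol_G`, so those tie —
chemically equivalent explanations of the same pattern). `RefNumber` is
the residue number in the reference (first) sequence, which here has two
gaps before column 25; an empty `Property` cell is the
substitution-matrix channel. A supervised run replaces the sequence-
similarity target with an external labelled matrix:
`sdpscan score --msa fam.fasta --mode supervised --funcsim func.tsv`.

Programmatic use mirrors the CLI:

```python
from sdpscan import read_alignment, load_builtin_scales, load_mclachlan, score_alignment

aln = read_alignment("fam.fasta")
table = score_alignment(aln, [load_mclachlan()] + load_builtin_scales(), top=10)
print(table.to_dataframe())
```

## Layout

- `src/sdpscan/scales.py` — property scales, substitution matrix, similarity transforms
- `src/sdpscan/alignment.py` — alignment reading/validation, columns, reference numbering
- `src/sdpscan/scoring.py` — similarity matrices and the Spearman SDP score
- `src/sdpscan/supervised.py` — external functional-similarity matrices
- `src/sdpscan/synthetic.py` — planted-signal alignment generator
- `src/sdpscan/cli.py` — `sdpscan score` / `sdpscan generate`
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
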