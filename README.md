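# polycub

Codon-usage-bias analysis of polyomavirus large T antigen (*LT-Ag*)
genes: a library and CLI for the complete descriptive toolkit used in
comparative viral codon-usage studies — nucleotide composition, RSCU,
ENC, CAI, parity-rule-2 bias, neutrality regression, correspondence
analysis, alignment diversity and neutrality tests, Nei–Gojobori dN/dS,
and LXCXE motif / functional-domain extraction — plus a synthetic-data
module so every statistic is testable offline against known parameters.

## Who this is for

Virologists and molecular evolution researchers comparing codon usage
of a gene family across host groups. The packaged reference tables
cover the 86 polyomavirus RefSeq genomes (host groups A avian, F fish,
H human, M non-primate mammal, P non-human primate; DnaJ and
superfamily-3 helicase domain coordinates of LT-Ag; LXCXE motif
positions), but every function operates on plain coding sequences and
alignments from any source.

## The statistics

For a coding sequence with codon counts $n_c$ and synonymous families
of degeneracy $d$:

- **RSCU**: $\mathrm{RSCU}_c = n_c \,/\, (N_{aa}/d)$ — observed count
  over its family-uniform expectation. Values within a family sum to
  $d$; RSCU ≥ 1.6 marks an over-represented codon, ≤ 0.6
  under-represented.
- **ENC** (effective number of codons, Wright): per amino acid with
  usage $n \ge 2$, the codon homozygosity is
  $F = (n\sum p_i^2 - 1)/(n-1)$; averaging $F$ within degeneracy
  classes gives $N_c = 2 + 9/\bar F_2 + 1/\bar F_3 + 5/\bar F_4 +
  3/\bar F_6 \in [20, 61]$. The null expectation at synonymous
  third-position GC content $s$ is $2 + s + 29/(s^2 + (1-s)^2)$.
- **CAI**: geometric mean of relative adaptiveness
  $w_c = n_c^{ref}/\max_{c'\in fam} n_{c'}^{ref}$ over all codons
  except ATG, TGG and stops; a bundled human reference table is the
  default.
- **PR2 bias**: $x = G_3/(G_3{+}C_3)$, $y = A_3/(A_3{+}T_3)$ at third
  positions of the eight fourfold-degenerate codon boxes; (0.5, 0.5)
  is the no-bias point.
- **Neutrality plot**: OLS of GC12 on GC3 across sequences; slope ≈
  share of directional mutation pressure, $1-$slope ≈ selection.
- **Correspondence analysis** of the sequences × 59-codon RSCU matrix,
  with per-axis inertia shares (total inertia equals the Pearson
  chi-square statistic over the grand total).
- **Diversity / neutrality**: segregating sites $S$, minimum mutations
  $\eta$, singletons, mean pairwise differences $k$, per-site
  diversity $\pi$, Tajima's $D$, Fu & Li's $D^*$ and $F^*$
  (no-outgroup form, corrected variance constants), all under
  complete deletion of gapped/ambiguous columns.
- **dN/dS**: Nei–Gojobori counting with all-minimal-pathway averaging
  (stop-avoiding) and Jukes–Cantor correction; group estimate is the
  ratio of averaged dN to averaged dS.

See `docs/methods.md` for conventions, parameter choices and
limitations.

## Worked example

Generate three synthetic coding sequences with a GC3s target of 0.34
(roughly the mammalian-polyomavirus range) and compute the core
per-sequence statistics:

```python
from polycub import (SyntheticSpec, generate_codon_sequences, codon_counts,
                     enc, expected_enc, composition_profile, cai)
from polycub.datasets import load_human_reference_usage

spec = SyntheticSpec(n_seqs=3, n_codons=500, seed=42, gc3_target=0.34)
ref = load_human_reference_usage()
print("id      GC3s    ENC     Nc_exp  CAI")
for s in generate_codon_sequences(spec):
    counts = codon_counts(s)
    p = composition_profile(s)
    print(f"{s.id}  {p.pct_GC3s:6.2f}  {enc(counts).enc:6.2f}  "
          f"{expected_enc(p.pct_GC3s/100):6.2f}  {cai(counts, ref).cai:.3f}")
```

prints

```
id      GC3s    ENC     Nc_exp  CAI
syn_0   32.24   57.53   53.82  0.690
syn_1   31.11   57.13   53.07  0.670
syn_2   35.28   60.11   55.73  0.705
```

GC3s lands near the requested 34% (sampling noise at 500 codons); the
measured ENC sits close to the no-selection expectation `Nc_exp` at
that GC3s, as it should for sequences generated with uniform
within-family preferences; and CAI against the human reference is in
the 0.67–0.71 band typical for unoptimised sequences.

The full pipeline (composition, ENC/CAI with group summaries, RSCU
group means and pairwise distances, PR2, neutrality fits,
correspondence analysis, population statistics, motif report) runs
from a YAML config:

```sh
polycub run --config config.yaml --out results/
```

or stage by stage (`polycub composition|rscu|enc|cai|pr2|neutrality|
coa|popgen|motif|simulate`), each reading FASTA and writing
fixed-schema TSV.

## Analysing the published reference set

The per-virus headline numbers require the 86 RefSeq GenBank records,
which are not redistributed here. A one-time
`python scripts/fetch_refseq.py` (network required) downloads them to
`data/refseq/`; the reference-data tests in
`tests/test_acceptance.py` then reproduce the published values.

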