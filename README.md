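# armscan

Comparative sequence analysis for protein families built around a conserved
catalytic core with variable — and often intrinsically disordered — N- and
C-terminal arms, the architecture typified by the sirtuin (SIRT1–7)
deacylase family.

Given a set of homologous proteins, a multiple sequence alignment, an
organism table, and optionally the in-frame coding sequences, `armscan`:

- **segments** every member into N-arm / catalytic core / C-arm by projecting
  a reference core interval through the alignment;
- **profiles** per-region amino-acid composition, charged-residue fraction
  (the charged set is exactly {Lys, Arg, Asp, Glu}), Cys fraction, and
  disorder — from external predictor tracks or a built-in windowed
  propensity proxy over the TOP-IDP scale;
- **detects charged stretches**: maximal runs of ≥ 3 same-sign charged
  residues, plus one-interior-gap forms of the CCXCC / CXCCCC family
  (admitted from span 5 in strict mode, from span 4 — e.g. DEGE — in
  lenient mode);
- **scans motifs** with PROSITE-like patterns: the leucine-rich nuclear
  export signal `L-x(2,3)-[LIVFM]-x(2,3)-L-x-[LI]`, the nuclear
  localisation signal `RKKRKD`, and the casein kinase II acceptor consensus
  `(S/T)-x-x-(D/E)`; computes phospho-site proximity to charged stretches;
  and finds tandem repeats;
- **measures GC content** of the coding sequences — overall, per region,
  and per codon position (GC1/GC2/GC3) — fits ordinary least-squares trend
  lines of GC% against phylogenetic rank per family and region (the slope
  is the *angular coefficient* used to compare evolutionary rates), and
  classifies isochore membership (L: GC-poor < 41%; H1: 41–46%;
  H: very GC-rich ≥ 46%) for gene-vs-chromosomal-band concordance;
- **builds phylogenies** per scope (full length, N-arm only, C-arm only):
  p-distance with pairwise deletion, classical neighbor joining, bootstrap
  supports by column resampling, and a family-class partition per scope to
  expose arms whose evolutionary grouping differs from the core's.

A ground-truth **synthetic family generator** emulates the whole study
design — conserved cores, disorder-biased arms, planted stretches / motifs /
repeats, coding sequences with configurable GC3 trends, and discordant
core-vs-arm class structures — so every stage is testable end to end
without any downloads.

## Worked example

Generate a small synthetic family set (seven families, five taxa each) and
run the full pipeline:

```python
from armscan import synthetic as syn
from armscan.pipeline import RunConfig, run_pipeline

bundle = syn.generate_family(syn.default_config(taxa_per_family=5), seed=42)
paths = {k: str(v) for k, v in bundle.write("demo/ds").items()}
report = run_pipeline(RunConfig(
    proteins=paths["proteins"], metadata=paths["metadata"],
    alignment=paths["alignment"], cds=paths["cds"],
    reference_id=bundle.reference_id, ref_core=bundle.ref_core,
    out_dir="demo/report", bootstrap=50, seed=7,
))
```

`demo/report/region_lengths.tsv` starts:

```
family  region  mean   sd       min  max  n
F1      C       240.4  12.7593  218  248  5
F1      N       172.4  16.9941  159  196  5
F1      core    240    0        240  240  5
```

Family F1's arms are the longest (mean N 172, C 240 residues) while the
core length is invariant — the family's hallmark.  The stretch summary
(`stretch_summary.tsv`) counts three negative stretches per F1 member in
both arms plus the positive ones, and `classes.tsv` shows the regrouping
phenomenon: the full-length partition groups families {F1,F2,F3} | {F4} |
{F5} | {F6,F7} (four classes), the N-arm partition splits F1/F2/F3 apart
and merges {F4,F5} (five classes), and the C-arm partition collapses to
{F1,F6,F7} | {F2,F3} (two classes; F4/F5 lack C arms):

```
scope  family  class   purity
full   F1      class1  1
...
N      F4      class4  1
N      F5      class4  1
...
C      F1      class1  1
C      F6      class1  1
C      F7      class1  1
```

The same stages are available from the shell: `armscan synth`, `armscan
segment`, `armscan stretches`, `armscan motifs`, `armscan repeats`,
`armscan gc`, `armscan trends`, `armscan isochore`, `armscan tree`,
`armscan run --config run.yaml`.

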