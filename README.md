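# cd5switch

**BCR-repertoire clonality analysis of CD5 state switching in chronic
lymphocytic leukemia (CLL).**

CLL patients carry, besides the dominant CD5^high^ leukemic B-cell bulk, a
small CD5^low^ B-cell population. Are those CD5^low^ cells part of the same
leukemic clone — and if so, do cells switch CD5 state continuously, or did
the CD5^low^ population arise from one rare switch event? `cd5switch`
implements the full analysis chain that answers this from B-cell receptor
(BCR) sequencing, for repertoire bioinformaticians and for anyone who wants
a tested, self-contained reference implementation of the statistics:

- **read processing** — paired-end amplicon filtering (median Phred > 32),
  identity merging (overlap > 65 bp), an immunoglobulin-similarity screen,
  primer trimming and length filtering (> 240 bp);
- **network assembly** — unique sequences as vertices, single-substitution
  (Hamming-1, non-indel) edges, connected components as clonal clusters;
  the dominant cluster is the CLL clone;
- **single-cell matching** — plate wells called clonal when identical to a
  bulk cluster member or within 3 substitutions of the dominant BCR;
- **switching statistics** — the two tests at the core of the method:
  1. *variant overlap*: with central BCR length *l*, a variant at Hamming
     distance *d* is one of C(l,d)·3^d possible mutants; the probability
     that the CD5^high^ and CD5^low^ gates share ≥ k_d variants by chance
     is an exact hypergeometric tail over that universe, pooled across
     distance classes (Fisher);
  2. *co-clustering*: the ratio of mean within-gate to mean between-gate
     pairwise nucleotide distance, with a label-permutation null
     (1000 replicates); ratio ≪ 1 means the gates are distinct lineages;
  plus least-squares regression of subclonal variant frequencies between
  gates;
- **lineage reconstruction** — a minimum-spanning-tree parsimony
  approximation rooted at the central BCR, tips colored by the gate(s)
  each sequence was seen in, exported as Newick;
- **a synthetic repertoire simulator** — clones with known ground truth
  under three switching regimes (A: rare high→low founder switch, B: the
  mirror, C: common bidirectional switching), sequencing errors, quality
  spikes, and single-cell plates, so the whole pipeline is testable
  end to end without any external data.

The inference logic: under **common switching (C)** the two gates share
variant sequences far beyond chance (overlap p ≪ 10⁻¹⁰) and do **not**
co-cluster (permutation p ≫ 0.05); under a **rare switch (A/B)** the gates
share nothing, the switched gate forms a tight sub-lineage (permutation
p < 0.05), and its tips sit in a single subtree of the lineage.

## Worked example

`examples/` contains one narrative script per capability. The switching
statistics under both regimes (`python examples/05_switching_statistics.py`):

```
scenario C: |high|=58 |low|=15 shared=14
  overlap pooled log10 p = -36.87
  within/between ratio   = 0.992  (permutation p = 0.4386)
scenario A: |high|=51 |low|=8 shared=0
  overlap pooled log10 p = 0.00
  within/between ratio   = 0.690  (permutation p = 0.0010)
subclonal frequency regression (deep scenario C): slope=1.015, R^2=0.9999 over 83 shared variants
```

Reading this: under common switching the gates share 14 variant sequences —
drawing that overlap from the ~900 possible single mutants (and vastly
larger higher-distance universes) by chance has probability 10⁻³⁶·⁸⁷, while
the distance ratio ≈ 1 says the gates are one mixed population. Under the
rare-switch scenario there is no overlap at all, but the CD5^low^ gate
clusters tightly (ratio 0.69, p = 0.001). Deep common-switching sampling
puts per-variant frequencies of the two gates on the identity line
(R² ≈ 1) — the same population structure seen from both gates.

The full pipeline as a shell command:

```bash
cd5switch run --seed 3 --outdir out/
# -> out/report.json, network.graphml, lineage.nwk, overlap_test.tsv, plates, ...
```

which prints the consolidated verdict (`common-switching consistent`) after
simulating, processing ~10,000 read pairs, recovering the clone as the
largest network cluster (≈ 98.7% of reads), matching single-cell plates
(clonal fractions ≈ 100%) and running both statistics. Subcommands
(`simulate`, `process`, `network`, `match`, `switchtest`, `tree`) expose
each stage separately; the same functionality is available as a library
(`import cd5switch`).

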