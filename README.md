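# cryopirna

Comparative piRNA profiling of fresh vs frozen-thawed sperm, end to end.

Sperm cryopreservation injures sperm to a degree that varies sharply across
species — boar sperm is highly cold-sensitive while giant panda sperm
survives repeated freeze–thaw cycles — and PIWI-interacting RNAs (piRNAs),
the 24–32 nt germline small RNAs with a 5′-uridine bias transcribed from
genomic clusters, are candidates for explaining part of that difference.
`cryopirna` implements the complete computational pipeline such a
comparison needs, for small RNA-seq with **one pooled library per
condition** (fresh and frozen-thawed) in each of two species:

1. **Read cleaning** — 3′ adapter trimming, then quality / poly-N /
   two-stage length filtering (clean reads 18–34 nt; piRNA-range reads
   24–32 nt).
2. **ncRNA filtering** — removal of reads matching rRNA/tRNA/snRNA/snoRNA/
   repeat references by exact substring on either strand.
3. **Genome mapping** — a k-mer seed-and-verify end-to-end mapper
   (substitutions only), all hits retained, multi-mappers weighted 1/hits.
4. **Cluster detection** — gap-merge of mapped 5′ ends with density,
   span, 5′-U and length-window thresholds.
5. **Quantification** — piRNA identity is its distinct sequence; TPM-style
   normalisation (each library sums to 10⁶).
6. **Differential expression without replicates** — median-of-ratios size
   factors, blind method-of-moments dispersion with a robust
   α(μ) = a₀ + a₁/μ trend, a two-sided exact negative-binomial test
   conditioning on each pair total, Benjamini–Hochberg adjustment, and the
   strict calls padj < 0.01 and |log₂FC| > 1.
7. **Cross-species homology** — two DE piRNAs are homologous when
   positions 1–18 match perfectly and at most one mismatch occurs from
   position 19 (5′-anchored, 3′ overhang ignored); DE sets are partitioned
   into common and species-unique piRNAs.
8. **Targets and enrichment** — antisense seed (positions 2–11) plus
   extension target prediction, then hypergeometric GO/KEGG
   over-representation of the target set with BH within each ontology.

A planted-truth simulator (`cryopirna.simdata`) generates toy genomes,
annotations and FASTQ libraries so that every stage is verifiable offline
against known truth — planted clusters, planted fold changes, planted
homolog pairs and planted enrichment signals.

## Worked example: the DE model

```python
import numpy as np
from cryopirna.simdata import simulate_de_counts
from cryopirna.diffexpr import PiRNADEModel

rng = np.random.default_rng(42)
counts, truth = simulate_de_counts(rng, 300, n_up=40, n_down=10, log2fc=3.0)
res = PiRNADEModel(counts).fit()
print(res.summary())
```

```
Exact negative-binomial differential expression (no replicates)
===============================================================
features tested:        300
libraries:              fresh (fresh) vs frozen (frozen-thawed)
size factors:           0.9895, 1.0106
dispersion trend:       alpha(mu) = 0.05176 + 0/mu (fit-only)
thresholds:             padj < 0.01, |log2FC| > 1.0
DE piRNAs:              50 (40 up, 10 down)
```

All 40 planted up-regulated and 10 planted down-regulated piRNAs are
recovered, and nothing else: with high counts and a log₂ fold change of 3
the exact test separates signal from a correctly calibrated null.  The
size factors are near 1 (the libraries are balanced), and the fitted
dispersion trend (≈ 0.05) slightly over-covers the simulated dispersion of
0.01 because the blind estimate absorbs part of the condition effect —
the conservative direction for a design without replicates.

## Worked example: the full pipeline

```bash
cryopirna all --outdir out --seed 1
```

simulates two species ("panda", "boar": 2 chromosomes × 60 kb, 5 planted
clusters × 40 piRNAs each, ~10% contamination) and runs every stage,
writing TSVs plus `out/report.json`.  With seed 1 the report shows, for
each species, all 5 planted clusters recovered containing all 200 planted
piRNA sequences (`"n_clusters": 5, "n_cluster_pirnas": 200`), mapped
ratios near 97% of clean reads, and DE piRNA counts (3 in panda, 22 in
boar at this seed) that illustrate the deliberately limited power of a
1-vs-1 exact test at moderate depth and dispersion 0.1 — only the most
extreme planted shifts reach padj < 0.01.  Individual stages can be rerun
(`cryopirna de -o out`), and a stage whose inputs are missing exits with
an error naming the stage to run first.

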