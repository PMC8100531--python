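# Methods note

This note documents the statistical models, algorithms, parameter defaults
and numerical choices implemented in `cryopirna`, together with what the
planted-truth simulator does and does not emulate, and the limitations the
user should keep in mind. Everything stated here is computed by the code in
this repository; no external empirical claims are made.

## 1. Read processing (`cryopirna.readproc`)

**Adapter trimming.** The 3′ adapter is removed by finding the longest
suffix of the read that equals a prefix of the adapter sequence, requiring
at least `min_overlap = 5` matching bases; shorter chance overlaps are left
untouched. Exact matching only — the simulator appends the adapter without
sequencing errors, and the trimmer is specified to match that model.

**Filtering order and definitions.** Reads are filtered in a fixed order so
that each read is charged to exactly one failure category and read counts
are conserved (`ReadStats.validate` enforces `n_raw = failures + n_clean`):

1. quality — mean Phred score < 20 fails;
2. poly-N — N fraction > 10% fails;
3. stage-1 length window 18–34 nt inclusive ("clean reads");
4. stage-2 length window 24–32 nt inclusive (the piRNA size range).

Two stages exist because the broader window defines library quality
statistics while the narrow window defines the piRNA candidate set; reads
of 18–23 or 33–34 nt are clean but not piRNA-range.

## 2. ncRNA filtering and genome mapping (`cryopirna.mapping`)

**ncRNA filter.** A read is removed if it occurs as an exact substring of
any reference ncRNA (rRNA/tRNA/snRNA/snoRNA/repeat) on either strand. The
references are concatenated with a `#` separator so a single substring
scan suffices; `#` cannot occur in a read, so no false joins are possible.

**Mapper.** `GenomeIndex` is an exact k-mer index (k = 12) used
seed-and-verify: for a maximum of `m` mismatches the read is split into
`m + 1` non-overlapping seeds (pigeonhole — at least one seed must be
exact), candidate alignments are verified end-to-end by Hamming distance,
and both strands are searched. Substitutions only, no indels, no
soft-clipping. Reads shorter than the seeds require (< (m+1)·k) fall back
to a full scan. All hits at or below the mismatch cap are reported; a
sequence hitting `n` loci contributes weight `1/n` to each locus.

**Mapped ratio.** `mapped_ratio = 100 · n_mapped / n_clean`, i.e. the
denominator is the clean-read count (stage-1 survivors), not the
post-ncRNA-filter count. This is the definition under which the package's
overview-table arithmetic is internally consistent.

## 3. Cluster detection (`cryopirna.clusters`)

Sorted mapped hits (by chromosome, then 5′ end — the biologically aligned
end, strand-aware) are merged while the gap between consecutive 5′ ends is
at most `max_gap = 1000` nt. A merged run is reported as a cluster when:

| parameter | default | rationale |
|---|---|---|
| `min_members` | 10 | distinct piRNA sequences; rejects isolated hits |
| `min_span` | 1,000 nt | clusters are kilobase-scale loci, not stacks |
| `max_gap` | 1,000 nt | proTRAC-style density requirement |
| `min_u1` | 0.30 | fraction of members with 5′ U (T on the genome) |
| `min_window_frac` | 0.75 | fraction of members 24–32 nt long |

Fractions are computed over **distinct member sequences**, not reads, so a
single hyper-abundant piRNA cannot satisfy the composition thresholds by
itself.

**Quantification.** A piRNA's identity is its distinct sequence. Per
library, raw counts are summed read counts; TPM here is
`10⁶ · count / Σ counts` with **no length normalisation** (all piRNAs fall
in an 8-nt window, so length normalisation would add noise without
information); each library's TPM column therefore sums to exactly 10⁶. A
`per_kilobase` switch restores the classical length-normalised definition
when wanted.

## 4. Differential expression (`cryopirna.diffexpr`)

The design has **one pooled library per condition** (n = 1 vs n = 1), so DE
is necessarily exploratory. The model is a DESeq-flavoured exact test:

1. **Size factors** — median-of-ratios: `sf_j = median_i(c_ij / g_i)` with
   `g_i` the geometric mean across libraries, over features nonzero in all
   libraries. The median is taken on the ratio scale.
2. **Dispersion** — estimated "blind": both libraries are pooled as one
   pseudo-group. Per feature, method-of-moments raw dispersion
   `α_raw = max((v − m)/m², 0)` from the normalised counts, then a
   parametric trend `α(μ) = a₀ + a₁/μ` fitted by Huber robust regression
   (statsmodels RLM), with `a₀ ≥ 10⁻⁸`, `a₁ ≥ 0`.
3. **Sharing mode.** Default `"fit-only"`: every feature uses the trend
   value at its mean. With no replicates the per-feature raw dispersion is
   fully confounded with the condition effect — a strongly differential
   feature inflates its own raw dispersion roughly by `(Δ/2)²/μ²` and,
   under a `max(raw, fitted)` rule, can never reach significance
   regardless of effect size. Fit-only sharing is therefore the default
   (it matches the standard no-replicate practice of blind estimation with
   fitted values only); `sharing_mode="maximum"` is available and is
   strictly more conservative (verified by test).
4. **Exact test.** For the rounded normalised pair `(a, b)` with
   `s = a + b`, both margins are modelled NB(mean `s/2`, dispersion from
   the trend), and the two-sided p-value is the total probability of all
   splits `(x, s − x)`, `x = 0…s`, whose joint probability does not exceed
   the observed split's, normalised by the total over all splits
   (conditioning on `s`). `s = 0` gives p = 1.
5. **Multiplicity and calls.** Benjamini–Hochberg adjustment, then the
   strict calls `padj < 0.01` **and** `|log₂FC| > 1` (both inequalities
   strict). `log₂FC = log₂((n_frozen + 1)/(n_fresh + 1))` with pseudocount
   1 on normalised counts; positive = higher after freeze–thaw.
6. **Heatmap order.** DE features are ordered by complete-linkage
   hierarchical clustering with Euclidean distance on `log₁₀(TPM + 1)`
   rows (scipy's deterministic leaf order); fewer than two rows yield the
   identity order.

### Numerical choices

- Normalised counts are **rounded to the nearest integer** before the
  exact test (the test is defined on integer splits).
- Probability ties in the exact test use a **log-space tolerance of
  1e-10** (`log P(x) ≤ log P(obs) + 1e-10`), so splits equal to the
  observed one up to floating-point noise are always included — erring
  toward larger (conservative) p-values.
- Joint probabilities are computed from `nbinom.logpmf` and exponentiated
  after subtracting the maximum, so totals up to at least several thousand
  are handled without underflow.
- Dispersions are clipped below at **1e-8** everywhere; μ is clipped at
  1e-12 before division in the trend.
- Degenerate inputs raise rather than guess: negative counts, count
  matrices without two columns, no all-nonzero feature for size factors,
  p-values outside [0, 1].

## 5. Cross-species homology (`cryopirna.homology`)

Two DE piRNA sequences (U normalised to T, ACGT only — anything else
raises) are **homologous** when, aligned at their 5′ ends:

- both are at least 19 nt (overlap ≥ 19);
- positions 1–18 are identical;
- at most **one** mismatch occurs from position 19 through the end of the
  shorter sequence; the longer sequence's 3′ overhang is ignored.

`partition(set_a, set_b)` indexes set B by 18-nt prefix (the fast path;
the test oracle is an independent all-pairs scan), picks for each A
sequence the best partner by `(mismatches, −overlap, lexicographic B
sequence)`, and then takes the **symmetric closure**: any B sequence
homologous to some matched A sequence also counts as common, so "common"
is membership-based and `unique = set − matched`. An optional strict
`one_to_one` mode consumes each B partner at most once (processed in
sorted-A order). The identity
`|unique_a| + |matched_a| = |set_a|` (and likewise for B) always holds.

## 6. Target prediction and enrichment (`cryopirna.enrich`)

**Targets.** A piRNA targets a transcript at a site where the reverse
complement of its seed (piRNA positions 2–11, 1-based) occurs exactly,
and the full-length antisense extension over the rest of the piRNA fits
within the transcript with at most `max_ext_mismatch = 2` mismatches
outside the seed region. All occurrences are enumerated.

**Enrichment.** For a target set of size `n` drawn from a universe of `N`
annotated transcripts, a term with `K` annotated members and `k` members
in the target set gets the hypergeometric over-representation p-value
`P(X ≥ k) = hypergeom.sf(k − 1, N, K, n)` (so `k = 0` gives p = 1). BH
adjustment is applied **within each ontology** (GO and KEGG separately).
Terms are ranked by `(padj ascending, k descending, term_id)` — the
term_id tie-break makes the ranking fully deterministic. Target
transcripts absent from the universe raise an error rather than being
silently dropped.

## 7. The simulator (`cryopirna.simdata`)

The simulator exists to give every pipeline stage a checkable ground
truth. It emulates:

- genomes with **planted piRNA clusters** (default 5 clusters × 40 piRNAs
  per species, spans 2 kb, separated by ≥ 4 kb) whose piRNA slots are
  placed disjointly inside each cluster, so the 5′-U overwrite applied to
  one piRNA (u1_bias = 0.8) cannot corrupt another;
- **homolog pairs**: selected species-A piRNAs are copied into species-B
  clusters either verbatim (30%) or with exactly one mismatch at a 0-based
  position ≥ 18, and the recorded homolog truth is re-verified at
  generation time by a brute-force application of the homology rule
  (`TruthConsistencyError` otherwise);
- **negative-binomial read counts** per piRNA per condition
  (`var = m + m²·disp`), with a configurable DE fraction and log₂ fold
  change;
- **library artefacts**: the 3′ adapter appended to every read, and ~10%
  contamination cycling through four classes — ncRNA fragments,
  low-quality reads (Phred 5–12), poly-N reads, and out-of-window lengths
  (15–40 nt, both too short and too long);
- **annotations**: transcripts with planted, non-overlapping antisense
  target sites, and GO/KEGG term maps.

It does **not** emulate sequencing substitution/indel error within reads,
PCR duplication, ligation bias, untrimmable adapter variants, isoform
structure, or genome-scale repeat content; the mapper and trimmer are
specified against this idealised read model.

`simulate_de_counts` defaults (dispersion 0.01, means 200–800 counts,
log₂FC 3) describe a deliberately **high-signal regime**: deep counts and
large effects where the exact no-replicate test has essentially full
power, so planted-recovery tests check correctness of the machinery, not
borderline power. The full-pipeline simulator uses a moderate regime
(means 20–200, dispersion 0.1) where only the most extreme planted shifts
are called — which is the honest behaviour of a 1-vs-1 design.

`make_partition_instance(n_a, n_b, n_common, …)` constructs two sequence
sets with exactly `n_common` cross-species homolog pairs by giving every
sequence a unique 18-nt prefix and mutating designated partners only after
position 18; the construction is verified internally by brute force.

## 8. Limitations

- **No replicates.** With one library per condition, biological
  variability between animals or ejaculates is unobservable; the blind
  dispersion estimate absorbs part of any true condition effect, p-values
  are approximate, and DE calls should be read as candidate lists, not
  confirmed effects. The strict thresholds (padj < 0.01, |log₂FC| > 1)
  partially compensate but cannot substitute for replication.
- The mapper's substitution-only, end-to-end model cannot place reads with
  indels or untrimmed adapter remnants.
- The homology rule is positional and 5′-anchored; it does not model
  shifted 5′ ends or post-transcriptional 3′ trimming beyond ignoring the
  overhang.
- Seed-plus-extension target prediction is sequence-only and enumerates
  candidate sites; it does not model accessibility or PIWI loading, and
  enrichment inherits all the usual caveats of hypergeometric
  over-representation with an uncertain universe.
- TPM without length normalisation is appropriate only because piRNA
  lengths span a narrow window; the `per_kilobase` switch exists for other
  uses.
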