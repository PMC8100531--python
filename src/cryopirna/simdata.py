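"""Planted-truth simulator for the two-species fresh/frozen piRNA study.

Generates, per species, a toy genome carrying non-overlapping piRNA
clusters (each a run of distinct 24–32 nt piRNAs with a 5′-U bias), ncRNA
loci disjoint from the clusters, a toy transcriptome with planted antisense
target sites, and GO/KEGG annotation maps.  Sequencing libraries — one per
condition, mirroring the pooled single-library design of the motivating
study — draw per-piRNA read counts from a negative binomial whose mean
shifts by a planted log2 fold change for the DE fraction, append the 3′
adapter to every read, and mix in a configurable fraction of contaminants
(ncRNA fragments, low-quality reads, poly-N reads, out-of-window lengths).

Everything is driven by one explicitly passed :class:`numpy.random.Generator`;
identical config + seed reproduces byte-identical output files.  The truth
set is verified at generation time: planted cross-species homolog pairs are
checked by brute force against the homology rule over all planted pairs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .homology import match_pair
from .readproc import SmallRNARead
from .seqio import revcomp

_BASES = np.array(list("ACGT"))

DEFAULT_LENGTH_DIST: dict[int, float] = {
    24: 0.08, 25: 0.06, 26: 0.06, 27: 0.08, 28: 0.12,
    29: 0.18, 30: 0.22, 31: 0.14, 32: 0.06,
}

NCRNA_TYPES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulation; defaults define the study conditions."""

    seed: int = 0
    species: tuple[str, str] = ("panda", "boar")
    n_chromosomes: int = 2
    chrom_length: int = 60_000
    n_clusters: int = 5
    cluster_span: int = 2_000
    pirnas_per_cluster: int = 40
    pirna_length_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST))
    u1_bias: float = 0.8
    n_ncrna_loci: int = 20
    reads_per_library: int | None = None
    nb_mean_range: tuple[float, float] = (20.0, 200.0)
    nb_dispersion: float = 0.1
    de_fraction: float = 0.15
    de_up_fraction: float = 0.5
    de_log2fc: float = 3.0
    adapter_seq: str = "AGATCGGAAGAGCACACGTCT"
    contam_fraction: float = 0.10
    n_homolog_pairs: int = 10
    n_transcripts: int = 60
    transcript_length: int = 500
    n_target_sites: int = 30
    n_go_terms: int = 12
    n_kegg_terms: int = 8
    min_cluster_sep: int = 4_000

    def validate(self) -> None:
        for name in ("u1_bias", "de_fraction", "de_up_fraction", "contam_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        total = sum(self.pirna_length_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pirna_length_dist sums to {total}, not 1")
        if any(not 1 <= k for k in self.pirna_length_dist):
            raise ValueError("pirna_length_dist keys must be positive lengths")
        if self.chrom_length <= self.n_clusters * self.cluster_span:
            raise ValueError("chrom_length must exceed n_clusters * cluster_span")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.nb_mean_range[0] <= 0 or self.nb_mean_range[1] < self.nb_mean_range[0]:
            raise ValueError("nb_mean_range must be an increasing positive pair")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PlantedPiRNA:
    """One planted piRNA with its genomic origin and expression truth."""

    seq: str
    chrom: str
    start: int
    fresh_mean: float = 0.0
    frozen_mean: float = 0.0
    is_de: bool = False
    direction: str = "none"  # up / down / none (frozen-thawed vs fresh)

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass
class TruthSet:
    """Everything planted into the simulated data, for verification."""

    planted_clusters: dict[str, list[tuple[str, int, int]]]
    planted_pirnas: dict[str, dict[str, PlantedPiRNA]]
    homolog_pairs: list[tuple[str, str]]
    ncrna_loci: dict[str, list[tuple[str, int, int, str]]]
    ncrna_seqs: dict[str, dict[str, str]] = field(default_factory=dict)
    transcripts: dict[str, dict[str, str]] = field(default_factory=dict)
    annotation_map: dict[str, pd.DataFrame] = field(default_factory=dict)
    target_sites: dict[str, list[tuple[str, str, int]]] = field(default_factory=dict)

    def de_counts(self, species: str) -> tuple[int, int]:
        """(n_up, n_down) planted DE piRNAs for one species."""
        ps = self.planted_pirnas[species].values()
        return (sum(p.direction == "up" for p in ps),
                sum(p.direction == "down" for p in ps))


class TruthConsistencyError(RuntimeError):
    """Raised when a generated genome violates its own planted truth."""


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _place_disjoint(rng: np.random.Generator, chrom_length: int, n: int,
                    span: int, min_sep: int) -> list[int]:
    """n disjoint interval starts of width `span`, separated by >= min_sep."""
    slack = chrom_length - n * (span + min_sep)
    if slack < 0:
        raise ValueError(
            f"cannot place {n} intervals of {span} nt with separation "
            f"{min_sep} on a {chrom_length} nt chromosome")
    gaps = np.sort(rng.integers(0, slack + 1, size=n))
    return [int(g + i * (span + min_sep)) for i, g in enumerate(gaps)]


def _sample_length(rng: np.random.Generator, dist: dict[int, float]) -> int:
    lengths = sorted(dist)
    probs = np.array([dist[l] for l in lengths], dtype=float)
    return int(rng.choice(lengths, p=probs / probs.sum()))


def generate_genome(config: SimulationConfig, rng: np.random.Generator,
                    ) -> tuple[dict[str, dict[str, str]], TruthSet]:
    """Generate both species' genomes with planted clusters, piRNAs, ncRNA
    loci, expression truth and cross-species homolog pairs.

    Returns ({species: {chrom: seq}}, truth).  Deterministic for a given
    (config, generator state); the planted homolog list is verified by
    brute force against the homology rule before returning.
    """
    config.validate()
    genomes: dict[str, dict[str, str]] = {}
    truth = TruthSet(planted_clusters={}, planted_pirnas={}, homolog_pairs=[],
                     ncrna_loci={})

    # choose species-A piRNAs to copy (mutated) into species B
    homolog_sources: list[str] = []

    for sp_idx, species in enumerate(config.species):
        chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
        chrom_arrays = {c: rng.choice(_BASES, size=config.chrom_length)
                        for c in chrom_names}

        # distribute clusters round-robin over chromosomes
        per_chrom: dict[str, int] = {c: 0 for c in chrom_names}
        for i in range(config.n_clusters):
            per_chrom[chrom_names[i % len(chrom_names)]] += 1
        clusters: list[tuple[str, int, int]] = []
        for chrom, n in per_chrom.items():
            if n == 0:
                continue
            for start in _place_disjoint(rng, config.chrom_length, n,
                                         config.cluster_span, config.min_cluster_sep):
                clusters.append((chrom, start, start + config.cluster_span))

        # plant piRNAs: pick positions/lengths, overwrite genome bases where
        # needed (5'-U bias; homolog copies), extract sequences afterwards
        slots: list[tuple[str, int, int, str | None]] = []  # chrom, start, length, forced seq
        homolog_targets: list[int] = []
        slot_idx = 0
        for chrom, cstart, cend in clusters:
            max_len = max(config.pirna_length_dist)
            # non-overlapping slots so the 5'-U overwrite of one piRNA can
            # never corrupt another planted sequence
            positions = _place_disjoint(rng, cend - cstart - max_len,
                                        config.pirnas_per_cluster, max_len, 1)
            for pos in (cstart + p for p in positions):
                forced = None
                if sp_idx == 1 and slot_idx < len(homolog_sources):
                    src = homolog_sources[slot_idx]
                    forced = _mutate_homolog(src, rng)
                    homolog_targets.append(slot_idx)
                    truth.homolog_pairs.append((src, forced))
                    length = len(forced)
                else:
                    length = _sample_length(rng, config.pirna_length_dist)
                slots.append((chrom, int(pos), length, forced))
                slot_idx += 1

        for chrom, pos, length, forced in slots:
            arr = chrom_arrays[chrom]
            if forced is not None:
                arr[pos:pos + length] = list(forced)
            elif rng.random() < config.u1_bias:
                arr[pos] = "T"
            elif arr[pos] == "T":
                arr[pos] = rng.choice(np.array(list("ACG")))

        genome = {c: "".join(a) for c, a in chrom_arrays.items()}
        pirnas: dict[str, PlantedPiRNA] = {}
        for chrom, pos, length, _ in slots:
            seq = genome[chrom][pos:pos + length]
            if seq in pirnas:
                raise TruthConsistencyError(
                    f"duplicate planted piRNA sequence in {species}")
            pirnas[seq] = PlantedPiRNA(seq, chrom, pos)

        # expression truth
        mean_lo, mean_hi = config.nb_mean_range
        scale = 1.0
        if config.reads_per_library is not None:
            expected = len(pirnas) * (mean_lo + mean_hi) / 2.0
            scale = config.reads_per_library * (1 - config.contam_fraction) / expected
        for p in pirnas.values():
            p.fresh_mean = float(rng.uniform(mean_lo, mean_hi)) * scale
            if rng.random() < config.de_fraction:
                p.is_de = True
                p.direction = "up" if rng.random() < config.de_up_fraction else "down"
                shift = 2.0 ** config.de_log2fc
                p.frozen_mean = p.fresh_mean * shift if p.direction == "up" \
                    else p.fresh_mean / shift
            else:
                p.frozen_mean = p.fresh_mean

        # ncRNA loci: disjoint from clusters and from each other
        loci: list[tuple[str, int, int, str]] = []
        ncrna_seqs: dict[str, str] = {}
        occupied = {c: [(s, e) for ch, s, e in clusters if ch == c] for c in chrom_names}
        attempts = 0
        while len(loci) < config.n_ncrna_loci and attempts < 10_000:
            attempts += 1
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            length = int(rng.integers(80, 300))
            start = int(rng.integers(0, config.chrom_length - length))
            if any(start < e and s < start + length for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, start + length))
            ntype = NCRNA_TYPES[len(loci) % len(NCRNA_TYPES)]
            name = f"{ntype}_{len(loci) + 1}"
            loci.append((chrom, start, start + length, name))
            ncrna_seqs[name] = genome[chrom][start:start + length]
        if len(loci) < config.n_ncrna_loci:
            raise TruthConsistencyError("could not place all ncRNA loci disjointly")

        genomes[species] = genome
        truth.planted_clusters[species] = clusters
        truth.planted_pirnas[species] = pirnas
        truth.ncrna_loci[species] = loci
        truth.ncrna_seqs[species] = ncrna_seqs

        if sp_idx == 0 and config.n_homolog_pairs > 0:
            seqs = [s for s in pirnas if len(s) >= 24]
            idx = rng.choice(len(seqs), size=min(config.n_homolog_pairs, len(seqs)),
                             replace=False)
            homolog_sources = [seqs[i] for i in idx]

    _verify_homolog_truth(truth, config.species)
    return genomes, truth


def _mutate_homolog(src: str, rng: np.random.Generator) -> str:
    """Copy of a piRNA with zero or one mismatch after position 18."""
    if rng.random() < 0.3:
        return src
    pos = int(rng.integers(18, len(src)))  # 0-based, i.e. 1-based >= 19
    alt = rng.choice(np.array([b for b in "ACGT" if b != src[pos]]))
    return src[:pos] + str(alt) + src[pos + 1:]


def _verify_homolog_truth(truth: TruthSet, species: tuple[str, str]) -> None:
    """Brute-force the homology rule over every planted cross-species pair
    and require exact agreement with the recorded homolog list."""
    sp_a, sp_b = species
    found = set()
    for a in truth.planted_pirnas[sp_a]:
        for b in truth.planted_pirnas[sp_b]:
            if match_pair(a, b) is not None:
                found.add((a, b))
    if found != set(truth.homolog_pairs):
        raise TruthConsistencyError(
            f"planted homolog pairs ({len(truth.homolog_pairs)}) disagree with "
            f"brute-force rule check ({len(found)})")


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """One negative-binomial count with var = mean + mean^2 * dispersion."""
    r = 1.0 / dispersion
    return int(rng.negative_binomial(r, r / (r + mean)))


def simulate_counts(rng: np.random.Generator, fresh_means: np.ndarray,
                    frozen_means: np.ndarray, dispersion: float) -> pd.DataFrame:
    """NB count matrix (features x [fresh, frozen]) for given true means."""
    r = 1.0 / dispersion
    fresh = rng.negative_binomial(r, r / (r + np.asarray(fresh_means, float)))
    frozen = rng.negative_binomial(r, r / (r + np.asarray(frozen_means, float)))
    return pd.DataFrame({"fresh": fresh, "frozen": frozen})


def simulate_de_counts(rng: np.random.Generator, n_features: int,
                       n_up: int, n_down: int, log2fc: float = 3.0,
                       mean_range: tuple[float, float] = (200.0, 800.0),
                       dispersion: float = 0.01,
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Count matrix with the first n_up features up- and the next n_down
    down-regulated in the frozen library; returns (counts, truth call)."""
    if n_up + n_down > n_features:
        raise ValueError("more DE features than features")
    base = rng.uniform(*mean_range, size=n_features)
    shift = 2.0 ** log2fc
    frozen = base.copy()
    frozen[:n_up] *= shift
    frozen[n_up:n_up + n_down] /= shift
    counts = simulate_counts(rng, base, frozen, dispersion)
    call = pd.Series(["up"] * n_up + ["down"] * n_down
                     + ["ns"] * (n_features - n_up - n_down), name="truth")
    return counts, call


def simulate_libraries(genomes: dict[str, dict[str, str]], truth: TruthSet,
                       config: SimulationConfig, rng: np.random.Generator,
                       ) -> dict[tuple[str, str], list[SmallRNARead]]:
    """Four read sets keyed (species, condition), condition in
    {fresh, frozen}.  Signal reads repeat each planted piRNA NB-many times;
    every read carries the 3′ adapter; contaminants are mixed in at
    ``contam_fraction`` of the library in four classes (ncRNA fragment,
    low quality, poly-N, out-of-window length).
    """
    if not truth.planted_pirnas:
        raise ValueError("truth must be generated from the same genomes first")
    libraries: dict[tuple[str, str], list[SmallRNARead]] = {}
    for species in config.species:
        genome = genomes[species]
        ncrna = list(truth.ncrna_seqs.get(species, {}).values())
        for condition in ("fresh", "frozen"):
            reads: list[SmallRNARead] = []
            serial = 0
            for p in truth.planted_pirnas[species].values():
                mean = p.fresh_mean if condition == "fresh" else p.frozen_mean
                for _ in range(_nb_draw(rng, mean, config.nb_dispersion)):
                    serial += 1
                    reads.append(_make_read(f"{species}_{condition}_{serial}",
                                            p.seq, config, rng))
            n_signal = len(reads)
            if config.contam_fraction > 0:
                n_contam = round(config.contam_fraction / (1 - config.contam_fraction)
                                 * n_signal)
                for i in range(n_contam):
                    serial += 1
                    reads.append(_make_contaminant(
                        f"{species}_{condition}_c{serial}", i % 4, genome,
                        ncrna, config, rng))
            libraries[(species, condition)] = reads
    return libraries


def _qual(rng: np.random.Generator, n: int, lo: int = 33, hi: int = 41) -> list[int]:
    return [int(q) for q in rng.integers(lo, hi, size=n)]


def _make_read(read_id: str, insert: str, config: SimulationConfig,
               rng: np.random.Generator) -> SmallRNARead:
    seq = insert + config.adapter_seq
    return SmallRNARead(read_id, seq, _qual(rng, len(seq)))


def _random_fragment(genome: dict[str, str], length: int,
                     rng: np.random.Generator) -> str:
    chrom = list(genome)[int(rng.integers(len(genome)))]
    start = int(rng.integers(0, len(genome[chrom]) - length))
    return genome[chrom][start:start + length]


_ODD_LENGTHS = (15, 16, 17, 20, 22, 33, 34, 36, 40)


def _make_contaminant(read_id: str, kind: int, genome: dict[str, str],
                      ncrna: list[str], config: SimulationConfig,
                      rng: np.random.Generator) -> SmallRNARead:
    if kind == 0 and ncrna:  # ncRNA fragment, in-window length, survives QC
        ref = ncrna[int(rng.integers(len(ncrna)))]
        length = int(rng.integers(24, 33))
        start = int(rng.integers(0, len(ref) - length))
        insert = ref[start:start + length]
        return _make_read(read_id, insert, config, rng)
    if kind == 1:            # low quality
        insert = _random_fragment(genome, int(rng.integers(24, 33)), rng)
        seq = insert + config.adapter_seq
        return SmallRNARead(read_id, seq, _qual(rng, len(seq), 5, 12))
    if kind == 2:            # poly-N
        length = int(rng.integers(24, 33))
        return _make_read(read_id, "N" * length, config, rng)
    # out-of-window length (fails stage 1 or stage 2)
    length = _ODD_LENGTHS[int(rng.integers(len(_ODD_LENGTHS)))]
    return _make_read(read_id, _random_fragment(genome, length, rng), config, rng)


def generate_annotations(genomes: dict[str, dict[str, str]], truth: TruthSet,
                         config: SimulationConfig, rng: np.random.Generator) -> TruthSet:
    """Toy transcriptomes with planted antisense piRNA target sites plus
    GO/KEGG annotation maps; fills the corresponding truth fields.

    Target sites: for up to ``n_target_sites`` planted DE piRNAs per
    species, the reverse complement of the piRNA is embedded in a random
    transcript, so target prediction has recoverable truth.
    """
    for species in config.species:
        transcripts = {f"{species}_tx{i + 1}": _random_seq(rng, config.transcript_length)
                       for i in range(config.n_transcripts)}
        tx_ids = list(transcripts)

        de_seqs = [s for s, p in truth.planted_pirnas[species].items() if p.is_de]
        sites: list[tuple[str, str, int]] = []
        used: dict[str, list[tuple[int, int]]] = {tid: [] for tid in tx_ids}
        for seq in de_seqs[:config.n_target_sites]:
            for _ in range(100):  # rejection-sample a site overlapping no other
                tid = tx_ids[int(rng.integers(len(tx_ids)))]
                t = transcripts[tid]
                pos = int(rng.integers(0, len(t) - len(seq)))
                if all(pos >= e or s >= pos + len(seq) for s, e in used[tid]):
                    break
            else:
                continue
            transcripts[tid] = t[:pos] + revcomp(seq) + t[pos + len(seq):]
            used[tid].append((pos, pos + len(seq)))
            sites.append((seq, tid, pos))

        rows = []
        go_terms = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
        kegg_terms = [f"ko{i + 1:05d}" for i in range(config.n_kegg_terms)]
        for tid in tx_ids:
            for term in rng.choice(go_terms, size=int(rng.integers(1, 4)), replace=False):
                rows.append((tid, str(term), "GO"))
            n_kegg = int(rng.integers(0, 3))
            if n_kegg:
                for term in rng.choice(kegg_terms, size=n_kegg, replace=False):
                    rows.append((tid, str(term), "KEGG"))
        truth.transcripts[species] = transcripts
        truth.annotation_map[species] = pd.DataFrame(
            rows, columns=["transcript_id", "term_id", "ontology"])
        truth.target_sites[species] = sites
    return truth


def make_partition_instance(n_a: int, n_b: int, n_common: int,
                            rng: np.random.Generator,
                            length_range: tuple[int, int] = (26, 32),
                            ) -> tuple[list[str], list[str], list[tuple[str, str]]]:
    """Two DE piRNA sets with exactly ``n_common`` cross-set homolog pairs.

    Every sequence gets a unique 18-nt 5′ prefix except the planted
    partners, which copy their counterpart's prefix (and differ by at most
    one base from position 19), so the homology rule is satisfied by the
    planted pairs and — verified by brute force here — by no other pair.
    """
    if n_common > min(n_a, n_b):
        raise ValueError("n_common cannot exceed either set size")
    lo, hi = length_range
    if lo < 19:
        raise ValueError("sequences must be at least 19 nt")

    prefixes: set[str] = set()
    while len(prefixes) < n_a + (n_b - n_common):
        prefixes.add(_random_seq(rng, 18))
    prefix_list = sorted(prefixes)
    rng.shuffle(prefix_list)

    set_a = [prefix_list[i] + _random_seq(rng, int(rng.integers(lo - 18, hi - 17)))
             for i in range(n_a)]
    pairs = [(a, _mutate_homolog(a, rng)) for a in set_a[:n_common]]
    set_b = [b for _, b in pairs]
    set_b += [prefix_list[n_a + i] + _random_seq(rng, int(rng.integers(lo - 18, hi - 17)))
              for i in range(n_b - n_common)]

    found = {(a, b) for a in set_a for b in set_b if match_pair(a, b) is not None}
    if found != set(pairs):
        raise TruthConsistencyError("constructed instance violates its planted pairing")
    return set_a, set_b, pairs


def ncrna_bed(truth: TruthSet, species: str) -> str:
    """BED6 text of the species' ncRNA loci (0-based half-open)."""
    lines = [f"{chrom}\t{start}\t{end}\t{name}\t0\t+"
             for chrom, start, end, name in truth.ncrna_loci[species]]
    return "\n".join(lines) + ("\n" if lines else "")


def clusters_bed(truth: TruthSet, species: str) -> str:
    """BED6 text of the species' planted cluster intervals."""
    lines = [f"{chrom}\t{start}\t{end}\tplanted_{i + 1}\t0\t+"
             for i, (chrom, start, end) in enumerate(truth.planted_clusters[species])]
    return "\n".join(lines) + ("\n" if lines else "")
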