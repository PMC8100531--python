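"""File-based orchestration of the full pipeline.

Each stage reads the TSV/FASTQ/FASTA outputs of its upstream stages from
one output directory and writes its own; rerunning a stage with the same
inputs reproduces byte-identical outputs.  A stage whose inputs are missing
raises :class:`MissingStageError` naming the stage that must run first.
Every number in the final JSON report is recomputable from the stage files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clusters as clu
from . import diffexpr, enrich, homology, mapping, readproc, simdata
from .readproc import SmallRNARead
from .seqio import read_fasta, read_fastq, write_fasta, write_fastq

CONDITIONS = ("fresh", "frozen")


@dataclass
class PipelineConfig:
    """All stage parameters plus the simulation config and the seed."""

    seed: int = 0
    sim: simdata.SimulationConfig = field(default_factory=simdata.SimulationConfig)
    # read cleaning
    stage1_window: tuple[int, int] = (18, 34)
    stage2_window: tuple[int, int] = (24, 32)
    max_n_frac: float = 0.10
    min_mean_quality: float = 20.0
    min_adapter_overlap: int = 5
    # mapping
    seed_k: int = 12
    max_mismatch: int = 0
    # clustering
    cluster: clu.ClusterParams = field(default_factory=clu.ClusterParams)
    # quantification / DE
    per_kilobase: bool = False
    padj_cut: float = 0.01
    lfc_cut: float = 1.0
    sharing_mode: str = "fit-only"
    # homology / targets / enrichment
    one_to_one: bool = False
    target: enrich.TargetParams = field(default_factory=enrich.TargetParams)
    top_n: int = 10

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["pirna_length_dist"] = {int(k): float(v) for k, v
                                         in d["sim"]["pirna_length_dist"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim_d = dict(d.pop("sim", {}))
        for key in ("species", "nb_mean_range"):
            if key in sim_d:
                sim_d[key] = tuple(sim_d[key])
        if "pirna_length_dist" in sim_d:
            sim_d["pirna_length_dist"] = {int(k): float(v) for k, v
                                          in sim_d["pirna_length_dist"].items()}
        cluster_d = dict(d.pop("cluster", {}))
        if "length_window" in cluster_d:
            cluster_d["length_window"] = tuple(cluster_d["length_window"])
        target_d = dict(d.pop("target", {}))
        for key in ("stage1_window", "stage2_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(sim=simdata.SimulationConfig(**sim_d),
                   cluster=clu.ClusterParams(**cluster_d),
                   target=enrich.TargetParams(**target_d), **d)

    def save(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class MissingStageError(FileNotFoundError):
    """An upstream stage has not produced its outputs yet."""

    def __init__(self, missing: Path, producer: str):
        super().__init__(f"missing {missing.name}: run stage '{producer}' first")
        self.producer = producer


def _require(outdir: Path, name: str, producer: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise MissingStageError(path, producer)
    return path


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _read_reads(path: Path) -> list[SmallRNARead]:
    return [SmallRNARead(rid, seq, qual) for rid, seq, qual in read_fastq(path)]


# --------------------------------------------------------------------------
# stages

def stage_simulate(outdir: Path, cfg: PipelineConfig) -> None:
    rng = np.random.default_rng(cfg.seed)
    genomes, truth = simdata.generate_genome(cfg.sim, rng)
    simdata.generate_annotations(genomes, truth, cfg.sim, rng)
    libraries = simdata.simulate_libraries(genomes, truth, cfg.sim, rng)

    outdir.mkdir(parents=True, exist_ok=True)
    cfg.save(outdir / "config.yaml")
    for sp in cfg.sim.species:
        write_fasta(outdir / f"genome_{sp}.fa", genomes[sp])
        write_fasta(outdir / f"ncrna_{sp}.fa", truth.ncrna_seqs[sp])
        write_fasta(outdir / f"transcripts_{sp}.fa", truth.transcripts[sp])
        (outdir / f"ncrna_{sp}.bed").write_text(simdata.ncrna_bed(truth, sp))
        (outdir / f"truth_clusters_{sp}.bed").write_text(simdata.clusters_bed(truth, sp))
        _write_tsv(truth.annotation_map[sp], outdir / f"annotation_{sp}.tsv")
        rows = [(p.seq, p.chrom, p.start, p.end, p.fresh_mean, p.frozen_mean,
                 p.is_de, p.direction)
                for p in truth.planted_pirnas[sp].values()]
        _write_tsv(pd.DataFrame(rows, columns=[
            "seq", "chrom", "start", "end", "fresh_mean", "frozen_mean",
            "is_de", "direction"]), outdir / f"truth_pirnas_{sp}.tsv")
        for cond in CONDITIONS:
            write_fastq(outdir / f"reads_{sp}_{cond}.fastq",
                        ((r.read_id, r.seq, r.qual) for r in libraries[(sp, cond)]))
    _write_tsv(pd.DataFrame(truth.homolog_pairs, columns=["seq_a", "seq_b"]),
               outdir / "truth_homologs.tsv")


def stage_qc(outdir: Path, cfg: PipelineConfig) -> None:
    rows = []
    for sp in cfg.sim.species:
        for cond in CONDITIONS:
            raw = _read_reads(_require(outdir, f"reads_{sp}_{cond}.fastq", "simulate"))
            clean, stats = readproc.process_reads(
                raw, cfg.sim.adapter_seq, cfg.min_adapter_overlap,
                stage1_window=cfg.stage1_window, stage2_window=cfg.stage2_window,
                max_n_frac=cfg.max_n_frac, min_mean_quality=cfg.min_mean_quality)
            write_fastq(outdir / f"clean_{sp}_{cond}.fastq",
                        ((r.read_id, r.seq, r.qual) for r in clean))
            rows.append([sp, cond] + [getattr(stats, c) for c in readproc.STATS_COLUMNS])
    _write_tsv(pd.DataFrame(rows, columns=["species", "condition",
                                           *readproc.STATS_COLUMNS]),
               outdir / "read_stats.tsv")


def stage_filter_ncrna(outdir: Path, cfg: PipelineConfig) -> None:
    rows = []
    for sp in cfg.sim.species:
        ncrna = read_fasta(_require(outdir, f"ncrna_{sp}.fa", "simulate"))
        for cond in CONDITIONS:
            clean = _read_reads(_require(outdir, f"clean_{sp}_{cond}.fastq", "qc"))
            kept, removed = mapping.filter_ncrna(clean, ncrna.values())
            write_fastq(outdir / f"filtered_{sp}_{cond}.fastq",
                        ((r.read_id, r.seq, r.qual) for r in kept))
            rows.append((sp, cond, len(clean), removed, len(kept)))
    _write_tsv(pd.DataFrame(rows, columns=["species", "condition", "n_clean",
                                           "n_ncrna_removed", "n_kept"]),
               outdir / "ncrna_counts.tsv")


def stage_map(outdir: Path, cfg: PipelineConfig) -> None:
    ncrna_counts = pd.read_csv(_require(outdir, "ncrna_counts.tsv", "filter-ncrna"),
                               sep="\t")
    stat_rows = []
    for sp in cfg.sim.species:
        genome = read_fasta(_require(outdir, f"genome_{sp}.fa", "simulate"))
        index = mapping.GenomeIndex(genome, k=cfg.seed_k)
        for cond in CONDITIONS:
            reads = _read_reads(_require(outdir, f"filtered_{sp}_{cond}.fastq",
                                         "filter-ncrna"))
            hits = mapping.map_reads(reads, index, cfg.max_mismatch)
            rows = []
            for read in reads:
                hlist = hits[read.read_id]
                w = 1.0 / len(hlist) if hlist else 0.0
                for h in hlist:
                    rows.append((read.read_id, read.seq, h.chrom, h.start,
                                 h.end, h.strand, h.mismatches, w))
            df = pd.DataFrame(rows, columns=["read_id", "seq", "chrom", "start",
                                             "end", "strand", "mismatches", "weight"])
            df = df.sort_values(["chrom", "start", "read_id"], kind="mergesort")
            _write_tsv(df, outdir / f"hits_{sp}_{cond}.tsv")

            row = ncrna_counts.query("species == @sp and condition == @cond").iloc[0]
            stats = mapping.MappingStats(
                n_input=int(row["n_clean"]),
                n_ncrna_removed=int(row["n_ncrna_removed"]),
                n_mapped=sum(1 for r in reads if hits[r.read_id]),
                n_unmapped=sum(1 for r in reads if not hits[r.read_id]))
            stat_rows.append((sp, cond, stats.n_input, stats.n_ncrna_removed,
                              stats.n_mapped, stats.n_unmapped,
                              round(stats.mapped_ratio, 2)))
    _write_tsv(pd.DataFrame(stat_rows, columns=[
        "species", "condition", "n_clean", "n_ncrna_removed", "n_mapped",
        "n_unmapped", "mapped_ratio"]), outdir / "mapping_stats.tsv")


def _load_weighted_hits(outdir: Path, sp: str) -> list[clu.WeightedHit]:
    frames = []
    for cond in CONDITIONS:
        frames.append(pd.read_csv(_require(outdir, f"hits_{sp}_{cond}.tsv", "map"),
                                  sep="\t"))
    df = pd.concat(frames).sort_values(["chrom", "start"], kind="mergesort")
    return [(mapping.GenomeHit(r.chrom, int(r.start), int(r.end), r.strand,
                               int(r.mismatches)), r.seq, float(r.weight))
            for r in df.itertuples()]


def stage_clusters(outdir: Path, cfg: PipelineConfig) -> None:
    for sp in cfg.sim.species:
        found = clu.detect_clusters(_load_weighted_hits(outdir, sp), cfg.cluster)
        (outdir / f"clusters_{sp}.bed").write_text(
            "".join(c.to_bed() + "\n" for c in found))
        rows = [(c.chrom, c.start, c.end, c.n_member_sequences, c.n_reads,
                 c.u1_fraction, c.length_window_fraction) for c in found]
        _write_tsv(pd.DataFrame(rows, columns=[
            "chrom", "start", "end", "n_member_sequences", "n_reads",
            "u1_fraction", "length_window_fraction"]),
            outdir / f"clusters_{sp}.tsv")


def stage_quantify(outdir: Path, cfg: PipelineConfig) -> None:
    for sp in cfg.sim.species:
        libs = {}
        for cond in CONDITIONS:
            reads = _read_reads(_require(outdir, f"filtered_{sp}_{cond}.fastq",
                                         "filter-ncrna"))
            libs[cond] = [r.seq for r in reads]
        expr = clu.quantify(libs, per_kilobase=cfg.per_kilobase)
        _write_tsv(expr.reset_index(), outdir / f"expression_{sp}.tsv")


def stage_de(outdir: Path, cfg: PipelineConfig) -> None:
    for sp in cfg.sim.species:
        expr = pd.read_csv(_require(outdir, f"expression_{sp}.tsv", "quantify"),
                           sep="\t").set_index("pirna_seq")
        counts = expr[["raw_fresh", "raw_frozen"]].rename(
            columns={"raw_fresh": "fresh", "raw_frozen": "frozen"})
        res = diffexpr.PiRNADEModel(counts, "fresh", "frozen").fit(
            sharing_mode=cfg.sharing_mode, padj_cut=cfg.padj_cut, lfc_cut=cfg.lfc_cut)
        _write_tsv(res.table.reset_index(), outdir / f"de_{sp}.tsv")
        volcano = res.table[["log2fc", "padj", "call"]].reset_index()
        _write_tsv(volcano, outdir / f"volcano_{sp}.tsv")

        tpm = expr[["tpm_fresh", "tpm_frozen"]]
        order, transformed = res.heatmap(tpm)
        _write_tsv(transformed.iloc[order].reset_index(), outdir / f"heatmap_{sp}.tsv")


def stage_homology(outdir: Path, cfg: PipelineConfig) -> None:
    sp_a, sp_b = cfg.sim.species
    de_sets = {}
    for sp in (sp_a, sp_b):
        de = pd.read_csv(_require(outdir, f"de_{sp}.tsv", "de"), sep="\t")
        de_sets[sp] = sorted(de.loc[de["call"] != "ns", "pirna_seq"])
    result = homology.partition(de_sets[sp_a], de_sets[sp_b],
                                one_to_one=cfg.one_to_one)
    _write_tsv(pd.DataFrame(
        [(p.seq_a, p.seq_b, p.overlap_len,
          ",".join(map(str, p.mismatch_positions))) for p in result.common_pairs],
        columns=["seq_a", "seq_b", "overlap_len", "mismatch_positions"]),
        outdir / "homology_pairs.tsv")
    for sp, uniq in ((sp_a, result.unique_a), (sp_b, result.unique_b)):
        (outdir / f"unique_{sp}.txt").write_text(
            "".join(s + "\n" for s in sorted(uniq)))
    counts = {
        f"n_de_{sp_a}": len(de_sets[sp_a]), f"n_de_{sp_b}": len(de_sets[sp_b]),
        f"n_common_{sp_a}": result.n_common_a, f"n_common_{sp_b}": result.n_common_b,
        f"n_unique_{sp_a}": len(result.unique_a),
        f"n_unique_{sp_b}": len(result.unique_b),
    }
    (outdir / "homology_counts.json").write_text(
        json.dumps(counts, indent=2, sort_keys=True) + "\n")


def stage_targets(outdir: Path, cfg: PipelineConfig) -> None:
    for sp in cfg.sim.species:
        de = pd.read_csv(_require(outdir, f"de_{sp}.tsv", "de"), sep="\t")
        de_seqs = sorted(de.loc[de["call"] != "ns", "pirna_seq"])
        transcripts = read_fasta(_require(outdir, f"transcripts_{sp}.fa", "simulate"))
        hits = enrich.predict_targets(de_seqs, transcripts, cfg.target)
        _write_tsv(pd.DataFrame(
            [(h.pirna_seq, h.transcript_id, h.position, h.ext_mismatches)
             for h in hits],
            columns=["pirna_seq", "transcript_id", "position", "ext_mismatches"]),
            outdir / f"targets_{sp}.tsv")


def stage_enrich(outdir: Path, cfg: PipelineConfig) -> None:
    for sp in cfg.sim.species:
        targets = pd.read_csv(_require(outdir, f"targets_{sp}.tsv", "targets"),
                              sep="\t")
        ann = pd.read_csv(_require(outdir, f"annotation_{sp}.tsv", "simulate"),
                          sep="\t")
        universe = set(ann["transcript_id"])
        tset = set(targets["transcript_id"]) & universe if len(targets) else set()
        results = enrich.hypergeom_enrich(tset, ann)
        _write_tsv(enrich.enrichment_table(results), outdir / f"enrichment_{sp}.tsv")
        top = enrich.rank_terms(results, cfg.top_n)
        (outdir / f"top_terms_{sp}.json").write_text(json.dumps(
            [{"term_id": r.term_id, "ontology": r.ontology, "k": r.k,
              "padj": r.padj} for r in top], indent=2) + "\n")


def stage_report(outdir: Path, cfg: PipelineConfig) -> None:
    sp_a, sp_b = cfg.sim.species
    read_stats = pd.read_csv(_require(outdir, "read_stats.tsv", "qc"), sep="\t")
    map_stats = pd.read_csv(_require(outdir, "mapping_stats.tsv", "map"), sep="\t")
    homology_counts = json.loads(
        _require(outdir, "homology_counts.json", "homology").read_text())

    report: dict = {"species": list(cfg.sim.species), "libraries": {}}
    for sp in (sp_a, sp_b):
        for cond in CONDITIONS:
            rrow = read_stats.query("species == @sp and condition == @cond").iloc[0]
            mrow = map_stats.query("species == @sp and condition == @cond").iloc[0]
            report["libraries"][f"{sp}_{cond}"] = {
                "n_raw": int(rrow["n_raw"]),
                "n_clean": int(rrow["n_clean"]),
                "n_mapped": int(mrow["n_mapped"]),
                "mapped_ratio": float(mrow["mapped_ratio"]),
            }
    report["clusters"] = {}
    report["de"] = {}
    report["targets"] = {}
    report["top_terms"] = {}
    for sp in (sp_a, sp_b):
        cl = pd.read_csv(_require(outdir, f"clusters_{sp}.tsv", "clusters"), sep="\t")
        de = pd.read_csv(_require(outdir, f"de_{sp}.tsv", "de"), sep="\t")
        tg = pd.read_csv(_require(outdir, f"targets_{sp}.tsv", "targets"), sep="\t")
        report["clusters"][sp] = {
            "n_clusters": int(len(cl)),
            "n_cluster_pirnas": int(cl["n_member_sequences"].sum()) if len(cl) else 0,
        }
        report["de"][sp] = {
            "n_up": int((de["call"] == "up").sum()),
            "n_down": int((de["call"] == "down").sum()),
            "n_de": int((de["call"] != "ns").sum()),
            "n_expressed": int(len(de)),
        }
        report["targets"][sp] = {
            "n_target_transcripts": int(tg["transcript_id"].nunique()) if len(tg) else 0}
        report["top_terms"][sp] = json.loads(
            _require(outdir, f"top_terms_{sp}.json", "enrich").read_text())
    report["homology"] = homology_counts
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")


def validate_report(report: dict) -> None:
    """Schema check of a pipeline report (raises ValueError on violation)."""
    required = {"species": list, "libraries": dict, "clusters": dict, "de": dict,
                "targets": dict, "top_terms": dict, "homology": dict}
    for key, typ in required.items():
        if not isinstance(report.get(key), typ):
            raise ValueError(f"report key {key!r} missing or not {typ.__name__}")
    for lib, entry in report["libraries"].items():
        for f in ("n_raw", "n_clean", "n_mapped", "mapped_ratio"):
            if not isinstance(entry.get(f), (int, float)):
                raise ValueError(f"library {lib} missing numeric field {f!r}")
    for sp in report["species"]:
        for section, fields in (("clusters", ("n_clusters",)),
                                ("de", ("n_up", "n_down", "n_de")),
                                ("targets", ("n_target_transcripts",))):
            entry = report[section].get(sp, {})
            for f in fields:
                if not isinstance(entry.get(f), int):
                    raise ValueError(f"{section}[{sp}] missing int field {f!r}")


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "filter-ncrna": stage_filter_ncrna,
    "map": stage_map,
    "clusters": stage_clusters,
    "quantify": stage_quantify,
    "de": stage_de,
    "homology": stage_homology,
    "targets": stage_targets,
    "enrich": stage_enrich,
    "report": stage_report,
}

STAGE_ORDER = list(STAGES)


def run_stage(name: str, outdir: Path, cfg: PipelineConfig) -> None:
    """Run one named stage; raises MissingStageError when inputs are absent."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGE_ORDER}")
    STAGES[name](Path(outdir), cfg)


def run_all(outdir: Path, cfg: PipelineConfig) -> None:
    for name in STAGE_ORDER:
        run_stage(name, outdir, cfg)
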