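"""Pipeline orchestration: simulate -> detect -> classify -> cluster -> date
-> tree -> depth -> report, with one global seed fanned out per stage and a
manifest of every file written."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import abundance, chronology, detect, ioutils, phylo, synth, taxonomy
from ._rng import stage_seed

STAGES = ("simulate", "detect", "classify", "cluster", "date", "tree", "depth")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "run"
    reference_genome_label: str = "SYN"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    families: list = field(default_factory=list)  # list of FamilySpec kwargs
    background_length: int = 120_000
    mutation_rate: float = 1.3e-8
    coverage: float = 3.0
    read_length: int = 100
    read_error_rate: float = 0.0
    detector: dict = field(default_factory=dict)  # DetectorConfig overrides
    clustering: dict = field(default_factory=dict)
    clock: dict = field(default_factory=dict)
    dedupe_identity: float = 0.95
    library_min_length: int = 150
    top_n: int = 20

    _KNOWN = None  # filled below

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config = cls(**data)
        bad_stages = set(config.stages) - set(STAGES)
        if bad_stages:
            raise ValueError(f"unknown stages: {sorted(bad_stages)}")
        return config

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            return cls.from_dict(json.load(handle))

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2, sort_keys=True)

    def family_specs(self) -> list[synth.FamilySpec]:
        specs = []
        for kwargs in self.families:
            kwargs = dict(kwargs)
            if isinstance(kwargs.get("domain_order"), list):
                kwargs["domain_order"] = tuple(kwargs["domain_order"])
            if isinstance(kwargs.get("age_distribution"), list):
                kwargs["age_distribution"] = tuple(kwargs["age_distribution"])
            specs.append(synth.FamilySpec(**kwargs))
        return specs


def demo_config(outdir: str = "run", seed: int = 0) -> PipelineConfig:
    """A small bundled configuration exercising every stage in seconds."""
    return PipelineConfig(
        seed=seed,
        outdir=outdir,
        families=[
            dict(family_id="famA", superfamily="copia", ltr_length=400,
                 internal_length=2200, domain_order=list(synth.COPIA_ORDER),
                 copy_number=6, age_distribution=["uniform", 0.0, 1.5e6]),
            dict(family_id="famB", superfamily="gypsy", ltr_length=350,
                 internal_length=2200, domain_order=list(synth.GYPSY_ORDER),
                 copy_number=4, age_distribution=["uniform", 0.0, 1.0e6]),
            dict(family_id="famC", superfamily="unclassified", ltr_length=300,
                 internal_length=900, domain_order=[],
                 copy_number=3, age_distribution=5.0e5),
        ],
        background_length=100_000,
        coverage=3.0,
    )


@dataclass
class RunReport:
    counts: dict
    family_table: list
    parameters: dict

    def to_json(self) -> str:
        return json.dumps(
            {"counts": self.counts, "family_table": self.family_table,
             "parameters": self.parameters},
            indent=2,
            sort_keys=True,
        )


def make_family_table(
    families: Sequence[taxonomy.Family],
    age_summaries: Mapping[str, Mapping[str, float]],
    family_depth: Mapping[str, float],
    top_n: int,
) -> list[dict]:
    """Ranked per-family table (descending intact count with the taxonomy
    tie rules already applied by name_and_rank_families)."""
    if top_n <= 0:
        raise ValueError("top_n must be > 0")
    rows = []
    for rank, family in enumerate(families[:top_n], 1):
        ages = age_summaries.get(family.family_id, {})
        rows.append(
            {
                "rank": rank,
                "family_id": family.family_id,
                "superfamily": family.superfamily,
                "n_intact": family.n_intact,
                "copy_class": family.copy_class,
                "mean_age": round(ages.get("mean", float("nan")), 1)
                if ages else "",
                "normalized_depth": round(family_depth.get(family.family_id, 0.0), 4)
                if family_depth else "",
            }
        )
    return rows


def _elements_to_rows(elements: list[detect.IntactElement]) -> list[dict]:
    rows = []
    for el in elements:
        rows.append(
            {
                "element_id": el.element_id,
                "contig": el.contig,
                "start": el.start,
                "end": el.end,
                "ltr5_start": el.ltr5[0], "ltr5_end": el.ltr5[1],
                "ltr3_start": el.ltr3[0], "ltr3_end": el.ltr3[1],
                "tsd": el.tsd or "",
                "strand": el.strand,
                "ltr_identity": el.ltr_identity,
            }
        )
    return rows


def rows_to_elements(rows: list[dict]) -> list[detect.IntactElement]:
    out = []
    for row in rows:
        ltr5 = (int(row["ltr5_start"]), int(row["ltr5_end"]))
        ltr3 = (int(row["ltr3_start"]), int(row["ltr3_end"]))
        out.append(
            detect.IntactElement(
                contig=row["contig"],
                ltr5=ltr5,
                ltr3=ltr3,
                internal=(ltr5[1], ltr3[0]),
                tsd=row["tsd"] or None,
                strand=row["strand"],
                ltr_identity=float(row["ltr_identity"]),
                element_id=row["element_id"],
            )
        )
    return out


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.files: list[str] = []
        self.log_lines: list[str] = []

    def path(self, name: str) -> Path:
        self.files.append(name)
        return self.outdir / name

    def log(self, stage: str, level: str, message: str):
        self.log_lines.append(f"{stage}\t{level}\t{message}")

    def finalize(self):
        log_path = self.outdir / "log.txt"
        with open(log_path, "w") as handle:
            handle.write("\n".join(self.log_lines) + "\n")
        self.files.append("log.txt")
        with open(self.outdir / "manifest.json", "w") as handle:
            json.dump({"files": sorted(set(self.files))}, handle, indent=2)


def run_pipeline(config: PipelineConfig) -> RunReport:
    outdir = ioutils.ensure_dir(config.outdir)
    manifest = _Manifest(outdir)
    on = config.stages

    genome: synth.SyntheticGenome | None = None
    genome_seq: str | None = None
    reads: synth.ReadSet | None = None
    elements: list[detect.IntactElement] | None = None
    superfamilies: dict[str, str] = {}
    domain_hits: dict[str, list[taxonomy.DomainHit]] = {}
    families: list[taxonomy.Family] | None = None
    dates: list[chronology.InsertionDate] | None = None
    age_summaries: dict = {}
    family_depth: dict[str, float] = {}
    library = None
    mapped_fraction = 0.0

    def require(value, producer: str, consumer: str):
        if value is None:
            raise StageError(
                consumer, f"requires outputs of stage '{producer}' which is disabled"
            )
        return value

    if on.get("simulate", True):
        specs = config.family_specs()
        genome = synth.build_genome(
            specs,
            background_length=config.background_length,
            mutation_rate=config.mutation_rate,
            seed=stage_seed(config.seed, "simulate"),
        )
        genome_seq = genome.sequence
        manifest.log("simulate", "info",
                     f"genome {len(genome_seq)} bp, {len(genome.truth)} planted copies")
        ioutils.write_fasta({"chr1": genome_seq}, manifest.path("genome.fa"))
        synth.write_truth(genome, outdir / "truth")
        manifest.files += ["truth.gff3", "truth.tsv"]
        reads = synth.simulate_reads(
            genome,
            coverage=config.coverage,
            read_length=config.read_length,
            error_rate=config.read_error_rate,
            seed=stage_seed(config.seed, "reads"),
        )
        ioutils.write_fastq_pairs(
            [(p.read1, p.read2) for p in reads.pairs],
            manifest.path("reads_1.fq"),
            manifest.path("reads_2.fq"),
        )
        manifest.log("simulate", "info", f"{len(reads.pairs)} read pairs at "
                     f"{config.coverage}x")

    if on.get("detect", True):
        seq = require(genome_seq, "simulate", "detect")
        det_config = detect.DetectorConfig(**config.detector)
        manifest.log("detect", "info", f"config {det_config}")
        elements = detect.find_intact_elements(seq, det_config)
        elements = detect.remove_tandem_false_positives(elements, seq)
        ioutils.write_gff3(detect.elements_to_gff(elements),
                           manifest.path("elements.gff3"))
        ioutils.write_tsv(_elements_to_rows(elements), manifest.path("elements.tsv"))
        manifest.log("detect", "info", f"{len(elements)} intact elements")

    if on.get("classify", True):
        els = require(elements, "detect", "classify")
        seq = require(genome_seq, "simulate", "classify")
        references = synth.domain_references()
        rows = []
        for el in els:
            internal = seq[slice(*el.internal)]
            hits = taxonomy.scan_domains(internal, references)
            domain_hits[el.element_id] = hits
            superfamilies[el.element_id] = taxonomy.classify_superfamily(hits)
            rows.append(
                {
                    "element_id": el.element_id,
                    "superfamily": superfamilies[el.element_id],
                    "domains": ",".join(h.domain for h in hits),
                }
            )
        ioutils.write_tsv(rows, manifest.path("superfamilies.tsv"),
                          columns=["element_id", "superfamily", "domains"])
        manifest.log("classify", "info",
                     f"{sum(1 for v in superfamilies.values() if v != 'unclassified')}"
                     " elements with pol domains")

    if on.get("cluster", True):
        els = require(elements, "detect", "cluster")
        seq = require(genome_seq, "simulate", "cluster")
        clu_config = taxonomy.ClusteringConfig(**config.clustering)
        ltrs = {el.element_id: seq[slice(*el.ltr5)] for el in els}
        raw_families = taxonomy.cluster_families(ltrs, clu_config, superfamilies)
        families = taxonomy.name_and_rank_families(raw_families)
        rows = [
            {
                "family_id": fam.family_id,
                "superfamily": fam.superfamily,
                "n_intact": fam.n_intact,
                "copy_class": fam.copy_class,
                "members": ",".join(fam.members),
            }
            for fam in families
        ]
        ioutils.write_tsv(rows, manifest.path("families.tsv"),
                          columns=["family_id", "superfamily", "n_intact",
                                   "copy_class", "members"])
        manifest.log("cluster", "info", f"{len(families)} families")

    member_family = {}
    if families:
        for fam in families:
            for member in fam.members:
                member_family[member] = fam.family_id

    if on.get("date", True):
        els = require(elements, "detect", "date")
        seq = require(genome_seq, "simulate", "date")
        clock = chronology.ClockConfig(**config.clock)
        dates = chronology.date_elements(els, seq, clock, family_of=member_family)
        ioutils.write_tsv(
            [
                {
                    "element_id": d.element_id,
                    "family_id": d.family_id,
                    "p": f"{d.p:.6f}",
                    "K": f"{d.K:.6f}",
                    "T": f"{d.T:.1f}",
                    "aligned_sites": d.aligned_sites,
                    "datable": int(d.datable),
                }
                for d in dates
            ],
            manifest.path("dates.tsv"),
            columns=["element_id", "family_id", "p", "K", "T",
                     "aligned_sites", "datable"],
        )
        by_family: dict[str, list[float]] = {}
        for d in dates:
            if d.datable and d.family_id:
                by_family.setdefault(d.family_id, []).append(d.T)
        age_summaries = chronology.summarize_family_ages(by_family)
        manifest.log("date", "info",
                     f"{sum(1 for d in dates if d.datable)} datable elements")

    if on.get("tree", True):
        els = require(elements, "detect", "tree")
        seq = require(genome_seq, "simulate", "tree")
        if not domain_hits and on.get("classify", True) is False:
            raise StageError("tree", "requires outputs of stage 'classify' which is disabled")
        rt_seqs = {}
        for el in els:
            hits = domain_hits.get(el.element_id, [])
            rt = next((h for h in hits if h.domain == "RT"), None)
            if rt is None:
                manifest.log("tree", "info",
                             f"{el.element_id}: no RT hit, excluded from tree")
                continue
            protein, clean = phylo.extract_rt(seq[slice(*el.internal)], rt)
            if not clean:
                manifest.log("tree", "warn",
                             f"{el.element_id}: internal stop codons in RT")
            rt_seqs[el.element_id] = protein.rstrip("*")
        ioutils.write_fasta(rt_seqs, manifest.path("rt.fasta"))
        if len(rt_seqs) >= 3:
            aligned = phylo.align_sequences(rt_seqs)
            dm = phylo.p_distance_matrix(aligned)
            tree = phylo.neighbor_joining(dm)
            with open(manifest.path("tree.nwk"), "w") as handle:
                handle.write(tree.to_newick() + "\n")
            manifest.log("tree", "info", f"NJ tree over {len(rt_seqs)} RT sequences")
        else:
            manifest.log("tree", "warn",
                         f"only {len(rt_seqs)} RT sequences; tree skipped")

    if on.get("depth", True):
        els = require(elements, "detect", "depth")
        seq = require(genome_seq, "simulate", "depth")
        rds = require(reads, "simulate", "depth")
        ltr_triples = [
            (el.element_id, member_family.get(el.element_id, el.element_id),
             seq[slice(*el.ltr5)])
            for el in els
        ]
        library = abundance.build_ltr_library(
            ltr_triples, config.dedupe_identity, config.library_min_length
        )
        ioutils.write_fasta(
            [(rep.name, rep.sequence) for rep in library.representatives],
            manifest.path("library.fa"),
        )
        hit_sets = abundance.map_reads(rds, library)
        mean_depth = abundance.genome_mean_depth_from_reads(rds, len(seq))
        profile = abundance.depth_profile(hit_sets, library, mean_depth)
        family_depth = profile.family_depth
        n_reads = 2 * len(rds.pairs)
        mapped_fraction = (
            sum(1 for hs in hit_sets if hs) / n_reads if n_reads else 0.0
        )
        ioutils.write_tsv(
            [
                {"family_id": fam, "normalized_depth": f"{depth:.4f}"}
                for fam, depth in sorted(family_depth.items())
            ],
            manifest.path("depth.tsv"),
            columns=["family_id", "normalized_depth"],
        )
        manifest.log("depth", "info",
                     f"library {len(library)} representatives; "
                     f"mapped fraction {mapped_fraction:.4f}")

    counts = {
        "elements_detected": len(elements) if elements is not None else None,
        "families": len(families) if families is not None else None,
        "datable_elements": (
            sum(1 for d in dates if d.datable) if dates is not None else None
        ),
        "library_size": len(library) if library is not None else None,
        "mapped_read_fraction": round(mapped_fraction, 6) if library else None,
        "planted_copies": len(genome.truth) if genome is not None else None,
    }
    if families is not None and elements is not None:
        assert sum(f.n_intact for f in families) == len(elements)
    family_table = (
        make_family_table(families, age_summaries, family_depth, config.top_n)
        if families is not None
        else []
    )
    report = RunReport(
        counts=counts,
        family_table=family_table,
        parameters=config.to_dict(),
    )
    with open(manifest.path("report.json"), "w") as handle:
        handle.write(report.to_json() + "\n")
    manifest.finalize()
    return report
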