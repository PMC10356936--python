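"""End-to-end pipeline: screen -> primers -> abundance -> classify -> traits -> mcr.

Each stage reads plain-text inputs (TSV/FASTA/JSON), writes its outputs
into the run directory with a ``#config_hash=`` header, and contributes a
summary block to one JSON manifest.  The manifest records versions,
thresholds and seeds but no timestamps or absolute paths, so two runs of
the same configuration produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, abundance, biogeography, io, mcr, nif_screen, primer_match
from . import simulate, traits

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; prior intermediates are left intact."""


@dataclass
class PipelineConfig:
    """Input paths and thresholds for one full run.

    Optional stages are skipped when their input path is None.  Thresholds
    default to the screening e-value cutoff 1e-5, alignment filters
    (95% identity / 80 bp / 0.8 fraction), detection CPMM 1, and the
    Arctic latitude bound 66.5 degrees N.
    """

    outdir: str
    annotations: str | None = None
    contig_lengths: str | None = None
    nifh_targets: str | None = None
    primer_sets: str | None = None
    counts: str | None = None
    genome_lengths: str | None = None
    sample_meta: str | None = None
    proteomes: str | None = None
    cds: str | None = None
    modules: str | None = None
    ko_sets: str | None = None
    cold_gene_map: str | None = None
    seed: int = 0
    evalue_cutoff: float = nif_screen.DEFAULT_EVALUE_CUTOFF
    edge_rank: int = 1
    max_mismatch: int = 0
    detection_cpmm: float = abundance.DETECTION_CPMM
    arctic_min: float = abundance.ARCTIC_LATITUDE
    min_samples: int = 2
    endemicity_slack: int = 0
    marker_map: dict[str, list[str]] = field(
        default_factory=lambda: {k: sorted(v)
                                 for k, v in nif_screen.DEFAULT_MARKER_MAP.items()})

    def validate(self) -> None:
        for name in ("annotations", "nifh_targets", "primer_sets", "counts",
                     "genome_lengths", "sample_meta", "proteomes", "cds",
                     "modules", "ko_sets", "cold_gene_map", "contig_lengths"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"pipeline input {name}: {path} does not exist")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # manifest stability: record basenames, not absolute paths
        for key, val in d.items():
            if isinstance(val, str) and ("/" in val or "\\" in val):
                d[key] = Path(val).name
        return d


def simulate_inputs(sim_config: simulate.SimulationConfig, outdir: str | Path,
                    ) -> PipelineConfig:
    """Generate every pipeline input from the synthetic-data module.

    Writes annotation TSV, nifH target FASTA + primer JSON, survey count and
    metadata TSVs, module/KO TSVs and the truth tables, then returns a
    PipelineConfig wired to them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes, _, genome_truth = simulate.make_genomes(sim_config)
    io.write_tsv(io.annotations_to_frame(genomes), outdir / "annotations.tsv")
    contig_lengths = {
        g.genome_id: g.contig_lengths for g in genomes}
    (outdir / "contig_lengths.json").write_text(
        json.dumps(contig_lengths, indent=1, sort_keys=True))
    io.write_tsv(genome_truth, outdir / "truth_screen.tsv")

    targets, primer_truth = simulate.make_primer_targets(sim_config)
    io.write_fasta(targets, outdir / "nifh_targets.fasta")
    pset = simulate.DEFAULT_PRIMER_SET
    (outdir / "primer_sets.json").write_text(json.dumps([{
        "set_id": pset.set_id, "forward": pset.forward, "reverse": pset.reverse,
        "amplicon_min": pset.amplicon_bounds[0],
        "amplicon_max": pset.amplicon_bounds[1]}], indent=1))
    io.write_tsv(primer_truth, outdir / "truth_primers.tsv")

    summary, meta, survey_truth = simulate.make_survey(sim_config, genomes)
    counts = pd.DataFrame(
        [(s, g, c) for (s, g), c in sorted(summary.counts.items())],
        columns=["sample", "genome", "count"])
    io.write_tsv(counts, outdir / "counts.tsv")
    lengths = pd.DataFrame(sorted(summary.genome_lengths.items()),
                           columns=["genome", "length"])
    io.write_tsv(lengths, outdir / "genome_lengths.tsv")
    meta = meta.copy()
    meta["total_reads"] = meta["sample"].map(summary.total_reads)
    io.write_tsv(meta, outdir / "sample_meta.tsv")
    io.write_tsv(survey_truth, outdir / "truth_survey.tsv")

    ko_sets, modules, ko_truth = simulate.make_ko_sets(sim_config)
    io.write_tsv(pd.DataFrame(
        [(m.module_id, m.category, m.definition or mcr.serialize(m.expression))
         for m in modules.values()],
        columns=["module_id", "category", "definition"]), outdir / "modules.tsv")
    io.write_tsv(pd.DataFrame(
        [(g, ko) for g in sorted(ko_sets) for ko in sorted(ko_sets[g])],
        columns=["genome_id", "ko"]), outdir / "ko_sets.tsv")
    io.write_tsv(ko_truth, outdir / "truth_mcr.tsv")

    return PipelineConfig(
        outdir=str(outdir / "results"),
        annotations=str(outdir / "annotations.tsv"),
        contig_lengths=str(outdir / "contig_lengths.json"),
        nifh_targets=str(outdir / "nifh_targets.fasta"),
        primer_sets=str(outdir / "primer_sets.json"),
        counts=str(outdir / "counts.tsv"),
        genome_lengths=str(outdir / "genome_lengths.tsv"),
        sample_meta=str(outdir / "sample_meta.tsv"),
        modules=str(outdir / "modules.tsv"),
        ko_sets=str(outdir / "ko_sets.tsv"),
        seed=sim_config.seed,
    )


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        wrapped.__name__ = fn.__name__
        return wrapped
    return deco


@_stage("screen")
def _run_screen(config: PipelineConfig, outdir: Path, chash: str) -> dict:
    frame = io.read_tsv(config.annotations)
    contig_lengths = None
    if config.contig_lengths:
        contig_lengths = json.loads(Path(config.contig_lengths).read_text())
    genomes = io.frame_to_annotations(frame, contig_lengths)
    marker_map = {k: set(v) for k, v in config.marker_map.items()}
    inventories = nif_screen.screen(genomes, marker_map, config.evalue_cutoff,
                                    config.edge_rank)
    table = pd.DataFrame(
        [[inv.genome_id] + [inv.presence[g] for g in nif_screen.NIF_GENES]
         + [inv.rescue_applied, inv.verdict] for inv in inventories],
        columns=["genome"] + list(nif_screen.NIF_GENES) + ["rescue_applied", "verdict"])
    io.write_tsv(table, outdir / "nif_inventory.tsv", header=f"config_hash={chash}")
    return nif_screen.summarize_screen(inventories)


@_stage("primers")
def _run_primers(config: PipelineConfig, outdir: Path, chash: str) -> dict:
    targets = io.read_fasta(config.nifh_targets)
    primer_sets = io.read_primer_sets(config.primer_sets)
    rows = []
    for name in targets:
        report = primer_match.match_report(name, targets[name], primer_sets,
                                           config.max_mismatch)
        rows.append([name] + [report.set_compatible[s.set_id] for s in primer_sets]
                    + [report.overall])
    table = pd.DataFrame(
        rows, columns=["target"] + [s.set_id for s in primer_sets] + ["compatible"])
    io.write_tsv(table, outdir / "primer_report.tsv", header=f"config_hash={chash}")
    return {"n_targets": len(targets),
            "n_compatible": int(table["compatible"].sum())}


@_stage("abundance")
def _run_abundance(config: PipelineConfig, outdir: Path, chash: str) -> dict:
    counts = io.read_tsv(config.counts)
    lengths = io.read_tsv(config.genome_lengths)
    meta = io.read_tsv(config.sample_meta)
    summary = abundance.MappingSummary(
        counts={(r.sample, r.genome): int(r.count) for r in counts.itertuples()},
        total_reads={r.sample: int(r.total_reads) for r in meta.itertuples()},
        genome_lengths={r.genome: int(r.length) for r in lengths.itertuples()})
    matrix = abundance.abundance_matrix(summary)
    io.write_tsv(matrix, outdir / "abundance.tsv", header=f"config_hash={chash}")
    strat = abundance.stratify(matrix, meta, config.detection_cpmm, config.arctic_min)
    io.write_tsv(strat, outdir / "stratified.tsv", header=f"config_hash={chash}")
    return {"n_samples": int(matrix["sample"].nunique()),
            "n_genomes": int(matrix["genome"].nunique()),
            "max_cpmm": float(matrix["CPMM"].max())}


@_stage("classify")
def _run_classify(config: PipelineConfig, outdir: Path, chash: str) -> dict:
    strat = io.read_tsv(outdir / "stratified.tsv")
    rules = biogeography.ClassificationRules(
        min_samples=config.min_samples, endemicity_slack=config.endemicity_slack)
    calls = biogeography.classify_biogeography(strat, rules)
    table = pd.DataFrame(
        [(c.genome_id, c.pattern, json.dumps(c.detections, sort_keys=True))
         for c in calls], columns=["genome", "pattern", "detections"])
    io.write_tsv(table, outdir / "biogeography.tsv", header=f"config_hash={chash}")
    profile = biogeography.fraction_profile(strat)
    io.write_tsv(profile, outdir / "fraction_profile.tsv", header=f"config_hash={chash}")
    counts = table["pattern"].value_counts().to_dict()
    return {p: int(counts.get(p, 0)) for p in biogeography.PATTERNS}


@_stage("traits")
def _run_traits(config: PipelineConfig, outdir: Path, chash: str) -> dict:
    summary: dict = {}
    if config.proteomes:
        proteome = io.read_fasta(config.proteomes)
        summary["ivywrel_fraction"] = round(traits.ivywrel_fraction(proteome), 6)
    if config.cds:
        cds = io.read_fasta(config.cds)
        usage = traits.codon_usage(cds)
        summary["n_cds"] = len(cds)
        summary["top_codon"] = traits.CODONS[int(usage.argmax())] if usage.sum() else None
    if config.annotations and config.cold_gene_map:
        frame = io.read_tsv(config.annotations)
        genomes = io.frame_to_annotations(frame)
        gene_map = {k: set(v)
                    for k, v in json.loads(Path(config.cold_gene_map).read_text()).items()}
        table = traits.cold_gene_inventory(genomes, gene_map, config.evalue_cutoff)
        io.write_tsv(table, outdir / "cold_genes.tsv", header=f"config_hash={chash}")
        summary["n_cold_gene_labels"] = len(gene_map)
    return summary or {"skipped": True}


@_stage("mcr")
def _run_mcr(config: PipelineConfig, outdir: Path, chash: str) -> dict:
    modules = io.read_modules(config.modules)
    ko_sets = io.read_ko_sets(config.ko_sets)
    matrix = mcr.mcr_matrix(modules, ko_sets)
    out = matrix.reset_index().rename(columns={"index": "genome"})
    io.write_tsv(out, outdir / "mcr_matrix.tsv", header=f"config_hash={chash}")
    summary = {"n_modules": matrix.shape[1], "n_genomes": matrix.shape[0]}
    if len(matrix) >= 2 and (matrix.to_numpy() != 0).any():
        Z, labels = mcr.cluster_profiles(matrix)
        io.write_newick(mcr.linkage_to_newick(Z, labels), outdir / "mcr_dendrogram.nwk")
        summary["max_linkage_height"] = round(float(Z[-1, 2]), 6)
    return summary


_STAGES = [
    ("screen", _run_screen, ("annotations",)),
    ("primers", _run_primers, ("nifh_targets", "primer_sets")),
    ("abundance", _run_abundance, ("counts", "genome_lengths", "sample_meta")),
    ("classify", _run_classify, ("counts", "genome_lengths", "sample_meta")),
    ("traits", _run_traits, ()),
    ("mcr", _run_mcr, ("modules", "ko_sets")),
]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage whose inputs are configured; write the manifest.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory).  A stage failure raises :class:`StageError` naming
    the stage; outputs of earlier stages are left in place.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_dict = config.to_dict()
    chash = io.config_hash(config_dict)
    manifest = {
        "tool": "diazoscan",
        "version": __version__,
        "config": config_dict,
        "config_hash": chash,
        "stages": {},
    }
    for name, fn, required in _STAGES:
        if any(getattr(config, r) is None for r in required):
            manifest["stages"][name] = {"skipped": True}
            continue
        log.info("[%s] running", name)
        manifest["stages"][name] = fn(config, outdir, chash)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
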