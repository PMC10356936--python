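"""Readers and writers shared across the pipeline.

External conventions: FASTA with unique ids; GFF3 with 1-based inclusive
coordinates and ``gene`` features carrying ``ID`` and ``product``
attributes; TSV with a header row.  Coordinates stay 1-based inclusive in
files and in :class:`~diazoscan.nif_screen.GeneRecord`; any half-open
arithmetic is local to the function that needs it.  Output files carry a
``#config_hash=`` header comment so identical configurations can be
recognised from the artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from urllib.parse import quote, unquote

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .nif_screen import GeneRecord, GenomeAnnotation
from .primer_match import PrimerSet


class FormatError(ValueError):
    """A malformed input file; the message names the file and line."""


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered {id: sequence}; duplicate ids are a format error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- GFF3

def write_gff(genome: GenomeAnnotation, path: str | Path, header: str = "") -> None:
    """Write a genome's gene features as GFF3 (1-based inclusive)."""
    lines = ["##gff-version 3"]
    if header:
        lines.append(f"#{header}")
    for contig, length in sorted(genome.contig_lengths.items()):
        lines.append(f"##sequence-region {contig} 1 {length}")
    for gene in sorted(genome.genes, key=lambda g: (g.contig_id, g.start)):
        product = gene.hits[0][0] if gene.hits else "hypothetical"
        attrs = f"ID={quote(gene.gene_id)};product={quote(product)}"
        lines.append("\t".join([
            gene.contig_id, "diazoscan", "gene", str(gene.start), str(gene.end),
            ".", gene.strand, ".", attrs]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff(path: str | Path, genome_id: str | None = None) -> GenomeAnnotation:
    """Read `gene` features of a GFF3 file into a GenomeAnnotation.

    Coordinates are validated against ##sequence-region pragmas when
    present; a gene extending past its contig is a format error.
    """
    path = Path(path)
    contig_lengths: dict[str, int] = {}
    raw: list[tuple[str, int, int, str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: malformed sequence-region pragma")
            contig_lengths[parts[1]] = int(parts[3])
            continue
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
        contig, _, ftype, start, end, _, strand, _, attrs = cols
        if ftype != "gene":
            continue
        try:
            start_i, end_i = int(start), int(end)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
        if start_i < 1 or end_i < start_i:
            raise FormatError(f"{path}:{lineno}: malformed coordinates {start}..{end}")
        if contig in contig_lengths and end_i > contig_lengths[contig]:
            raise FormatError(
                f"{path}:{lineno}: gene end {end_i} exceeds contig length "
                f"{contig_lengths[contig]}")
        attr_map = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if "ID" not in attr_map:
            raise FormatError(f"{path}:{lineno}: gene feature lacks ID attribute")
        raw.append((contig, start_i, end_i, strand, unquote(attr_map["ID"])))
    for contig in {r[0] for r in raw}:
        contig_lengths.setdefault(contig, max(r[2] for r in raw if r[0] == contig))
    genes = []
    by_contig: dict[str, list] = {}
    for contig, start, end, strand, gid in sorted(raw, key=lambda r: (r[0], r[1])):
        rank = len(by_contig.setdefault(contig, []))
        by_contig[contig].append(gid)
        genes.append(GeneRecord(
            gene_id=gid, genome_id=genome_id or path.stem, contig_id=contig,
            start=start, end=end, strand=strand, rank_on_contig=rank))
    return GenomeAnnotation(genome_id=genome_id or path.stem,
                            contig_lengths=contig_lengths, genes=genes)


# ---------------------------------------------------------------- TSV

def read_tsv(path: str | Path) -> pd.DataFrame:
    """TSV with a header row; ragged rows raise a FormatError naming the line."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty table")
    width = len(lines[0].split("\t"))
    for lineno, ln in enumerate(lines[1:], start=2):
        if ln and len(ln.split("\t")) != width:
            raise FormatError(f"{path}:{lineno}: expected {width} fields, "
                              f"got {len(ln.split(chr(9)))}")
    return pd.read_csv(path, sep="\t", comment="#")


def write_tsv(frame: pd.DataFrame, path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        frame.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------- newick

def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.rstrip("\n") + "\n")


def read_newick(path: str | Path) -> str:
    text = Path(path).read_text().strip()
    if not text.endswith(";"):
        raise FormatError(f"{path}: newick string must end with ';'")
    return text


# ------------------------------------------------- domain-table adapters

ANNOTATION_COLUMNS = ["gene_id", "genome_id", "contig_id", "start", "end",
                      "strand", "accession", "evalue"]


def annotations_to_frame(genomes: list[GenomeAnnotation]) -> pd.DataFrame:
    """Flatten genomes into the long annotation table (one row per hit).

    Hit-less genes get an empty accession and NaN e-value so their
    coordinates survive the round trip.
    """
    rows = []
    for genome in genomes:
        for gene in genome.genes:
            hits = gene.hits or ((None, None),)
            for acc, ev in hits:
                rows.append((gene.gene_id, genome.genome_id, gene.contig_id,
                             gene.start, gene.end, gene.strand, acc, ev))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def frame_to_annotations(
    frame: pd.DataFrame,
    contig_lengths: dict[str, dict[str, int]] | None = None,
) -> list[GenomeAnnotation]:
    """Rebuild GenomeAnnotation objects from the long annotation table.

    ``contig_lengths`` maps genome_id -> {contig_id: bp}; when absent, each
    contig's length is taken as the maximum gene end observed on it.
    """
    missing = set(ANNOTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"annotation table lacks columns: {sorted(missing)}")
    genomes = []
    for genome_id, gframe in frame.groupby("genome_id", sort=True):
        lengths = dict((contig_lengths or {}).get(genome_id, {}))
        for contig, cframe in gframe.groupby("contig_id"):
            lengths.setdefault(contig, int(cframe["end"].max()))
        genes = []
        for contig, cframe in gframe.groupby("contig_id"):
            gene_order = (cframe.groupby("gene_id")["start"].min()
                          .sort_values().index.tolist())
            for rank, gid in enumerate(gene_order):
                rows = cframe[cframe["gene_id"] == gid]
                first = rows.iloc[0]
                hits = tuple(
                    (str(r.accession), float(r.evalue))
                    for r in rows.itertuples()
                    if pd.notna(r.accession) and pd.notna(r.evalue))
                genes.append(GeneRecord(
                    gene_id=str(gid), genome_id=str(genome_id), contig_id=str(contig),
                    start=int(first["start"]), end=int(first["end"]),
                    strand=str(first["strand"]), rank_on_contig=rank, hits=hits))
        genomes.append(GenomeAnnotation(genome_id=str(genome_id),
                                        contig_lengths=lengths, genes=genes))
    return genomes


def read_primer_sets(path: str | Path) -> list[PrimerSet]:
    """Primer sets from JSON (list of objects) or TSV."""
    path = Path(path)
    if path.suffix == ".json":
        entries = json.loads(path.read_text())
    else:
        entries = read_tsv(path).to_dict("records")
    sets = []
    for e in entries:
        bounds = e.get("amplicon_bounds") or (e.get("amplicon_min", 200),
                                              e.get("amplicon_max", 500))
        partner = e.get("nested_partner")
        if pd.isna(partner) if not isinstance(partner, (str, type(None))) else False:
            partner = None
        sets.append(PrimerSet(
            set_id=str(e["set_id"]), forward=str(e["forward"]),
            reverse=str(e["reverse"]), nested_partner=partner,
            amplicon_bounds=(int(bounds[0]), int(bounds[1]))))
    return sets


def read_modules(path: str | Path):
    """Module definition TSV (module_id, category, definition) -> dict."""
    from .mcr import parse_module
    frame = read_tsv(path)
    return {
        str(r.module_id): parse_module(str(r.definition), str(r.module_id),
                                       str(r.category))
        for r in frame.itertuples()
    }


def read_ko_sets(path: str | Path) -> dict[str, set[str]]:
    """KO membership TSV (genome_id, ko) -> {genome: set of KOs}."""
    frame = read_tsv(path)
    out: dict[str, set[str]] = {}
    for r in frame.itertuples():
        out.setdefault(str(r.genome_id), set()).add(str(r.ko))
    return out
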