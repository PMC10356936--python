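"""Diazotroph screening of genomes from HMM hit tables.

A genome is called a diazotroph when it carries the full nitrogenase gene
complement nifH, nifD, nifK (structural subunits) and nifE, nifN, nifB
(FeMo-cofactor biosynthesis).  nifH alone is a poor marker: a substantial
fraction of nifH-positive genomes in public databases lack nifD/nifK and
cannot fix nitrogen.  Draft genomes binned from metagenomic assemblies are
fragmented, so a genome whose nifD sits at the very end of a contig may
appear to lack nifK only because the nifHDK operon was truncated by the
assembly; such genomes are rescued by a structural rule rather than
rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

NIF_GENES = ("nifH", "nifD", "nifK", "nifE", "nifN", "nifB")

#: nifH is identified by its TIGRFAM model; the remaining five default to the
#: corresponding TIGRFAM nitrogenase/cofactor models but are user-overridable.
DEFAULT_MARKER_MAP: dict[str, frozenset[str]] = {
    "nifH": frozenset({"TIGR01287"}),
    "nifD": frozenset({"TIGR01282"}),
    "nifK": frozenset({"TIGR01286"}),
    "nifE": frozenset({"TIGR01283"}),
    "nifN": frozenset({"TIGR01285"}),
    "nifB": frozenset({"TIGR01290"}),
}

DEFAULT_EVALUE_CUTOFF = 1e-5


@dataclass(frozen=True)
class GeneRecord:
    """One predicted protein-coding gene with its HMM hits.

    Coordinates are 1-based inclusive on the contig; ``rank_on_contig`` is
    the 0-based ordinal of the gene along its contig in coordinate order.
    ``hits`` is a list of (marker accession, e-value) pairs.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    rank_on_contig: int
    hits: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if any(e < 0 for _, e in self.hits):
            raise ValueError(f"gene {self.gene_id}: negative e-value")

    def best_hit(self) -> tuple[str, float] | None:
        """Lowest-e-value hit, or None if the gene has no hits.

        Ties between a nif marker and another marker resolve toward the nif
        marker (logged); ties are pathological with real HMM scores.
        """
        if not self.hits:
            return None
        best_e = min(e for _, e in self.hits)
        tied = [(a, e) for a, e in self.hits if e == best_e]
        if len(tied) > 1:
            all_nif = frozenset().union(*DEFAULT_MARKER_MAP.values())
            nif_tied = [t for t in tied if t[0] in all_nif]
            if nif_tied:
                log.warning("gene %s: e-value tie resolved toward nif marker %s",
                            self.gene_id, nif_tied[0][0])
                return nif_tied[0]
        return tied[0]


@dataclass
class GenomeAnnotation:
    """A genome's contigs and annotated genes — the unit screened."""

    genome_id: str
    contig_lengths: dict[str, int]
    genes: list[GeneRecord] = field(default_factory=list)
    taxonomy: str | None = None

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.contig_id not in self.contig_lengths:
                raise ValueError(f"gene {g.gene_id} on unknown contig {g.contig_id}")
            if g.end > self.contig_lengths[g.contig_id]:
                raise ValueError(
                    f"gene {g.gene_id} end {g.end} exceeds contig "
                    f"{g.contig_id} length {self.contig_lengths[g.contig_id]}")

    @property
    def genome_length(self) -> int:
        return sum(self.contig_lengths.values())

    def genes_on_contig(self, contig_id: str) -> list[GeneRecord]:
        return sorted((g for g in self.genes if g.contig_id == contig_id),
                      key=lambda g: g.start)


@dataclass
class NifInventory:
    """Per-genome nif presence/absence plus the screening verdict."""

    genome_id: str
    presence: dict[str, bool]
    rescue_applied: bool = False
    verdict: str = "non_diazotroph"

    @property
    def missing(self) -> list[str]:
        return [g for g in NIF_GENES if not self.presence.get(g, False)]


def _check_marker_map(marker_map: dict) -> dict[str, frozenset[str]]:
    missing = [g for g in NIF_GENES if g not in marker_map]
    if missing:
        raise ValueError(f"marker_map missing nif genes: {missing}")
    return {g: frozenset(marker_map[g]) for g in marker_map}


def _significant_best_hit(gene: GeneRecord, cutoff: float) -> str | None:
    best = gene.best_hit()
    if best is None or best[1] >= cutoff:
        return None
    return best[0]


def detect_nifH(
    genomes: list[GenomeAnnotation],
    marker: str = "TIGR01287",
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> list[str]:
    """Genomes with >=1 gene whose significant best hit is the nifH marker.

    A gene qualifies when its lowest-e-value hit is ``marker`` and that
    e-value is strictly below ``evalue_cutoff``.
    """
    if evalue_cutoff < 0:
        raise ValueError("evalue_cutoff must be non-negative")
    out = []
    for genome in genomes:
        for gene in genome.genes:
            if _significant_best_hit(gene, evalue_cutoff) == marker:
                out.append(genome.genome_id)
                break
    return out


def inventory_nif(
    genome: GenomeAnnotation,
    marker_map: dict[str, set[str]] | None = None,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> NifInventory:
    """Presence/absence over the six nif genes (no verdict assigned yet)."""
    mm = _check_marker_map(marker_map or DEFAULT_MARKER_MAP)
    presence = {g: False for g in NIF_GENES}
    for gene in genome.genes:
        acc = _significant_best_hit(gene, evalue_cutoff)
        if acc is None:
            continue
        for nif_gene in NIF_GENES:
            if acc in mm[nif_gene]:
                presence[nif_gene] = True
    return NifInventory(genome_id=genome.genome_id, presence=presence)


def rescue_fragmented(
    genome: GenomeAnnotation,
    inventory: NifInventory,
    edge_rank: int = 1,
    marker_map: dict[str, set[str]] | None = None,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> bool:
    """Assembly-fragmentation rescue: nifK alone missing, nifD contig-terminal.

    nifHDK generally form an operon, so a nifD within ``edge_rank`` genes of
    either contig end suggests the contig (and the operon) was truncated
    before nifK.  Returns False on any unmet condition; applies to nifK only.
    """
    if inventory.missing != ["nifK"]:
        return False
    mm = _check_marker_map(marker_map or DEFAULT_MARKER_MAP)
    for gene in genome.genes:
        acc = _significant_best_hit(gene, evalue_cutoff)
        if acc is None or acc not in mm["nifD"]:
            continue
        contig_genes = genome.genes_on_contig(gene.contig_id)
        n = len(contig_genes)
        rank = next(i for i, g in enumerate(contig_genes) if g.gene_id == gene.gene_id)
        if rank < edge_rank or rank >= n - edge_rank:
            return True
    return False


def screen(
    genomes: list[GenomeAnnotation],
    marker_map: dict[str, set[str]] | None = None,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    edge_rank: int = 1,
) -> list[NifInventory]:
    """Full diazotroph screen: inventory, rescue, verdict per genome.

    Verdicts: ``diazotroph`` (all six nif genes), ``diazotroph_rescued``
    (only nifK missing with contig-terminal nifD), else ``non_diazotroph``.
    """
    inventories = []
    for genome in genomes:
        inv = inventory_nif(genome, marker_map, evalue_cutoff)
        if not inv.missing:
            inv.verdict = "diazotroph"
        elif rescue_fragmented(genome, inv, edge_rank, marker_map, evalue_cutoff):
            inv.rescue_applied = True
            inv.verdict = "diazotroph_rescued"
        else:
            inv.verdict = "non_diazotroph"
        inventories.append(inv)
    return inventories


def summarize_screen(inventories: list[NifInventory]) -> dict[str, int]:
    """Summary counts; diazotrophs include rescued genomes."""
    n_diazo = sum(1 for i in inventories if i.verdict in ("diazotroph", "diazotroph_rescued"))
    return {
        "n_screened": len(inventories),
        "n_diazotroph": n_diazo,
        "n_rescued": sum(1 for i in inventories if i.verdict == "diazotroph_rescued"),
        "n_rejected": len(inventories) - n_diazo,
    }


def _ungapped_local_identity(query: str, reference: str) -> float:
    """Best ungapped local identity between two sequences.

    Maximum over all relative offsets of (#matching positions in the
    overlap) / min(len(query), len(reference)).
    """
    q, r = query.upper(), reference.upper()
    if not q or not r:
        return 0.0
    denom = min(len(q), len(r))
    best = 0
    for shift in range(-(len(q) - 1), len(r)):
        matches = 0
        for i, aa in enumerate(q):
            j = shift + i
            if 0 <= j < len(r) and aa == r[j]:
                matches += 1
        best = max(best, matches)
    return best / denom


def assign_nifH_cluster(
    nifH_protein: str,
    references: dict[str, str],
    identity_floor: float = 0.60,
) -> str:
    """Assign a nifH protein to a canonical nifH cluster (I–IV).

    ``references`` maps reference id -> protein sequence, where the cluster
    label is the reference id's prefix up to the first ``|`` (e.g.
    ``I|Azotobacter``) or the whole id.  The query takes the cluster of the
    highest-identity reference; ``unassigned`` below ``identity_floor``.
    """
    if not references:
        raise ValueError("empty nifH cluster reference set")
    best_label, best_ident = "unassigned", -1.0
    for ref_id in sorted(references):
        ident = _ungapped_local_identity(nifH_protein, references[ref_id])
        if ident > best_ident:
            best_ident = ident
            best_label = ref_id.split("|", 1)[0]
    if best_ident < identity_floor:
        return "unassigned"
    return best_label
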