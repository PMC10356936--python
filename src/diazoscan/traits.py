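"""Genome-level trait scans: cold adaptation, thermal signature, gene families.

Cold-environment adaptation leaves genomic signatures: cold-inducible
proteins (the RNA chaperone CspA above all, the low-temperature lipid-A
acyltransferase LpxP, DEAD-box RNA helicases, the DNA-repair phosphatase
Gph), and a proteome-wide amino-acid composition — the pooled fraction of
the seven residues I, V, Y, W, R, E, L tracks optimal growth temperature.
Gene-family counts (e.g. glycosyltransferases, which drive extracellular
polysaccharide production) and codon-usage ordination complete the scan.
"""

from __future__ import annotations

import logging
from collections import Counter
from itertools import product

import numpy as np
import pandas as pd

from .nif_screen import DEFAULT_EVALUE_CUTOFF, GenomeAnnotation, _significant_best_hit
from . import mcr as mcr_mod

log = logging.getLogger(__name__)

IVYWREL = frozenset("IVYWREL")
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Cold-inducible gene labels shipped by default; accession sets are data and
#: must be supplied by the caller's gene map.
COLD_GENE_LABELS = ("cspA", "lpxP", "deadBox", "gph")

CODONS = tuple("".join(c) for c in product("ACGT", repeat=3))
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}


def cold_gene_inventory(
    genomes: list[GenomeAnnotation],
    gene_map: dict[str, set[str]],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> pd.DataFrame:
    """Presence/absence of cold-inducible genes per genome.

    A gene label is present iff some gene's significant best hit falls in
    the label's accession set.  The e-value cutoff defaults to the
    screening cutoff for consistency.
    """
    if not gene_map:
        raise ValueError("empty cold-gene map")
    rows = []
    for genome in genomes:
        best_hits = {_significant_best_hit(g, evalue_cutoff) for g in genome.genes}
        best_hits.discard(None)
        rows.append([genome.genome_id] + [
            bool(best_hits & set(gene_map[label])) for label in sorted(gene_map)])
    return pd.DataFrame(rows, columns=["genome"] + sorted(gene_map))


def ivywrel_fraction(proteome: dict[str, str]) -> float:
    """Pooled IVYWREL fraction of a proteome.

    (count of I+V+Y+W+R+E+L) / (count of all 20 canonical residues), pooled
    over every sequence — not averaged per protein.  X, stops and other
    non-canonical symbols are excluded from the denominator.
    """
    counts = Counter()
    for seq in proteome.values():
        counts.update(seq.upper())
    denom = sum(n for aa, n in counts.items() if aa in CANONICAL_AA)
    if denom == 0:
        return 0.0
    return sum(n for aa, n in counts.items() if aa in IVYWREL) / denom


def count_family(
    genome: GenomeAnnotation,
    family: set[str],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> int:
    """Number of genes whose significant best hit is in the family's accessions."""
    if not family:
        raise ValueError("empty gene-family accession set")
    return sum(1 for g in genome.genes
               if _significant_best_hit(g, evalue_cutoff) in family)


def codon_usage(cds: dict[str, str]) -> np.ndarray:
    """Relative codon frequencies pooled over a genome's coding sequences.

    Returns a 64-vector in the fixed lexicographic codon order (AAA..TTT)
    summing to 1.  Trailing partial codons are dropped with a warning;
    codons containing ambiguous bases are skipped.
    """
    counts = np.zeros(64, dtype=float)
    for seq_id, seq in cds.items():
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3:
            log.warning("CDS %s length %d not divisible by 3; trailing bases dropped",
                        seq_id, len(seq))
        for i in range(0, len(seq) - len(seq) % 3, 3):
            idx = _CODON_INDEX.get(seq[i:i + 3])
            if idx is not None:
                counts[idx] += 1
    total = counts.sum()
    if total == 0:
        return counts
    return counts / total


def ordinate(vectors: dict[str, np.ndarray], n_components: int = 2) -> pd.DataFrame:
    """Centered principal-component projection of per-genome codon vectors.

    Deterministic sign convention: within each component, the loading of
    largest magnitude is made positive, so results do not depend on the
    eigensolver's arbitrary sign choice.
    """
    if len(vectors) < 2:
        raise ValueError("ordination needs >=2 genomes")
    ids = sorted(vectors)
    X = np.vstack([np.asarray(vectors[g], dtype=float) for g in ids])
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    comps = vt[:n_components]
    for k in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
    coords = X @ comps.T
    return pd.DataFrame(coords, index=ids,
                        columns=[f"PC{i + 1}" for i in range(comps.shape[0])])


def pathway_presence(
    ko_sets: dict[str, set[str]],
    modules: dict[str, "mcr_mod.ModuleDefinition"],
    pathway_map: dict[str, str],
    threshold: float = 100.0,
) -> pd.DataFrame:
    """Presence of named degradation pathways per genome, via module completion.

    ``pathway_map`` maps a human label (e.g. "carbazole degradation") to a
    module id; a pathway is present when the module's completion ratio
    reaches ``threshold`` percent (default strict 100%).
    """
    unknown = [m for m in pathway_map.values() if m not in modules]
    if unknown:
        raise ValueError(f"pathway_map references unknown modules: {unknown}")
    labels = sorted(pathway_map)
    rows = []
    for genome in sorted(ko_sets):
        present = [
            mcr_mod.evaluate_mcr(modules[pathway_map[label]], ko_sets[genome]) >= threshold
            for label in labels
        ]
        rows.append([genome] + present)
    return pd.DataFrame(rows, columns=["genome"] + labels)
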