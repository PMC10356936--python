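"""Screen a panel of genomes for the full nitrogenase gene complement.

Builds the nine-genome panel (complete operons, a contig-truncated nifHD
case, a nifB-less genome, and a nifH-only genome), runs the screen, and
prints each verdict.  The truncated genome is rescued because nifHDK form
an operon: a nifD at a contig end means nifK was likely lost to assembly
fragmentation, not from the organism.
"""

from diazoscan import NIF_GENES, screen, summarize_screen
from diazoscan.simulate import NifProfile, SimulationConfig, make_genomes

ALL = frozenset(NIF_GENES)
profiles = [
    NifProfile("complete-1", ALL),
    NifProfile("complete-2", ALL),
    NifProfile("truncated-operon", ALL - {"nifK"}, fragmented=True),
    NifProfile("no-nifB", ALL - {"nifB"}),
    NifProfile("nifH-only", frozenset({"nifH"})),
]

genomes, _, _ = make_genomes(SimulationConfig(seed=1, nif_profiles=profiles))
inventories = screen(genomes)

for inv in inventories:
    missing = ",".join(inv.missing) or "-"
    print(f"{inv.genome_id:18s} missing={missing:18s} verdict={inv.verdict}")
print(summarize_screen(inventories))
# Genomes lacking any of the six nif genes are rejected unless the rescue
# applies; the summary counts diazotrophs (incl. rescued) vs rejected.
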