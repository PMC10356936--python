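# diazoscan

Diazotroph discovery and biogeography from annotated genomes.

Marine nitrogen fixation is carried out by diazotrophs — prokaryotes whose
nitrogenase turns N₂ into ammonia. Surveys have long relied on the *nifH*
marker gene alone, but *nifH* without the rest of the nitrogenase gene
complement does not make a diazotroph: a genome must also carry *nifD* and
*nifK* (the MoFe protein subunits) and *nifE*, *nifN*, *nifB* (FeMo-cofactor
biosynthesis). `diazoscan` implements the genome-resolved screening and
biogeography workflow this implies, for people analysing metagenome-assembled
genomes (MAGs) from ocean surveys:

- **nif screening** — a genome is a diazotroph iff all six genes
  {*nifH, nifD, nifK, nifE, nifN, nifB*} have significant best HMM hits
  (*nifH*: best hit to TIGR01287, e < 1e−5), with an
  **assembly-fragmentation rescue**: if only *nifK* is missing and *nifD*
  sits at a contig end, the *nifHDK* operon was likely truncated by the
  assembly and the genome is rescued rather than rejected.
- **primer compatibility** — in-silico PCR of *nifH* sequences against
  degenerate (IUPAC) universal primer pairs: a target is detectable iff a
  forward and a convergent reverse site exist with a plausible amplicon span.
- **abundance** — the TPM-like, length-normalized statistics

  ```
  G_i  = 1000 · C_i / L_i
  CPMT = 10⁶ · G_i / Σⱼ G_j                (count per million targeted genomes)
  CPMM = CPMT · mapped_total / total_reads (count per million microbe genomes)
  ```

  from read counts filtered at ≥95% identity, ≥80 bp and ≥80% aligned
  fraction; a CPMM of 1000 ≈ 0.1% of the total community.
- **biogeography** — per-genome distribution patterns (Arctic-endemic /
  cosmopolitan / low-latitude-endemic / undetermined) from CPMM detections
  stratified by size fraction (≥0.2 µm, 0.2–3 µm, <0.2 µm), depth band
  (≤200 m, 200–1000 m, ≥1000 m) and latitude band (Arctic = ≥66.5°N).
- **traits** — cold-inducible gene inventory (*cspA*, *lpxP*, DEAD-box,
  *gph*), the pooled IVYWREL amino-acid fraction (a thermal-adaptation
  signature), gene-family counts, and codon-usage PCA.
- **mcr** — KEGG-style Boolean module definitions parsed and scored as
  module completion ratios (MCR), and complete-linkage Euclidean clustering
  of genomes by MCR profile.
- **synthetic data** — seeded generators for every input above, each with a
  planted truth table, so the whole pipeline runs and is testable with no
  external data.

## Worked example

```python
from diazoscan.abundance import MappingSummary, abundance_matrix, cpmm_to_percent

summary = MappingSummary(
    counts={("station-A", "genome-1"): 10, ("station-A", "genome-2"): 20},
    genome_lengths={"genome-1": 1000, "genome-2": 2000},
    total_reads={"station-A": 1000},
)
print(abundance_matrix(summary).to_string(index=False))
```

prints

```
   sample   genome  C    G     CPMT    CPMM
station-A genome-1 10 10.0 500000.0 15000.0
station-A genome-2 20 10.0 500000.0 15000.0
```

Both genomes have the same per-base coverage (G = 10), so CPMT splits the
million evenly; 30 of 1000 sample reads map to the two genomes, so each
genome's CPMM is 5×10⁵ · 30/1000 = 15 000 — `cpmm_to_percent(15000)` = 1.5%
of the community each. The `examples/` directory has one narrative script
per capability (screening with the rescue rule, primer matching, abundance,
biogeography recovery from a planted survey, MCR clustering, and the full
pipeline); each prints its results and a line on what they mean.

A thin CLI wraps the same library:

```bash
diazoscan simulate --seed 9 --outdir work        # synthetic inputs + truths
diazoscan screen --annotations work/annotations.tsv
diazoscan abundance --counts work/counts.tsv \
    --genome-lengths work/genome_lengths.tsv --meta work/sample_meta.tsv
diazoscan run --config pipeline.json             # all stages + manifest
```

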