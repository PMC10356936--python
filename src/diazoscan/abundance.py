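"""Length-normalized genome abundance from read recruitment.

The abundance of a genome i in a sample is expressed on two related scales:

    G_i   = 1000 * C_i / L_i
    CPMT  = 10^6 * G_i / sum_j G_j          (count per million targeted genomes)
    CPMM  = CPMT * mapped_total / total     (count per million microbe genomes)

where C_i is the filtered mapped-read count on genome i, L_i its length in
bp, mapped_total the read count recruited by the whole target genome set in
that sample and total the sample's total read count.  CPMT is TPM-like: it
sums to 10^6 over the target set.  CPMM rescales CPMT by the fraction of
the community the target set recruits, so a CPMM of 1000 corresponds to an
estimated 0.1% of the total microbial community.

Reads count toward C_i only if they pass the alignment filters: >=95%
identity, >=80 bp aligned, and the alignment covering >=80% of the read
length (all thresholds inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEPTH_BANDS = ("shallow", "intermediate", "deep")
FRACTIONS = ("total", "bacterial", "viral")
ARCTIC_LATITUDE = 66.5
DETECTION_CPMM = 1.0


@dataclass(frozen=True)
class AlignmentRecord:
    """One read alignment against one genome."""

    read_id: str
    genome_id: str
    identity: float        # percent, 0..100
    alignment_length: int  # bp
    read_length: int       # bp

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 100:
            raise ValueError(f"identity {self.identity} outside [0, 100]")
        if self.alignment_length > self.read_length:
            raise ValueError("alignment length exceeds read length")


@dataclass
class MappingSummary:
    """Filtered per-sample per-genome read counts plus genome lengths.

    ``counts`` maps (sample_id, genome_id) -> C_i; ``total_reads`` maps
    sample_id -> total read count; ``genome_lengths`` maps genome_id -> L_i
    in bp.
    """

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    total_reads: dict[str, int] = field(default_factory=dict)
    genome_lengths: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative read count")
        if any(length <= 0 for length in self.genome_lengths.values()):
            raise ValueError("non-positive genome length")
        unknown_samples = {s for s, _ in self.counts} - set(self.total_reads)
        if unknown_samples:
            raise ValueError(f"counts for samples without a total read count: "
                             f"{sorted(unknown_samples)}")
        unknown_genomes = {g for _, g in self.counts} - set(self.genome_lengths)
        if unknown_genomes:
            raise ValueError(f"counts for genomes without a length: "
                             f"{sorted(unknown_genomes)}")
        for sample, m in self.mapped_totals().items():
            if m > self.total_reads[sample]:
                raise ValueError(
                    f"sample {sample}: mapped reads {m} exceed total {self.total_reads[sample]}")

    def samples(self) -> list[str]:
        return sorted(self.total_reads)

    def genomes(self) -> list[str]:
        return sorted(self.genome_lengths)

    def mapped_totals(self) -> dict[str, int]:
        """Reads recruited by the whole target genome set, per sample."""
        out: dict[str, int] = {s: 0 for s in self.total_reads}
        for (sample, _), c in self.counts.items():
            out[sample] = out.get(sample, 0) + c
        return out


def filter_alignments(
    records: list[AlignmentRecord],
    sample_id: str,
    min_identity: float = 95.0,
    min_length: int = 80,
    min_fraction: float = 0.8,
) -> dict[tuple[str, str], int]:
    """Count alignments passing the triple filter, per (sample, genome).

    All three thresholds are inclusive.  Records with read length 0 are
    rejected with a warning rather than raising.
    """
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        if rec.read_length == 0:
            log.warning("read %s has zero length; rejected", rec.read_id)
            continue
        if (rec.identity >= min_identity
                and rec.alignment_length >= min_length
                and rec.alignment_length / rec.read_length >= min_fraction):
            key = (sample_id, rec.genome_id)
            counts[key] = counts.get(key, 0) + 1
    return counts


def select_largest_run(runs: dict[str, list[int]]) -> str:
    """Of several sequencing runs for one sample, keep the largest (by bases)."""
    if not runs:
        raise ValueError("no runs supplied")
    return max(sorted(runs), key=lambda r: sum(runs[r]))


def subsample_run(
    read_lengths: list[int],
    cap_bp: int = 5_000_000_000,
    seed: int = 0,
) -> list[int]:
    """Random subsample of a run down to at most ``cap_bp`` total bases.

    Reads are drawn uniformly without replacement until adding the next
    drawn read would exceed the cap; a run already within the cap is
    returned unchanged.  Returns the indices of the retained reads.
    """
    total = sum(read_lengths)
    if total <= cap_bp:
        return list(range(len(read_lengths)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(read_lengths))
    kept, bases = [], 0
    for idx in order:
        if bases + read_lengths[idx] > cap_bp:
            break
        kept.append(int(idx))
        bases += read_lengths[idx]
    return kept


def length_normalize(summary: MappingSummary) -> pd.DataFrame:
    """G_i = 1000 * C_i / L_i for every (sample, genome) pair.

    Returns a long-format frame with columns sample, genome, C, G covering
    the full sample x genome grid (absent counts are 0).
    """
    summary.validate()
    samples, genomes = summary.samples(), summary.genomes()
    rows = []
    for s in samples:
        for g in genomes:
            c = summary.counts.get((s, g), 0)
            rows.append((s, g, c, 1000.0 * c / summary.genome_lengths[g]))
    return pd.DataFrame(rows, columns=["sample", "genome", "C", "G"])


def cpmt(g_values: np.ndarray) -> np.ndarray:
    """CPMT_i = 10^6 * G_i / sum_j G_j for one sample.

    A sample recruiting no reads at all has CPMT undefined by the formula
    (0/0); zeros are emitted by convention.
    """
    g = np.asarray(g_values, dtype=float)
    total = g.sum()
    if total == 0:
        return np.zeros_like(g)
    return 1e6 * g / total


def cpmm(cpmt_values: np.ndarray, mapped_total: int, total_read_count: int) -> np.ndarray:
    """CPMM_i = CPMT_i * mapped_total / total_read_count."""
    if total_read_count < mapped_total:
        raise ValueError(f"mapped reads {mapped_total} exceed total {total_read_count}")
    if mapped_total < 0:
        raise ValueError("negative mapped read count")
    if total_read_count == 0:
        return np.zeros_like(np.asarray(cpmt_values, dtype=float))
    return np.asarray(cpmt_values, dtype=float) * mapped_total / total_read_count


def cpmm_to_percent(value: float) -> float:
    """Community percentage a CPMM value corresponds to (1000 -> 0.1%)."""
    return value / 1e6 * 100.0


def abundance_matrix(summary: MappingSummary) -> pd.DataFrame:
    """Full abundance table: sample, genome, C, G, CPMT, CPMM.

    Within every sample with nonzero recruitment, CPMT sums to 10^6.
    """
    frame = length_normalize(summary)
    mapped = summary.mapped_totals()
    parts = []
    for sample, grp in frame.groupby("sample", sort=True):
        grp = grp.copy()
        grp["CPMT"] = cpmt(grp["G"].to_numpy())
        grp["CPMM"] = cpmm(grp["CPMT"].to_numpy(), mapped[sample],
                           summary.total_reads[sample])
        parts.append(grp)
    return pd.concat(parts, ignore_index=True)


def assign_depth_band(depth_m: float) -> str:
    """Shallow <=200 m, deep >=1000 m, intermediate in between.

    The 200 m boundary belongs to shallow and the 1000 m boundary to deep;
    the intermediate band is the open interval (200, 1000).
    """
    if depth_m <= 200:
        return "shallow"
    if depth_m >= 1000:
        return "deep"
    return "intermediate"


def assign_latitude_band(latitude: float, arctic_min: float = ARCTIC_LATITUDE) -> str:
    """Arctic at or above ``arctic_min`` degrees north, low_latitude below."""
    return "arctic" if latitude >= arctic_min else "low_latitude"


def stratify(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    detection_cpmm: float = DETECTION_CPMM,
    arctic_min: float = ARCTIC_LATITUDE,
) -> pd.DataFrame:
    """Per-genome abundance stratified by size fraction, depth and latitude band.

    ``meta`` needs columns sample, latitude, depth, fraction.  Returns one
    row per (genome, fraction, depth_band, latitude_band) cell with the
    cell's max CPMM, the number of samples with CPMM >= ``detection_cpmm``
    (``n_detected``), and the number of samples in the cell.
    """
    missing = {"sample", "latitude", "depth", "fraction"} - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata lacks columns: {sorted(missing)}")
    bad = set(meta["fraction"]) - set(FRACTIONS)
    if bad:
        raise ValueError(f"unknown size fractions: {sorted(bad)}")
    meta = meta.copy()
    meta["depth_band"] = meta["depth"].map(assign_depth_band)
    meta["latitude_band"] = meta["latitude"].map(
        lambda lat: assign_latitude_band(lat, arctic_min))
    merged = matrix.merge(
        meta[["sample", "fraction", "depth_band", "latitude_band"]], on="sample")
    grouped = (
        merged.groupby(["genome", "fraction", "depth_band", "latitude_band"], sort=True)
        .agg(max_cpmm=("CPMM", "max"),
             n_detected=("CPMM", lambda v: int((v >= detection_cpmm).sum())),
             n_samples=("CPMM", "size"))
        .reset_index()
    )
    return grouped
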