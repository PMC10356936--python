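"""Synthetic fixtures for the whole pipeline: genomes, surveys, primers, KOs.

Every generator here emits its own truth table alongside the data, so the
downstream modules can be checked against planted ground truth: annotated
genomes with controllable nif content (including a contig-truncated
nifHD case), nifH nucleotide sequences with and without primer binding
sites, a stratified global survey of read counts with planted
Arctic-endemic / cosmopolitan / low-latitude-endemic abundance archetypes,
and per-genome KO sets with known module completion.

Counts in the survey are negative-binomial around archetype-driven means
(Poisson-like at overdispersion 0, exactly the rounded means at noise 0),
the simplest model reproducing sparse metagenomic read recruitment.  All
randomness flows from the single config seed through named substreams, so
each generator is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nif_screen import DEFAULT_MARKER_MAP, NIF_GENES, GeneRecord, GenomeAnnotation
from .primer_match import IUPAC_EXPANSION, PrimerSet
from .mcr import ModuleDefinition, parse_module

ARCHETYPES = ("arctic_endemic", "cosmopolitan", "low_latitude_endemic", "absent")

DEFAULT_LATITUDE_BANDS = (("arctic", (66.5, 90.0)), ("low_latitude", (-65.0, 66.0)))
DEFAULT_DEPTH_BANDS = (("shallow", (5.0, 200.0)), ("intermediate", (250.0, 950.0)),
                       ("deep", (1000.0, 4000.0)))
DEFAULT_FRACTIONS = ("total", "bacterial", "viral")

#: A degenerate pair in the style of universal nifH primers (data, not dogma).
DEFAULT_PRIMER_SET = PrimerSet(
    set_id="nifH_synth",
    forward="TGYGAYCCNAARGCNGA",
    reverse="ADNGCCATCATYTCNCC",
    amplicon_bounds=(200, 500),
)

_STREAMS = {"genomes": 1, "survey": 2, "primers": 3, "kos": 4}


class ConfigurationError(ValueError):
    """A simulation request that contradicts itself or its bands."""


@dataclass(frozen=True)
class NifProfile:
    """Requested nif content of one synthetic genome.

    ``fragmented`` plants nifH and nifD as the last two genes of a contig in
    operon order with nifK absent — the assembly-truncation case the rescue
    rule exists for.  Requesting nifK together with fragmentation is
    contradictory.
    """

    genome_id: str
    genes: frozenset[str]
    fragmented: bool = False
    n_decoys: int = 20

    def __post_init__(self) -> None:
        unknown = self.genes - set(NIF_GENES)
        if unknown:
            raise ConfigurationError(
                f"{self.genome_id}: unknown nif genes {sorted(unknown)}")
        if self.fragmented:
            if "nifK" in self.genes:
                raise ConfigurationError(
                    f"{self.genome_id}: fragmented operon profile cannot request nifK")
            if not {"nifH", "nifD"} <= self.genes:
                raise ConfigurationError(
                    f"{self.genome_id}: fragmented operon needs nifH and nifD")

    def expected_verdict(self) -> str:
        missing = [g for g in NIF_GENES if g not in self.genes]
        if not missing:
            return "diazotroph"
        if missing == ["nifK"] and self.fragmented:
            return "diazotroph_rescued"
        return "non_diazotroph"


@dataclass
class SimulationConfig:
    """Study design of one synthetic run.

    Defaults emulate a polar survey at desk scale: 40 genomes observed over
    120 samples stratified across two latitude bands, three depth bands and
    three size fractions, with negative-binomial count noise.
    """

    seed: int = 0
    n_genomes: int = 40
    n_samples: int = 120
    nif_profiles: list[NifProfile] | None = None
    latitude_bands: tuple = DEFAULT_LATITUDE_BANDS
    depth_bands: tuple = DEFAULT_DEPTH_BANDS
    fractions: tuple = DEFAULT_FRACTIONS
    archetype_assignments: dict[str, str] | None = None
    mean_depth_of_coverage: float = 2.0
    noise: float = 0.5
    read_length: int = 100
    total_reads_per_sample: int = 10_000_000

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ConfigurationError("noise (overdispersion) must be >= 0")
        if self.mean_depth_of_coverage <= 0:
            raise ConfigurationError("mean depth of coverage must be positive")
        for label, (lo, hi) in self.latitude_bands:
            if lo >= hi or abs(lo) > 90 or abs(hi) > 90:
                raise ConfigurationError(f"bad latitude band {label}: {(lo, hi)}")
        for (l1, r1), (l2, r2) in zip(self.latitude_bands, self.latitude_bands[1:]):
            if max(r1[0], r2[0]) < min(r1[1], r2[1]):
                raise ConfigurationError(f"latitude bands {l1} and {l2} overlap")

    def genome_ids(self) -> list[str]:
        if self.nif_profiles is not None:
            return [p.genome_id for p in self.nif_profiles]
        return [f"SG{i:03d}" for i in range(self.n_genomes)]


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[stream],)))


def default_profiles(config: SimulationConfig) -> list[NifProfile]:
    """One profile per genome cycling through the screening-relevant cases."""
    cases = [
        (frozenset(NIF_GENES), False),                                  # complete
        (frozenset(NIF_GENES) - {"nifK"}, True),                        # truncated operon
        (frozenset({"nifH"}), False),                                   # nifH only
        (frozenset(NIF_GENES) - {"nifB"}, False),                       # no nifB
        (frozenset(NIF_GENES), False),
        (frozenset(NIF_GENES) - {"nifK"}, False),                       # nifK truly absent
    ]
    return [NifProfile(genome_id=gid, genes=cases[i % len(cases)][0],
                       fragmented=cases[i % len(cases)][1])
            for i, gid in enumerate(config.genome_ids())]


_GENE_LEN = 900
_SPACER = 120
_DECOY_ACCESSIONS = tuple(f"PF{i:05d}" for i in range(1, 9))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def make_genomes(
    config: SimulationConfig,
) -> tuple[list[GenomeAnnotation], dict[str, dict[str, str]], pd.DataFrame]:
    """Annotated genomes with the requested nif content.

    Returns (annotations, contig sequences per genome, truth table with the
    verdict the screen must reproduce).  Fragmented profiles place nifH and
    nifD as the last two genes of their contig, in operon order.
    """
    rng = _rng(config, "genomes")
    profiles = config.nif_profiles or default_profiles(config)
    genomes, sequences, truth_rows = [], {}, []
    for profile in profiles:
        nif_genes = [g for g in NIF_GENES if g in profile.genes]
        decoys = [f"decoy{i}" for i in range(profile.n_decoys)]
        if profile.fragmented:
            operon = [g for g in nif_genes if g in ("nifH", "nifD")]
            contig1 = decoys[: profile.n_decoys // 2] + operon  # nifH,nifD terminal
            contig2 = [g for g in nif_genes if g not in ("nifH", "nifD")] \
                + decoys[profile.n_decoys // 2:]
        else:
            half = profile.n_decoys // 2
            contig1 = decoys[:half] + nif_genes + decoys[half:half + half // 2]
            contig2 = decoys[half + half // 2:]
        genes, contig_lengths, contig_seqs = [], {}, {}
        for c_idx, layout in enumerate(filter(None, [contig1, contig2])):
            contig_id = f"{profile.genome_id}_c{c_idx}"
            pos, rank = 1 + _SPACER, 0
            for label in layout:
                start, end = pos, pos + _GENE_LEN - 1
                if label.startswith("decoy"):
                    acc = _DECOY_ACCESSIONS[rng.integers(0, len(_DECOY_ACCESSIONS))]
                else:
                    acc = sorted(DEFAULT_MARKER_MAP[label])[0]
                hits = ((acc, 10.0 ** -float(rng.uniform(10, 40))),)
                genes.append(GeneRecord(
                    gene_id=f"{profile.genome_id}_{label}", genome_id=profile.genome_id,
                    contig_id=contig_id, start=start, end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    rank_on_contig=rank, hits=hits))
                pos = end + 1 + _SPACER
                rank += 1
            contig_lengths[contig_id] = pos - 1
            contig_seqs[contig_id] = _random_seq(rng, pos - 1)
        genomes.append(GenomeAnnotation(genome_id=profile.genome_id,
                                        contig_lengths=contig_lengths, genes=genes))
        sequences[profile.genome_id] = contig_seqs
        truth_rows.append((profile.genome_id, ";".join(nif_genes),
                           profile.fragmented, profile.expected_verdict()))
    truth = pd.DataFrame(truth_rows,
                         columns=["genome", "nif_genes", "fragmented", "verdict"])
    return genomes, sequences, truth


# ---------------------------------------------------------------- survey

def default_archetypes(config: SimulationConfig) -> dict[str, str]:
    """Round-robin archetype assignment over the genome ids."""
    return {gid: ARCHETYPES[i % len(ARCHETYPES)]
            for i, gid in enumerate(config.genome_ids())}


def _sample_grid(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    combos = [(lb, db, fr)
              for lb, _ in config.latitude_bands
              for db, _ in config.depth_bands
              for fr in config.fractions]
    lat_ranges = dict(config.latitude_bands)
    depth_ranges = dict(config.depth_bands)
    rows = []
    for i in range(config.n_samples):
        lb, db, fr = combos[i % len(combos)]
        lat = rng.uniform(*lat_ranges[lb])
        depth = rng.uniform(*depth_ranges[db])
        rows.append((f"S{i:04d}", round(float(lat), 3), round(float(rng.uniform(-180, 180)), 3),
                     round(float(depth), 1), fr, lb, db))
    return pd.DataFrame(rows, columns=["sample", "latitude", "longitude", "depth",
                                       "fraction", "latitude_band", "depth_band"])


def _active(archetype: str, latitude_band: str, depth_band: str) -> bool:
    if archetype == "arctic_endemic":
        return latitude_band == "arctic"
    if archetype == "cosmopolitan":
        return latitude_band == "arctic" or depth_band == "deep"
    if archetype == "low_latitude_endemic":
        return latitude_band != "arctic" and depth_band == "shallow"
    return False


def make_survey(
    config: SimulationConfig,
    genomes: list[GenomeAnnotation],
) -> tuple["MappingSummary", pd.DataFrame, pd.DataFrame]:
    """Stratified survey of read counts with planted biogeographic archetypes.

    Returns (mapping summary, sample metadata, truth table mapping each
    genome to its planted archetype).  Counts are negative-binomial with
    mean = coverage x genome length / read length in active samples and 0
    elsewhere; at noise 0 the counts equal the rounded means.
    """
    from .abundance import MappingSummary

    rng = _rng(config, "survey")
    assignments = config.archetype_assignments or default_archetypes(config)
    ids = {g.genome_id for g in genomes}
    missing = set(assignments) - ids | ids - set(assignments)
    if missing:
        raise ConfigurationError(f"archetype assignment incomplete for: {sorted(missing)}")
    bad = set(assignments.values()) - set(ARCHETYPES)
    if bad:
        raise ConfigurationError(f"unknown archetypes: {sorted(bad)}")

    meta = _sample_grid(config, rng)
    needed = {
        "arctic_endemic": meta["latitude_band"].eq("arctic").any(),
        "cosmopolitan": (meta["latitude_band"].eq("arctic").any()
                         and ((meta["latitude_band"] != "arctic")
                              & (meta["depth_band"] == "deep")).any()),
        "low_latitude_endemic": ((meta["latitude_band"] != "arctic")
                                 & (meta["depth_band"] == "shallow")).any(),
        "absent": True,
    }
    for gid, arch in assignments.items():
        if not needed[arch]:
            raise ConfigurationError(
                f"{gid}: archetype {arch} requires samples the band design lacks")

    summary = MappingSummary(
        genome_lengths={g.genome_id: g.genome_length for g in genomes})
    for row in meta.itertuples():
        summary.total_reads[row.sample] = config.total_reads_per_sample
        for genome in genomes:
            arch = assignments[genome.genome_id]
            if not _active(arch, row.latitude_band, row.depth_band):
                continue
            mu = (config.mean_depth_of_coverage * genome.genome_length
                  / config.read_length)
            if config.noise == 0:
                count = int(round(mu))
            else:
                n = 1.0 / config.noise
                count = int(rng.negative_binomial(n, n / (n + mu)))
            if count > 0:
                summary.counts[(row.sample, genome.genome_id)] = count
    truth = pd.DataFrame(
        sorted(assignments.items()), columns=["genome", "archetype"])
    truth["expected_pattern"] = truth["archetype"].map(
        lambda a: "undetermined" if a == "absent" else a)
    return summary, meta.drop(columns=["latitude_band", "depth_band"]), truth


# ---------------------------------------------------------------- primers

def _realize(rng: np.random.Generator, primer: str) -> str:
    """One concrete sequence drawn from a degenerate primer's expansion."""
    return "".join(sorted(IUPAC_EXPANSION[c])[rng.integers(0, len(IUPAC_EXPANSION[c]))]
                   for c in primer.upper())


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = sorted(set("ACGT") - {out[p]})[rng.integers(0, 3)]
    return "".join(out)


def make_primer_targets(
    config: SimulationConfig,
    primer_set: PrimerSet = DEFAULT_PRIMER_SET,
    n_targets: int = 20,
    target_length: int = 360,
    n_mismatches: int = 3,
) -> tuple[dict[str, str], pd.DataFrame]:
    """nifH-like nucleotide targets, half with exact primer binding sites.

    Even-indexed targets embed an exact forward site and a convergent
    reverse site within the amplicon bounds; odd-indexed targets embed both
    sites with ``n_mismatches`` substitutions each.  Returns (sequences,
    truth table of expected strict-match compatibility).
    """
    from Bio.Seq import reverse_complement

    rng = _rng(config, "primers")
    f_len, r_len = len(primer_set.forward), len(primer_set.reverse)
    lo, hi = primer_set.amplicon_bounds
    if max(f_len, r_len) > target_length or lo > target_length:
        raise ConfigurationError(
            f"primer/amplicon ({max(f_len, r_len, lo)} bp) longer than "
            f"target ({target_length} bp)")
    sequences, rows = {}, []
    for i in range(n_targets):
        name = f"T{i:03d}"
        background = _random_seq(rng, target_length)
        fwd = _realize(rng, primer_set.forward)
        rev_site = reverse_complement(_realize(rng, primer_set.reverse))
        exact = i % 2 == 0
        if not exact:
            fwd = _mutate(rng, fwd, n_mismatches)
            rev_site = _mutate(rng, rev_site, n_mismatches)
        amplicon = int(rng.integers(max(lo, f_len + r_len + 10),
                                    min(hi, target_length) + 1))
        f_start = int(rng.integers(0, target_length - amplicon + 1))
        r_start = f_start + amplicon - r_len
        seq = (background[:f_start] + fwd
               + background[f_start + f_len: r_start]
               + rev_site + background[r_start + r_len:])
        sequences[name] = seq
        rows.append((name, exact, f_start, r_start, amplicon))
    truth = pd.DataFrame(rows, columns=["target", "compatible",
                                        "forward_pos", "reverse_pos", "amplicon"])
    return sequences, truth


# ---------------------------------------------------------------- KO sets

def default_modules(n_modules: int = 8, max_kos: int = 6) -> dict[str, ModuleDefinition]:
    """Small synthetic module catalog: plain AND chains of distinct KOs.

    AND-only definitions make the planted completion exactly
    100 * (#planted KOs) / (#KOs), independent of evaluator semantics.
    """
    modules = {}
    ko_counter = 0
    for m in range(n_modules):
        n_kos = 3 + m % (max_kos - 2)
        kos = [f"K{ko_counter + k:05d}" for k in range(n_kos)]
        ko_counter += n_kos
        mid = f"M9{m:04d}"
        modules[mid] = parse_module(" ".join(kos), mid)
    return modules


def make_ko_sets(
    config: SimulationConfig,
    modules: dict[str, ModuleDefinition] | None = None,
) -> tuple[dict[str, set[str]], dict[str, ModuleDefinition], pd.DataFrame]:
    """Per-genome KO sets with planted module completion.

    For each genome and AND-chain module a completion level is drawn and
    exactly that share of the module's KOs is planted, so the truth table's
    MCR is arithmetic, not evaluator output.  Decoy KOs are added to every
    genome.  Returns (ko_sets, modules, truth table genome/module/mcr).
    """
    rng = _rng(config, "kos")
    modules = modules or default_modules()
    rows, ko_sets = [], {}
    for gid in config.genome_ids():
        kos: set[str] = {f"Kdecoy{j}" for j in range(5)}
        for mid in sorted(modules):
            leaves = sorted(modules[mid].expression.required_leaves())
            n_plant = int(rng.integers(0, len(leaves) + 1))
            planted = sorted(rng.choice(leaves, size=n_plant, replace=False))
            kos.update(planted)
            rows.append((gid, mid, 100.0 * n_plant / len(leaves)))
        ko_sets[gid] = kos
    truth = pd.DataFrame(rows, columns=["genome", "module", "mcr"])
    return ko_sets, modules, truth
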