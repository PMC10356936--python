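"""Distribution-pattern classification of genomes from stratified abundance.

Marine diazotrophs broadly split into genomes found almost exclusively in
the Arctic Ocean (Arctic-endemic) and genomes found both in the Arctic and
at lower latitudes (cosmopolitan) — where the low-latitude occurrence is
often in deep water, whose temperature is uniformly low.  A third archetype
occurs only outside the Arctic.  The published dichotomy rests on visual
inspection of abundance maps; the formal rule here (detection threshold,
minimum positive samples, Arctic latitude bound, endemicity slack) is this
module's contribution and every part of it is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)

PATTERNS = ("arctic_endemic", "cosmopolitan", "low_latitude_endemic", "undetermined")


@dataclass(frozen=True)
class ClassificationRules:
    """Tunable thresholds behind the endemic/cosmopolitan dichotomy.

    ``min_samples``: samples with CPMM >= the detection threshold a band
    needs before the genome counts as detected there.  ``endemicity_slack``:
    stray detections tolerated in the opposite band before endemicity is
    broken ("almost exclusively" — 0 means strictly exclusive).
    """

    min_samples: int = 2
    endemicity_slack: int = 0


@dataclass
class BiogeographyCall:
    genome_id: str
    pattern: str
    detections: dict[str, int] = field(default_factory=dict)  # latitude band -> n_detected
    max_cpmm: dict[str, float] = field(default_factory=dict)  # latitude band -> max CPMM
    warnings: list[str] = field(default_factory=list)


def classify_biogeography(
    stratified: pd.DataFrame,
    rules: ClassificationRules | None = None,
) -> list[BiogeographyCall]:
    """Assign each genome one distribution pattern from the stratified table.

    ``stratified`` is the output of :func:`diazoscan.abundance.stratify`
    (columns genome, fraction, depth_band, latitude_band, max_cpmm,
    n_detected, n_samples).  A genome is detected in a latitude band when
    its positive samples there (any fraction, any depth) reach
    ``rules.min_samples``; arctic_endemic = detected in the Arctic band and
    nowhere else (up to the slack), cosmopolitan = detected in the Arctic
    band and in >=1 non-Arctic band (deep-water occurrence counts),
    low_latitude_endemic = detected only outside the Arctic, undetermined
    otherwise.
    """
    rules = rules or ClassificationRules()
    bands_present = set(stratified["latitude_band"])
    coverage_warning = []
    if "arctic" not in bands_present or (bands_present - {"arctic"}) == set():
        coverage_warning.append(
            "survey does not cover both Arctic and non-Arctic samples; "
            "calls limited to the covered bands")
        log.warning(coverage_warning[0])
    calls = []
    for genome, grp in stratified.groupby("genome", sort=True):
        per_band = grp.groupby("latitude_band").agg(
            n_detected=("n_detected", "sum"), max_cpmm=("max_cpmm", "max"))
        detections = per_band["n_detected"].to_dict()
        arctic_hits = detections.get("arctic", 0)
        other_hits = sum(v for band, v in detections.items() if band != "arctic")
        in_arctic = arctic_hits >= rules.min_samples
        in_other = other_hits >= rules.min_samples
        if in_arctic and (not in_other) and other_hits <= rules.endemicity_slack:
            pattern = "arctic_endemic"
        elif in_arctic and in_other:
            pattern = "cosmopolitan"
        elif (not in_arctic) and in_other and arctic_hits <= rules.endemicity_slack:
            pattern = "low_latitude_endemic"
        else:
            pattern = "undetermined"
        calls.append(BiogeographyCall(
            genome_id=genome,
            pattern=pattern,
            detections={str(k): int(v) for k, v in detections.items()},
            max_cpmm={str(k): float(v) for k, v in per_band["max_cpmm"].to_dict().items()},
            warnings=list(coverage_warning),
        ))
    return calls


def fraction_profile(stratified: pd.DataFrame, ratio: float = 10.0) -> pd.DataFrame:
    """Dominant size fraction per genome with a lifestyle note.

    A genome whose viral-fraction (<0.2 µm) maximum CPMM exceeds its maxima
    in the other fractions by >= ``ratio`` is flagged "sub-0.2 µm enriched"
    (cells small enough to pass a 0.2 µm filter); one whose total-fraction
    (>=0.2 µm) maximum similarly exceeds the bacterial fraction (0.2-3 µm)
    is flagged ">3 µm/particle-associated" (large cells, aggregates, or
    host-associated lifestyles removed by the 3 µm prefilter).
    """
    rows = []
    for genome, grp in stratified.groupby("genome", sort=True):
        maxima = grp.groupby("fraction")["max_cpmm"].max().to_dict()
        viral = maxima.get("viral", 0.0)
        total = maxima.get("total", 0.0)
        bacterial = maxima.get("bacterial", 0.0)
        note = ""
        others = max(total, bacterial)
        if viral > 0 and viral >= ratio * max(others, 1e-12) and viral > others:
            note = "sub-0.2 um enriched"
        elif total > 0 and total >= ratio * max(bacterial, 1e-12) and total > bacterial:
            note = ">3 um/particle-associated"
        dominant = max(maxima, key=lambda f: (maxima[f], f)) if maxima else ""
        rows.append((genome, dominant, viral, total, bacterial, note))
    return pd.DataFrame(
        rows, columns=["genome", "dominant_fraction", "max_cpmm_viral",
                       "max_cpmm_total", "max_cpmm_bacterial", "lifestyle_note"])
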