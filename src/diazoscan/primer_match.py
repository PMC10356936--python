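"""In-silico PCR compatibility of degenerate nifH primers.

Universal nifH primer sets are written with IUPAC ambiguity codes.  A target
nucleotide sequence is "detectable" by a set when a forward-primer site on
the plus strand and a reverse-primer site on the minus strand face each
other in convergent orientation with a plausible amplicon length between
them.  Nested sets (an outer pair plus an inner pair) require both pairs to
be compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

#: IUPAC code -> set of concrete bases it stands for (T covers U inputs upstream).
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}

DEFAULT_AMPLICON_BOUNDS = (200, 500)  # plausible nifH amplicon span, bp


@dataclass(frozen=True)
class PrimerSet:
    """A degenerate primer pair, optionally part of a nested design."""

    set_id: str
    forward: str
    reverse: str
    nested_partner: str | None = None
    amplicon_bounds: tuple[int, int] = DEFAULT_AMPLICON_BOUNDS

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            bad = [c for c in seq.upper() if c not in IUPAC_EXPANSION]
            if bad:
                raise ValueError(f"primer set {self.set_id}: non-IUPAC characters {bad}")
        lo, hi = self.amplicon_bounds
        if lo > hi:
            raise ValueError(f"primer set {self.set_id}: amplicon bounds {lo} > {hi}")


@dataclass
class PrimerMatchReport:
    """Evidence for one target sequence against a collection of primer sets."""

    target_id: str
    sites: dict[str, list[tuple[int, str, int]]] = field(default_factory=dict)
    set_compatible: dict[str, bool] = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return any(self.set_compatible.values())


def iupac_matches(code: str, base: str) -> bool:
    """True iff ``base`` is in the expansion of IUPAC ``code``.

    The comparison is primer-code vs concrete target base; an ambiguous
    base in the target (e.g. N) never matches, because it carries no
    evidence of a binding site.
    """
    expansion = IUPAC_EXPANSION.get(code.upper())
    if expansion is None:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}")
    return base.upper() in expansion


def _window_mismatches(primer: str, window: str, limit: int) -> int | None:
    """Mismatch count of primer vs window, or None once it exceeds limit."""
    n = 0
    for code, base in zip(primer, window):
        if base not in IUPAC_EXPANSION.get(code, ()):  # target N etc. counts as mismatch
            n += 1
            if n > limit:
                return None
    return n


def find_sites(primer: str, target: str, max_mismatch: int = 0) -> list[tuple[int, str, int]]:
    """All binding sites of a degenerate primer on both strands of a target.

    Returns (position, strand, mismatches) triples; positions are 0-based
    offsets of the site's leftmost base on the forward strand, for both
    strands.  A site is any window whose IUPAC mismatch count is
    <= ``max_mismatch``.
    """
    primer = primer.upper()
    target = target.upper()
    bad = [c for c in primer if c not in IUPAC_EXPANSION]
    if bad:
        raise ValueError(f"non-IUPAC characters in primer: {bad}")
    if len(primer) > len(target):
        raise ValueError(f"primer ({len(primer)} bp) longer than target ({len(target)} bp)")
    span = len(primer)
    rc_target = reverse_complement(target)
    sites: list[tuple[int, str, int]] = []
    for offset in range(len(target) - span + 1):
        mm = _window_mismatches(primer, target[offset:offset + span], max_mismatch)
        if mm is not None:
            sites.append((offset, "+", mm))
        mm = _window_mismatches(primer, rc_target[offset:offset + span], max_mismatch)
        if mm is not None:
            # map the rc-strand window back to forward-strand coordinates
            sites.append((len(target) - span - offset, "-", mm))
    return sorted(sites)


def set_compatible(
    target: str,
    primer_set: PrimerSet,
    max_mismatch: int = 0,
    all_sets: dict[str, PrimerSet] | None = None,
) -> tuple[bool, dict[str, list[tuple[int, str, int]]]]:
    """Decide detectability of a target by one primer set, with evidence.

    Compatible iff a forward site on the + strand has a reverse site on the
    - strand downstream of it with the amplicon span (outer edge to outer
    edge) within the set's bounds.  If the set names a nested partner and
    ``all_sets`` provides it, the partner pair must be compatible too.
    """
    fwd_sites = [s for s in find_sites(primer_set.forward, target, max_mismatch) if s[1] == "+"]
    rev_sites = [s for s in find_sites(primer_set.reverse, target, max_mismatch) if s[1] == "-"]
    evidence = {f"{primer_set.set_id}.forward": fwd_sites,
                f"{primer_set.set_id}.reverse": rev_sites}
    lo, hi = primer_set.amplicon_bounds
    ok = False
    for fpos, _, _ in fwd_sites:
        for rpos, _, _ in rev_sites:
            if rpos <= fpos:
                continue  # divergent or overlapping-upstream orientation
            amplicon = rpos + len(primer_set.reverse) - fpos
            if lo <= amplicon <= hi:
                ok = True
    if ok and primer_set.nested_partner and all_sets:
        partner = all_sets.get(primer_set.nested_partner)
        if partner is not None:
            ok_partner, ev = set_compatible(target, partner, max_mismatch)
            evidence.update(ev)
            ok = ok and ok_partner
    return ok, evidence


def match_report(
    target_id: str,
    target: str,
    primer_sets: list[PrimerSet],
    max_mismatch: int = 0,
) -> PrimerMatchReport:
    """Evaluate every primer set against one target."""
    by_id = {s.set_id: s for s in primer_sets}
    report = PrimerMatchReport(target_id=target_id)
    for pset in primer_sets:
        ok, evidence = set_compatible(target, pset, max_mismatch, by_id)
        report.set_compatible[pset.set_id] = ok
        report.sites.update(evidence)
    return report
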