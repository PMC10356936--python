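# Methods

## Diazotroph screening

A gene's *functional call* is its best HMM hit: the lowest e-value among
the gene's hits, required to be strictly below the cutoff (default 1e−5).
*nifH* is identified by TIGR01287; the other five nif genes default to the
corresponding TIGRFAM models (nifD TIGR01282, nifK TIGR01286, nifE
TIGR01283, nifN TIGR01285, nifB TIGR01290) but the whole marker map is
user-supplied data — different HMM libraries assign different accessions,
and nothing in the method depends on the defaults. A tie between a nif
marker and another marker at the same e-value resolves toward the nif
marker with a logged warning; exact ties are pathological with real HMM
scores. Genes on either strand qualify; operon orientation is not checked.

Verdicts: `diazotroph` when all six genes are present; `diazotroph_rescued`
when the missing set is exactly {*nifK*} and the gene carrying the *nifD*
hit lies within `edge_rank` genes of either end of its contig (default 1,
i.e. strictly first or last); otherwise `non_diazotroph`. The rescue is
purely structural — it encodes the observation that *nifHDK* form an operon,
so a contig ending right after *nifD* plausibly truncated *nifK*. It is
deliberately conservative: it never applies to any missing gene but *nifK*,
and `rescue_applied ⇒ missing == {nifK}` is an enforced invariant.

*nifH* cluster assignment uses best ungapped local identity: the maximum
over all relative offsets of (#matching positions in the overlap) divided
by the shorter sequence's length. This is a deliberate simplification —
canonical nifH clusters are deep phylogenetic groups and any sane identity
measure separates them; the floor below which a query is `unassigned`
defaults to 60%.

## Primer matching

IUPAC expansion comes from Biopython's ambiguity table. The comparison is
asymmetric: a degenerate code in the *primer* matches any base of its
expansion, but an ambiguous base in the *target* (N etc.) never matches,
because an N carries no evidence of a binding site. A primer set is
compatible with a target iff a forward site on the plus strand has a
reverse site on the minus strand downstream of it with the outer-edge to
outer-edge span inside the amplicon bounds; nested designs additionally
require the partner pair. Defaults: `max_mismatch = 0` (strict
detectable/not-detectable dichotomy) and amplicon bounds (200, 500) bp,
which bracket the common *nifH* amplicons; both are parameters, not claims.

## Abundance

The three-stage statistic G → CPMT → CPMM is computed exactly as defined
(see README). Numerical conventions: all three alignment-filter thresholds
are inclusive; a sample in which no target genome recruits any read has
CPMT formally 0/0 and is emitted as all zeros rather than an error; CPMT
sums to 10⁶ per recruiting sample to ~1e−16 relative in practice (the
tested tolerance is 1e−6). Aligned fraction uses the full read length (the
choice for clipped/paired reads is not standardised; full length is the
stricter reading). Depth bands are printed with overlapping endpoints
(≤200, 200–1000, ≥1000 m) — here 200 m belongs to shallow and 1000 m to
deep, making the intermediate band the open interval. Run handling: of
multiple sequencing runs per sample only the largest (by total bases) is
used, and runs over 5 Gbp are uniformly subsampled without replacement
until the next read would exceed the cap.

## Biogeography

The endemic/cosmopolitan dichotomy is made operational with three
parameters, all configurable and recorded in the output: detection means
CPMM ≥ 1 (the same threshold used for plotting detections) in at least
`min_samples = 2` samples of a latitude band, pooled over fractions and
depths; Arctic = latitude ≥ 66.5°N (the Arctic Circle — the source
analyses never define "Arctic" numerically); `endemicity_slack = 0` stray
detections tolerated in the opposite band ("almost exclusively" read
strictly). Cosmopolitan requires detection in the Arctic *and* a non-Arctic
band, where deep (≥1000 m) low-latitude water counts — deep water is
uniformly cold, so cold-adapted genomes plausibly occur there. Missing
coverage of a band degrades calls to `undetermined` with a warning, never
an error. Raising the detection threshold can move genomes only toward
`undetermined`, not between endemic classes.

The fraction profile labels a genome "sub-0.2 µm enriched" when its
viral-fraction maximum CPMM exceeds its other-fraction maxima ≥10-fold
(cells passing a 0.2 µm filter), and ">3 µm/particle-associated" for the
analogous total-vs-bacterial excess (large, aggregated or host-associated
cells removed by a 3 µm prefilter). The factor 10 separates the planted
archetypes by orders of magnitude and is a display heuristic, not a test
statistic.

## Traits

IVYWREL is pooled over the proteome — total IVYWREL residues over total
canonical residues — not averaged per protein; pooling matches a
composition fraction "relative to the overall amino acid composition" and
is invariant to how the proteome is split into records. X, stops and other
non-canonical symbols are excluded from the denominator. Codon usage is
the 64-vector of relative codon frequencies (trailing partial codons
dropped with a warning, ambiguous codons skipped); ordination is a centred
PCA via SVD with a deterministic sign convention (the largest-magnitude
loading of each component is made positive) so results are reproducible
across BLAS implementations and input orderings. Trait hit significance
inherits the screening e-value cutoff for consistency. Gene-family and
cold-gene accession sets (which Pfam/KO ids constitute "glycosyltransferase"
or "cspA") are data supplied by the user, not code.

## Module completion ratio

Module definitions are parsed by a recursive-descent parser: space = AND,
comma = OR, `+` = complex subunit, `-` prefix = optional, parentheses
group; KO tokens are `K\d{5}` or any alphanumeric id (synthetic tests use
free-form ids). The completion score is recursive: LEAF ∈ {0,1}, OR = max,
AND and COMPLEX = arithmetic mean over non-optional children, OPTIONAL
excluded from every denominator; a module with no required components
scores 0 with a warning. Mean (not min) is the interpretation of
"completion ratio" — min would collapse every partially encoded pathway to
0 — and the whole semantics is isolated in one function so an alternative
recursion can be substituted. The working-probability (Q-value) statistic
of the reference implementation is out of scope: it needs cross-taxon
ortholog statistics that are not published.

Clustering: modules at 0% in every genome are removed (they carry no
signal and would only compress distances), genomes are ordered
lexicographically for deterministic tie-breaking, and complete-linkage
agglomeration runs on pairwise Euclidean distances (scipy); the dendrogram
serializes to newick. An independent O(n³) agglomerator exists in the test
suite as the oracle.

## Synthetic data

The generators emulate, at desk scale, a polar MAG survey: default 40
genomes × 120 samples, stratified round-robin over two latitude bands
(Arctic ≥66.5°N; low-latitude drawn from −65° to 66° to avoid boundary
ambiguity), three depth bands (drawn from 5–200, 250–950, 1000–4000 m)
and three size fractions. Read counts are negative-binomial with mean =
coverage × genome length / read length (defaults 2×, 100 bp) in samples
where a genome's archetype is active and exactly zero elsewhere;
`noise` is the overdispersion (variance = μ + noise·μ²), 0.5 by default as
a moderately overdispersed regime typical of recruitment counts, with
noise = 0 giving the rounded means for exact downstream checks. Every
generator emits its own truth table (screening verdicts, primer
compatibility, archetypes, planted MCR), and all randomness flows from the
single config seed through named substreams, so outputs are byte-identical
for identical configs.

What the generator does *not* emulate: real community composition,
taxonomic covariance between genomes, spatial autocorrelation of samples,
mapping ambiguity between related genomes, or chimeric/contaminated bins.
Passing the planted-truth round trips therefore shows the *logic* of the
pipeline is correct under the stated model, not that the thresholds are
optimal for real ocean data.

Planted KO sets use AND-chain modules only, so the planted completion is
plain arithmetic (100·k/n) independent of the evaluator; modules with
OR/complex structure are checked against the independent recursive oracle
instead.

## Problem sizes and determinism

Test and acceptance runs use 9–40 genomes, 36–120 samples, 200–500 random
oracle cases and 10-genome clustering instances; these sizes make every
planted signal unambiguous while keeping the full suite and the
acceptance script each well under a minute. Pipeline manifests contain
versions, thresholds, seeds and per-stage summaries but no timestamps or
absolute paths, and every output file carries a hash of its configuration,
so same-config runs are byte-identical and verifiably so.

## Known limitations

- The rescue rule trusts contig structure; a genuinely *nifK*-less genome
  whose *nifD* happens to end a contig is rescued incorrectly. External
  corroboration (e.g. an independently binned relative) is out of scope.
- Primer matching is combinatorial only — no melting temperature or
  thermodynamics — so "compatible" means sequence-detectable, not
  guaranteed to amplify.
- CPMM compares genomes within the supplied target set; it is not an
  absolute cell abundance and inherits all read-recruitment biases.
- The biogeography rule reduces a continuous distribution to four classes;
  genomes near the detection threshold flip classes under small threshold
  changes (by design, toward `undetermined`).
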