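"""Test nifH sequences against a degenerate universal primer pair in silico.

Generates 10 nifH-like targets — half carrying exact convergent binding
sites for the primer pair, half carrying sites with 3 mismatches each —
and reports which are detectable under the strict (0-mismatch) rule.
"""

from diazoscan.primer_match import set_compatible
from diazoscan.simulate import DEFAULT_PRIMER_SET, SimulationConfig, make_primer_targets

targets, truth = make_primer_targets(SimulationConfig(seed=2), n_targets=10)
expected = truth.set_index("target")["compatible"]

for name, seq in targets.items():
    ok, _ = set_compatible(seq, DEFAULT_PRIMER_SET, max_mismatch=0)
    print(f"{name}: compatible={ok} (planted: {expected[name]})")
# A target is "compatible" when a forward site and a downstream reverse
# site face each other with an amplicon length inside the set's bounds —
# an incompatible nifH would be invisible to PCR surveys using this pair.
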