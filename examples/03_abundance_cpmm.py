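"""Compute length-normalized genome abundance (G -> CPMT -> CPMM) by hand.

Two genomes recruit reads in one sample; the longer genome needs twice the
reads for the same length-normalized abundance.  CPMT sums to 10^6 over
the target set; CPMM rescales by the fraction of the community the target
set recruits, so CPMM/10^6*100 is an estimated community percentage.
"""

from diazoscan.abundance import MappingSummary, abundance_matrix, cpmm_to_percent

summary = MappingSummary(
    counts={("station-A", "genome-1"): 10, ("station-A", "genome-2"): 20},
    genome_lengths={"genome-1": 1000, "genome-2": 2000},
    total_reads={"station-A": 1000},
)
matrix = abundance_matrix(summary)
print(matrix.to_string(index=False))
for _, row in matrix.iterrows():
    print(f"{row['genome']}: CPMM {row['CPMM']:.0f} "
          f"= {cpmm_to_percent(row['CPMM']):.4f}% of the community")
# Both genomes have G = 10 (equal coverage), so CPMT splits 500000/500000;
# with 30 of 1000 reads mapped, CPMM = 15000 each, i.e. 1.5% of the
# community per genome.
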