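"""Simulate a small cancer/control cfDNA cohort with known ground truth.

Builds a two-contig genome, plants one hypermethylated DMR and one
chromosome-arm gain, draws neutrophil-dominant cell mixtures with tumor
fractions for cases, and writes per-CpG call files plus 100-kb bin counts.
"""

from labs_cfdna import SimulationConfig, simulate_cohort

config = SimulationConfig(
    n_cases=6,
    n_controls=6,
    genome=[("chr1", 1_000_000), ("chr2", 500_000)],
    coverage_mean=30,
    reads_per_sample=200_000,
    dmrs=[("chr1", 400_000, 450_000, 0.4)],
    cna_segments=[("chr1", 600_000, 1_000_000, 3.0)],
    tumor_fraction_range=(0.1, 0.4),
    seed=7,
)
cohort = simulate_cohort(config, out_dir="scratch/example_cohort")

first_case = cohort.truth.samples[0]
print(f"samples written: {len(cohort.calls)}")
print(f"CpG sites per sample: ~{len(cohort.calls[first_case['name']])}")
print(f"{first_case['name']}: tumor fraction {first_case['tumor_fraction']:.3f}, "
      f"neutrophil share {first_case['proportions']['neutrophil']:.3f}")
print("planted truth saved to scratch/example_cohort/truth.json")
# Each case's methylation difference in the planted DMR scales with its own
# tumor fraction (ctDNA dilution); controls carry neither DMRs nor CNAs.
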