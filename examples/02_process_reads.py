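"""Filter and merge paired amplicon reads the way the repertoire pipeline does.

Emits paired reads for a simulated clone (with sequencing errors and a
spiked fraction of low-quality pairs), then applies the filter chain:
median base quality > 32, identical paired-end overlap > 65 bp, local
alignment similarity to V-like reference segments, both primers found and
trimmed length > 240 bp.
"""

from cd5switch import ReadPair, SimulationConfig, assign_cd5_states, emit_reads, process_sample
from cd5switch.simulate import simulate_clone

config = SimulationConfig(seed=7, clone_cells=300, background_clones=30,
                          error_rate=0.001, low_quality_fraction=0.05)
truth = simulate_clone(config)
assign_cd5_states(truth)
records, _abundance = emit_reads(truth)
pairs = [ReadPair(*r) for r in records]

processed, report = process_sample(pairs, config.primer_fwd, config.primer_rev)

print(f"read pairs in: {len(pairs)}")
for stage in report.stages:
    print(f"  {stage['stage']:<13} kept {stage['n_retained']:>5}  "
          f"discarded {stage['n_discarded']:>4}  {stage['reasons']}")
print(f"unique sequences out: {len(processed)}")
print(f"reads out:            {sum(p.read_count for p in processed)}")

# Quality failures track the spiked 5%; merge failures are pairs with an
# error inside the overlap (identity merging takes no consensus); the
# similarity screen removes the random background; primer trimming drops
# reads with an error inside a primer.
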