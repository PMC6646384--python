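"""IS-anchored G4 positional profile with a shuffled-coordinate null.

Simulates a genome whose origins carry G4 motifs planted ~250 bp upstream
of the initiation site, scans it, and recovers the planted offset from
the oriented per-bp coverage profile; a shuffled-IS null band shows what
random placement would look like.
"""

from g4ori import (
    assign_g4_status,
    call_g4_regions,
    peak_offset,
    shuffle_null_band,
    simulate_genome_with_g4,
)

sim = simulate_genome_with_g4(n_chrom=2, chrom_len=1_000_000, origin_count=300, seed=5)
regions = []
for chrom, seq in sim.sequences.items():
    regions += call_g4_regions(seq, seq_id=chrom)
print(f"window-scorer G4 calls genome-wide: {len(regions)}")

status = assign_g4_status(sim.origins, regions)
print(f"G4-positive origins (+/-500 bp of IS): {100 * status.g4_positive.mean():.1f}%")

prof = shuffle_null_band(sim.origins, regions, sim.genome,
                         flank=1000, n_shuffles=200, seed=5)
print(f"profile peak offset: {peak_offset(prof)} bp "
      f"(negative = upstream of the IS)")
print(f"peak fraction {prof.fraction.max():.3f} vs null mean "
      f"{prof.null_mean.mean():.4f}")
print()
print("The sharp peak a few hundred bp upstream of the IS is the planted")
print("G-rich element; the flat null band confirms it is positional, not")
print("a genome-wide density artifact.")
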