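"""Generate the canonical F/M mitogenome pair and inspect its divergence.

Builds the annotated female-type reference (17,428 bp, 12 CDS, 22 tRNAs,
2 rRNAs, 2 non-coding regions), evolves the male-type lineage at a 5.5%
target divergence with rate hotspots, and prints the realized divergence
and structural events. The two headline structural diagnostics are the
127-bp insertion in the M-type 16S rRNA and the 10-residue cox1 extension.
"""
from mitoduo import SynthConfig, make_lineage_pair

pair = make_lineage_pair(SynthConfig(seed=1))

print(f"F genome: {len(pair.genome_f)} bp, {len(pair.genome_f.features)} features")
print(f"M genome: {len(pair.genome_m)} bp")
print(f"substitutions applied: {pair.n_substitutions}")
print(f"realized p-distance:   {pair.realized_divergence:.4f} (target 0.055)")
for e in pair.event_log:
    if e[0] == "ins":
        print(f"insertion: {e[2]} bp in {e[4]} (carrier {e[3]})")
print(f"cox1 protein: F={len(pair.genome_f.protein('cox1'))} aa, "
      f"M={len(pair.genome_m.protein('cox1'))} aa")
# The M cox1 protein is 10 residues longer; the realized p-distance sits
# within binomial noise of the configured 5.5% target.
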