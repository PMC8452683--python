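"""Scan the F/M alignment for diagnostic fixed differences.

Counts alignment columns where the two mitotype groups share no state
(gap included as a fifth state), profiles them in a 500-column sliding
window with step 1, computes the bootstrap p-distance, and localizes the
diagnostic indel. Hotspot features (e.g. 16S, cytb) stand out against
conserved ones (12S, cox2).
"""
from mitoduo import (GroupAlignment, SynthConfig, fixed_difference_columns,
                     locate_indels, make_lineage_pair, p_distance,
                     per_feature_divergence, sliding_window_profile)
from mitoduo.scan import feature_column_spans

pair = make_lineage_pair(SynthConfig(seed=1))
aln = GroupAlignment.from_pair(pair)

positions = fixed_difference_columns(aln)
profile = sliding_window_profile(positions, aln.length, window=500, step=1)
dist = p_distance(pair.aligned_f, pair.aligned_m, bootstrap_reps=1000, seed=0)

print(f"fixed differences: {len(positions)} of {aln.length} columns")
print(f"p-distance: {dist.distance:.4f} +- {dist.se:.4f} (1000 bootstrap reps)")
print(f"peak window count: {profile.counts.max()} "
      f"(window starting at column {int(profile.counts.argmax()) + 1})")

for rec in locate_indels(aln, feature_column_spans(pair)):
    print(f"indel: {rec.length} bp, carrier {rec.carrier}, inside {rec.feature}")

tab = per_feature_divergence(pair).set_index("feature")
print(tab.loc[["16S", "cytb", "12S", "cox2"],
              ["rate_class", "p_distance", "fixed_differences"]])
# The window peak falls over the 16S insertion; per-feature divergence
# separates hotspot from conserved features by an order of magnitude.
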