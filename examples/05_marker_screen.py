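"""W-linked marker screening on a synthetic RAD-tag matrix.

Plants 5 W-linked tags among 2,000 background tags over a 12-male /
12-female (8 WZ + 4 WW) cohort with 20% dropout, then screens with the
"present in >60% of females, absent in all males" filter.
"""

from wzpop import RadDesign, screen_sex_markers, simulate_rad_matrix, tag_association_stats

design = RadDesign(n_tags=2000, n_w_linked=5, dropout=0.2, false_presence=0.0)
m = simulate_rad_matrix(design, seed=11)
res = screen_sex_markers(m, female_fraction_threshold=0.6)

print(f"{len(res.selected_tags)} candidate tag(s) of {len(m.tags)} screened "
      f"({res.n_female} females, {res.n_male} males):")
sel = res.table[res.table["selected"]]
print(sel.to_string(index=False))
# Planted tags (named Wtag...) survive the screen whenever their realized
# female presence clears 60% despite dropout; background tags must be
# absent in all 12 males AND >60% present in females by chance to slip in.

stats = tag_association_stats(m)
print("\nper-sex presence counts of the planted tags:")
print(stats.head(design.n_w_linked).to_string(index=False))
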