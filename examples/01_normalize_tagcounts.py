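"""Merge per-sample tag counts and normalize totals by ploidy.

Species of different ploidy yield proportionally more GBS tags; before any
presence/absence comparison, species totals are scaled so a diploid holds
1x, a tetraploid 2x and a hexaploid 3x of a common unit, using unbiased
per-tag stochastic rounding.
"""

from gbspaint import TagCountTable, downsample_counts, merge_tagcounts, normalize_by_ploidy

# two samples of one diploid species, merged by union-sum
s1 = TagCountTable({"ACGTACGT": 300, "TTGGCCAA": 120}, label="dip_s1")
s2 = TagCountTable({"ACGTACGT": 250, "GGGGCCCC": 80}, label="dip_s2")
dip = merge_tagcounts([s1, s2], label="diploid")
dip.ploidy = 2
print(f"merged diploid: {len(dip)} tags, total {dip.total}")

# a deeper tetraploid species table
tet = TagCountTable({"ACGTACGT": 700, "TTGGCCAA": 500, "CCCCAAAA": 400},
                    label="tetraploid", ploidy=4)

normalized, plan = normalize_by_ploidy([dip, tet], seed=0)
print(f"1x unit U = {plan.unit} (min of total/(ploidy/2) across species)")
for t in normalized:
    m = plan.multipliers[t.label]
    print(f"  {t.label}: target {plan.targets[t.label]} = {m}xU, "
          f"realized total {t.total}")

# the worked example: a tag seen 600 times in a 3,000,000-tag table
# scaled to 2,000,000 keeps an integral expectation and is always 400
big = TagCountTable({"A" * 8: 600, "C" * 8: 2_999_400})
out = downsample_counts(big, 2_000_000, seed=1)
print(f"count 600 at ratio 2/3 -> {out.counts['A' * 8]} (deterministic)")
# Realized totals land within a tag or two of their targets because each
# tag rounds to floor or ceil of its scaled expectation, unbiased.
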