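# Published five-outcome gene-tree classification counts for the placental
# mammal root quartet (Xenarthra, Afrotheria, Boreoeutheria, outgroups).
# Columns are analysis variants: binned supergene trees (bin-size weighted)
# and unbinned gene trees, each at 50% and 75% bootstrap-support collapse
# thresholds.  Every column totals 11,169 genes.
outcome	binned_50	unbinned_50	binned_75	unbinned_75
REJECTS_ALL	2994	2418	1673	763
INDECISIVE	1788	5256	5293	9079
Xenarthra	1751	876	1113	281
Afrotheria	1969	926	1199	303
Atlantogenata	2667	1693	1891	743
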