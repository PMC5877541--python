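"""Relative synonymous codon usage under the invertebrate mitochondrial code.

RSCU(c) = N(c) * k / sum(N over the family), where k is the synonymous
family size; serine is one 8-codon family (UCN + AGN) and leucine one
6-codon family under translation table 5.
"""

from mitofeatures import count_codons, rscu_from_counts, start_stop_report
from mitofeatures.data import load_reference_codon_usage
from mitofeatures.synthetic import GenomeSpec, generate_genome

# published counts -> RSCU
df = load_reference_codon_usage()
rscu = rscu_from_counts(dict(zip(df.codon, df.n)))
for codon in ("TTA", "TTT", "TCT", "ATT"):
    print(f"RSCU({codon.replace('T', 'U')}) = {rscu[codon]:.2f}")

# codon usage of a synthetic genome with the published start/stop layout
genome, table, _ = generate_genome(GenomeSpec.from_reference(seed=1))
usage = count_codons(genome, table)
print(f"\nstop codons across 13 PCGs: UAA x {usage.records['TAA'].n}, "
      f"UAG x {usage.records['TAG'].n}")
for record in start_stop_report(genome, table):
    if record.start_class != "ATN-standard":
        print(f"{record.gene}: alternative start {record.start_codon} "
              f"({record.start_class}), stop {record.stop_codon}")

# RSCU > 1 marks codons used more often than expected under equal
# synonym usage: UUA(Leu) at 2.60 reflects the strong A+T bias of the
# genome. Incomplete stops (T-) are completed by mRNA polyadenylation.
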