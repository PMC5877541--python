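"""Structural scan of a mitochondrial control region.

Generates a control region with the published architecture (leading
segment, 7-nt tandem repeat array, remainder with poly tracts and
hairpins), then recovers every element: segmentation, the repeat array,
poly-N runs, and stem-loops with their TATA / G(A)nT flanking motifs.
"""

from mitofeatures import (
    detect_flanking_motifs,
    find_poly_runs,
    find_stem_loops,
    segment_control_region,
)
from mitofeatures.synthetic import CRSpec, generate_control_region

seq, truth = generate_control_region(CRSpec(), seed=11)
print(f"control region: {len(seq)} nt")

seg = segment_control_region(seq)
print(f"leading {seg.leading}, repeat block {seg.repeat_block}, "
      f"remainder {seg.remainder}")
rep = seg.repeat
print(f"tandem repeat: unit {rep.consensus} ({rep.period} nt) x "
      f"{rep.copy_number} copies, identity {rep.identity:.0%}")

print("poly-N tracts (>= 7 nt):")
for run in find_poly_runs(seq):
    print(f"  poly-{run.base} {run.start}-{run.end} ({run.length} nt)")

print("stem-loops:")
for sl in find_stem_loops(seq, min_stem=12, max_mismatch=0):
    sl = detect_flanking_motifs(seq, sl)
    print(f"  stem {sl.stem_len} bp at {sl.span[0]}-{sl.span[1]}: "
          f"5' TATA {sl.tata_5prime.present}, 3' G(A)nT {sl.gant_3prime.present}")

# The leading/repeat/remainder segmentation and the motif-flanked
# hairpins mirror the elements implicated in replication initiation in
# insect control regions; all spans are 1-based and CR-local.
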