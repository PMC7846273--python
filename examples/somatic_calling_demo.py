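"""Call somatic variants on a simulated tumor/normal pair.

Plants one somatic variant (VAF 0.3) and one germline variant (VAF 0.5) on
a small locus, writes SAM/FASTA, and runs the threshold caller (depth >= 9,
alt reads >= 2) with matched-normal subtraction.
"""

import tempfile

import numpy as np
import pysam

from nmdmutscan.somatic_calling import (TargetLocus, call_variants,
                                        pileup_region, subtract_matched_normal)
from nmdmutscan.synthetic_data import PlannedVariant, simulate_alignments

rng = np.random.default_rng(13)
locus = TargetLocus("UPF1", "chrT", 0, 400)
plan = [PlannedVariant("UPF1", "chrT", 150, "G", vaf=0.30, is_germline=False),
        PlannedVariant("UPF1", "chrT", 250, "C", vaf=0.50, is_germline=True)]

with tempfile.TemporaryDirectory() as tmp:
    reference, *_ = simulate_alignments([locus], plan, rng, depth=60,
                                        out_dir=tmp, sample="p1")
    with pysam.AlignmentFile(f"{tmp}/p1.tumor.sam") as fh:
        tumor_pile = pileup_region(fh, locus, reference)
    with pysam.AlignmentFile(f"{tmp}/p1.normal.sam") as fh:
        normal_pile = pileup_region(fh, locus, reference)

tumor_calls = call_variants(tumor_pile, locus, reference)
print("pos  ref>alt  depth  alt_reads  vaf    normal   somatic")
for call in subtract_matched_normal(tumor_calls, normal_pile, "p1"):
    print(f"{call.site.pos:<5}{call.site.ref_base}>{call.alt}      "
          f"{call.site.depth:<7}{call.site.alt_counts[call.alt]:<11}"
          f"{call.vaf:.2f}   {call.normal_status:<9}{call.is_somatic}")

# Both planted variants are called in the tumor; the germline one is also
# called in the matched normal and therefore subtracted (somatic=False),
# while the somatic variant survives subtraction with a VAF near 0.30.
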