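"""Plant Ty elements in a synthetic genome, corrupt the raw hits with
realistic annotation errors, then curate them back and compare with truth.

The curated full/truncated/solo counts should equal the planted ground truth
exactly: the curation operations (divergence filter, LTR relabelling, tandem
splitting, fused-solo splitting) repair every injected error mode.
"""

import numpy as np

from tyland import annotation as ann
from tyland import simulate as sim

rng = np.random.default_rng(1)
config = sim.GenomeConfig(
    elements=[
        sim.ElementSpec(subfamily="canonical"),
        sim.ElementSpec(subfamily="ty1prime", strand="-"),
        sim.ElementSpec(tandem_copies=2),
        sim.ElementSpec(structural_class="truncated", truncated_fraction=0.5,
                        with_fused_solo=True),
        sim.ElementSpec(structural_class="solo_ltr"),
    ],
    errors=sim.ErrorModeConfig(p_mislabel_ltr=0.5, p_merge_tandem=1.0,
                               p_fuse_solo=1.0, fp_rate=10.0),
)
truth = sim.plant_genome(config, seed=7)
print(f"genome: {len(truth.genome['chrI']):,} bp, "
      f"{len(truth.elements)} planted elements, {len(truth.raw_hits)} raw hits")

library = ann.TyLibrary({"Ty1": ann.TyFamily("Ty1", 334, 5250),
                         "Ty2": ann.TyFamily("Ty2", 332, 5296)})
elements = ann.curate(truth.raw_hits, library, strain="demo")
counts = ann.count_by_family(elements)

print("\ncurated elements:")
for el in elements:
    print(f"  {el.element_id:10s} {el.structural_class:12s} {el.family} "
          f"{el.chrom}:{el.start}-{el.end} ({el.strand}) {len(el.blocks)} block(s)")

print("\ncounts vs planted truth (full/truncated/solo per family):")
print("  curated:", counts.per_family)
print("  truth:  ", truth.truth_counts)
print("  pooled Ty1/Ty2 solo LTRs:", counts.pooled_ty1_ty2_solo)
assert counts.per_family == truth.truth_counts
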