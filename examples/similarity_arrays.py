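"""Sort the library into image arrays by similarity to a reference probe.

Ranks aldehyde and head building blocks by Tanimoto coefficient against a
reference compound's blocks and assembles sorted montage arrays, including
the structurally similar (Tc > 0.4) and dissimilar (Tc < 0.25) subsets.
A small sample of images is rendered for the montage; the rest stay blank.
"""

from pathlib import Path

import probeloc as pl

library = pl.generate_library(8, 168, seed=11)
screen = pl.generate_screen(library, seed=11)
reference = next(c for c in library if c.compound_id == "C-40")

alds, heads, tables = pl.rank_blocks_by_similarity(library, reference)
print(f"reference {reference.compound_id}: "
      f"aldehyde ranking starts {alds[:6]} (Tc "
      f"{[round(t, 2) for t in tables['aldehyde']['Tc'][:6]]})")

# render the top-left 6x4 corner of the sorted array; leave the rest blank
images = {}
for ald in alds[:6]:
    for head in heads[:4]:
        c = next(x for x in library
                 if x.aldehyde.index == ald and x.head.index == head)
        images[c.compound_id] = screen.render(c.compound_id, 0)

outdir = Path("scratch/examples")
for name, kwargs in [
    ("tanimoto_array", {}),
    ("similar_subset", {"tc_min": 0.4}),
    ("dissimilar_subset", {"tc_max": 0.25}),
]:
    spec, montage = pl.build_tanimoto_array(
        library, images, reference, crop_mode="cell", **kwargs
    )
    pl.export_montage(spec, montage, outdir / f"{name}.png")
    print(f"{name}: {len(spec.row_order)} rows x {len(spec.col_order)} cols, "
          f"reference at (0,0) with Tc {spec.row_values[0]:.1f}/{spec.col_values[0]:.1f}")
print(f"wrote montages and metadata sidecars to {outdir}/")
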