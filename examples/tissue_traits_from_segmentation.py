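"""Turn zone-level segmentation pixel counts into synthetic tissue traits.

Each FASGA-stained cross-section is segmented into 44 zones; their
pixel counts are converted to %ICS (share of the internode
cross-section) and summed into colour / digestibility groupings the
analysis actually uses (blue pith, red rind, highly digestible...).
"""

from maizedig import simulate, traits

seg = simulate.gen_segmentation(3, seed=42)
out = traits.segmentation_traits(seg)

cols = [
    "sample", "blue_pith", "highly_digestible", "digestible",
    "drt_total", "lrt_total", "rind_total", "drt_to_rind",
]
print(out[cols].round(2).to_string(index=False))
print("\ndrt_total + lrt_total == rind_total (the rind partition);")
print("all traits are %ICS, i.e. percent of the whole cross-section.")
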