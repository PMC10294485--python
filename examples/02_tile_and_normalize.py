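"""Tile a slide with Otsu masking and apply Reinhard stain normalization.

A slide becomes a grid of 256x256 tiles; tiles that are mostly background
(Otsu mask) or featureless are discarded.  Stain normalization then maps
each tile's color statistics onto a fixed reference in the decorrelated
log-color (lαβ) space, shrinking the color gap between sources.
"""

import numpy as np

import histomil
from histomil import apply_reinhard, preset_fit, tile_slide

scenario = histomil.make_multicenter_scenario("confounded_trio", seed=7)
slide_a = scenario["A"][0][0]
slide_b = scenario["B"][0][0]

fit = preset_fit()
print(f"normalization target (lαβ means): {np.round(fit.target_mean, 3)}")

for slide in (slide_a, slide_b):
    store = tile_slide(slide)
    t = store.tiles[0]
    before = t.pixels.reshape(-1, 3).mean(axis=0)
    after = apply_reinhard(t.pixels, fit).reshape(-1, 3).mean(axis=0)
    print(
        f"{slide.slide_id} ({slide.dataset_id}): {store.n_kept}/{store.n_candidates} "
        f"tiles kept; first tile mean RGB {np.round(before, 1)} -> {np.round(after, 1)}"
    )

print("\nafter normalization the two sources' tile colors nearly coincide,")
print("even though their raw casts pointed in opposite directions")
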