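"""Learn lateral weights from synthetic images and check like-to-like.

Responses of the 18-filter bank to collinear-contour images are pooled
into co-occurrence weights W(j, k, dy, dx) = <c_j c_k>/(<c_j><c_k>) - 1
on a 43x43 offset grid; offsets with overlapping receptive fields are
then masked out.  Collinear image structure should make same-orientation
pairs carry more positive weight than orthogonal ones.
"""

from latnet import (
    build_v1_basis, cooccurrence_weights, crf_responses, mask_overlap,
    orientation_dependence, preprocess_image, surround_effect_stats,
)
from latnet.synthetic import gen_oriented_contours

bank = build_v1_basis()
images = gen_oriented_contours(20, size=96, seed=7)
maps = [crf_responses(preprocess_image(im), bank) for im in images]

lw = cooccurrence_weights(maps, max_offset=21)
print(f"weight tensor: {lw.W.shape}  (range {lw.W.min():.3f} .. {lw.W.max():.3f})")

masked = mask_overlap(lw, rf_size=15)
bins = orientation_dependence(masked, bank, sign="positive")
print("mean positive weight by orientation difference:")
for b, v in bins.items():
    print(f"  {b:>5.0f} deg: {v:.4f}")
print("-> like-to-like: the 0-deg bin should exceed the 90-deg bin.")

mean, sd = surround_effect_stats(maps[:5], masked)
print(f"surround term over the corpus: mean {mean:.3f}, sd {sd:.3f} "
      "(how strongly the surround modulates a unit before scaling by alpha)")
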