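"""Out-of-focus image exclusion from the (object count, granularity) plot.

Generates sharp synthetic images and Gaussian-blurred copies, embeds each as
(number of nuclei, granularity scalar), fits the separating line from a few
labeled examples and classifies the rest. Blur lowers granularity, so blurred
images fall on the negative side of the line and get the excluded flag.
"""

from scipy import ndimage

import phenoplate as pp
from phenoplate.data import ImageKey
from phenoplate.focus import IN_FOCUS, OUT_OF_FOCUS

spec = pp.PlateSpec(wells=("A01", "A02"), images_per_well=3, image_size=96,
                    cells_per_image=12, seed=2)
plate = pp.generate_plate(spec)

points = []
for i, im in enumerate(plate.images):
    n = im.labelmatrices["nuclei"].n_objects
    g_sharp = pp.granularity_spectrum(im.channels["dna"], rounds=8).scalar
    blurred = ndimage.gaussian_filter(im.channels["dna"], 3.0)
    g_blur = pp.granularity_spectrum(blurred, rounds=8).scalar
    points.append(pp.FocusTrainingPoint(im.key, n, g_sharp, IN_FOCUS))
    points.append(
        pp.FocusTrainingPoint(ImageKey("blur", im.key.well, im.key.site),
                              n, g_blur, OUT_OF_FOCUS)
    )
    print(f"{im.key.well} site {im.key.site}: {n:2d} nuclei, "
          f"granularity sharp {g_sharp:.4f} vs blurred {g_blur:.4f}")

line = pp.fit_focus_line(points[:8])  # train on the first 4 image pairs
print(f"\nfitted line: {line.w1:.4g}*n_objects + {line.w2:.4g}*granularity "
      f"+ {line.b:.4g} >= 0  => in focus")

correct = sum(
    pp.classify_focus(line, p.n_objects, p.granularity) == p.label
    for p in points
)
print(f"line classifies {correct}/{len(points)} images correctly")
print()
print("Blurring roughly halves the granularity scalar while the object count")
print("stays put, so a line in this 2-D embedding cleanly separates the two")
print("groups; images on the negative side are flagged excluded and skipped")
print("by training candidate selection and by all well/plate summaries.")
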