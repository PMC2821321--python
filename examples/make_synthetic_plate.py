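"""Generate a synthetic fixture plate and inspect its ground truth.

Writes TIFF channel images, nuclei/cells/spots label matrices, a manifest CSV
and truth tables — the same formats the rest of the toolkit consumes — fully
reproducible from the seed.
"""

from pathlib import Path

import phenoplate as pp

outdir = Path("/tmp/phenoplate_demo_plate")
spec = pp.PlateSpec(wells=("A01", "B01"), images_per_well=2, image_size=96,
                    cells_per_image=10, mitotic_fraction=0.2,
                    blur_fraction=0.25, seed=17)
plate = pp.generate_plate(spec, outdir=outdir)

t = plate.truth_objects
print(f"wrote {len(plate.images)} sites to {outdir}")
print(f"{len(t)} nuclei: {(t.true_class == 'mitotic').sum()} mitotic, "
      f"{(t.mitotic_neighbor == 1).sum()} neighbors of mitotic, "
      f"{(t.n_spots > 0).sum()} with >= 1 docked spot")
print(f"blurred images: {plate.truth_images['blurred'].sum()} of "
      f"{len(plate.truth_images)}")

records = pp.read_manifest(outdir / "manifest.csv")
print(f"manifest lists {len(records)} sites; first site channels: "
      f"{sorted(records[0].channel_paths)}; label matrices: "
      f"{sorted(records[0].labelmatrix_paths)}")
print()
print("Mitotic nuclei are rendered ~1.5x brighter and smaller with stronger")
print("internal texture; spots dock onto cells with a 5x Poisson-rate")
print("preference for mitotic cells — ground truth stays in separate files,")
print("never inside the measurement tables.")
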