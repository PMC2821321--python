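"""From classified objects to a plate report.

Runs the docking pipeline on a synthetic plate (classify nuclei, relate spots
to cells, build vectors), evaluates image and well variables including a
plate-standard normalization, and writes the spreadsheet, heat-map grid and
an outlined image.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import phenoplate as pp
from phenoplate.reporting import (
    OutlineSpec,
    export_tables,
    plate_heatmap,
    render_outlined_image,
)

outdir = Path("/tmp/phenoplate_report")
wells = ("A01", "A02", "B01", "B02", "G01", "G02")
spec = pp.PlateSpec(wells=wells, images_per_well=2, image_size=96,
                    cells_per_image=12, mitotic_fraction=0.2, seed=6)
plate = pp.generate_plate(spec)
table = plate.measure(kinds=("intensity",))
truth = plate.truth_labels()

X = table.feature_matrix()
y = np.array([truth[r] for r in table.refs()])
model = pp.train_model(X, y, C=1.0, gamma=0.5, feature_names=table.feature_names)
ctx = plate.build_context(table)
ctx.predictions["nuclei"] = dict(
    zip(table.refs(), pp.predict(model, X, table.feature_names))
)

reg = ctx.vectors
reg.add(pp.ClassEquals("mitotic", "nuclei", class_name="mitotic"))
reg.add(pp.Logic("not_mitotic", "nuclei", op="NOT", operands=("mitotic",)))
reg.add(pp.Logic("all_nuclei", "nuclei", op="OR",
                 operands=("mitotic", "not_mitotic")))
reg.add(pp.ChildCountCmp("infected", "nuclei", child_type="spots",
                         op=">=", threshold=1))

image_vars = {
    "n_nuclei": pp.ImageVarDef("n_nuclei", "all_nuclei", "count"),
    "n_infected": pp.ImageVarDef("n_infected", "infected", "count"),
    "pct_infected": pp.ImageVarDef("pct_infected", "infected", "percent_of",
                                   reference="all_nuclei"),
}
well_defs = [
    pp.WellVarDef("n_nuclei", image_var="n_nuclei", image_summarizer="sum"),
    pp.WellVarDef("n_infected", image_var="n_infected", image_summarizer="sum"),
    pp.WellVarDef("pct_infected", calculation=("*", 100.0,
                                               ("/", "n_infected", "n_nuclei"))),
    # log2 normalization to the standard wells G01-G02
    pp.WellVarDef("log2_vs_standard",
                  calculation=("log2", ("/", "pct_infected", "standard"))),
]
plate_vars = [pp.PlateVarDef("standard", "pct_infected", wells=("G01", "G02"))]

series = pp.eval_well_series(well_defs, [("plate1", w) for w in wells], ctx,
                             image_vars, plate_vars=plate_vars)
well_df = pd.DataFrame(
    {"well": wells,
     **{name: [series[name][("plate1", w)] for w in wells]
        for name in ("n_nuclei", "n_infected", "pct_infected",
                     "log2_vs_standard")}}
)
print(well_df.round(3).to_string(index=False))

paths = export_tables(None, well_df, None, outdir)
fig, grid = plate_heatmap(
    dict(zip(well_df["well"], well_df["pct_infected"])), pp.PLATE_96,
    title="percent infected nuclei",
)
fig.savefig(outdir / "heatmap.png", dpi=80)
print(f"\nwrote {paths['xlsx'].name}, {paths['well'].name} and heatmap.png "
      f"to {outdir}")

# outlined image: infected nuclei outlined red, the rest blue
im = plate.images[0]
vec_inf = pp.eval_vector("infected", im.key, ctx)
vec_rest = pp.eval_vector("not_mitotic", im.key, ctx)
spec_out = OutlineSpec(layers=((vec_inf, (1.0, 0.0, 0.0)),
                               (vec_rest, (0.0, 0.4, 1.0))), line_width=1)
rgb = render_outlined_image(im.channels, im.labelmatrices["nuclei"], spec_out,
                            channel_colors={"dna": "g", "bacteria": "r"})
import matplotlib.pyplot as plt

plt.imsave(outdir / "outlined_A01_s0.png", np.clip(rgb, 0, 1))
print("outlined_A01_s0.png projects the classification onto the image:")
print("red outlines mark infected nuclei, blue the non-mitotic rest.")
print()
print("pct_infected is the well-level ratio of sums; log2_vs_standard is")
print("log2 of each well against the mean of the standard wells G01-G02,")
print("so the standards themselves sit near 0.")
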