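"""The binary vector algebra on a 5-cell image.

An image holds 5 cells; the classifier calls cells 1 and 3 mitotic, and the
spot-to-cell relation marks cells 1, 4 and 5 as carrying at least one docked
bacterial spot ("infected"). Every subpopulation is then one logical
expression over the two base vectors.
"""

import pandas as pd

import phenoplate as pp
from phenoplate.data import ImageKey, ObjectRef, ObjectTable, RelationTable

img = ImageKey("plate1", "A01", 0)
ctx = pp.EvalContext()
ctx.tables["cells"] = ObjectTable(
    pd.DataFrame({"plate": "plate1", "well": "A01", "site": 0,
                  "object_id": [1, 2, 3, 4, 5], "area": [1.0] * 5}),
    "cells",
)
ctx.predictions["cells"] = {
    ObjectRef("plate1", "A01", 0, i): ("mitotic" if i in (1, 3) else "normal")
    for i in range(1, 6)
}
ctx.relations[("cells", "spots")] = {
    img: RelationTable("cells", "spots", pairs=[(1, 1), (4, 2), (5, 3)],
                       child_counts={1: 1, 2: 0, 3: 0, 4: 1, 5: 1})
}

reg = ctx.vectors
reg.add(pp.ClassEquals("mitotic", "cells", class_name="mitotic"))
reg.add(pp.ChildCountCmp("infected", "cells", child_type="spots",
                         op=">=", threshold=1))
reg.add(pp.Logic("infected mitotic", "cells", op="AND",
                 operands=("mitotic", "infected")))
reg.add(pp.Logic("non-mitotic", "cells", op="NOT", operands=("mitotic",)))
reg.add(pp.Logic("infected non-mitotic", "cells", op="AND",
                 operands=("non-mitotic", "infected")))

for name in ("mitotic", "infected", "infected mitotic", "infected non-mitotic"):
    v = pp.eval_vector(name, img, ctx)
    print(f"{name:22s} -> {', '.join(map(str, v.flags))}   (count {v.count})")

print()
print("Each vector has one 0/1 flag per cell (ids 1..5); AND/OR/NOT of")
print("vectors carve out any subpopulation, e.g. the single infected mitotic")
print("cell is cell 1, and the infected non-mitotic cells are 4 and 5.")
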