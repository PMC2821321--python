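"""The four training modes on a noisy 2-class pool.

Starts with a few random forced-choice labels, then compares refining the
model with decision-boundary candidates (the objects the current model is
least sure about) against labeling more random objects.
"""

import numpy as np
import pandas as pd

import phenoplate as pp
from phenoplate.data import ObjectTable

rng = np.random.default_rng(0)
X, y = pp.generate_feature_blobs(250, k=2, separation=3.0, n_features=6, seed=0)
image_of = rng.integers(0, 20, len(X))
rows = []
for i in range(len(X)):
    row = {"plate": "p", "well": f"A{image_of[i] + 1:02d}", "site": 0,
           "object_id": int(1 + (image_of[: i + 1] == image_of[i]).sum())}
    row.update({f"f{f}": X[i, f] for f in range(X.shape[1])})
    rows.append(row)
table = ObjectTable(pd.DataFrame(rows), "cells")
truth = dict(zip(table.refs(), y))
Xt, yt = table.feature_matrix(), np.array([truth[r] for r in table.refs()])


def fit(refs):
    sub = table.subset(refs)
    return pp.train_model(sub.feature_matrix(),
                          np.array([truth[r] for r in sub.refs()]),
                          C=1.0, gamma=0.5, feature_names=table.feature_names)


# "random" mode: forced-choice draws, image first, then object
session = pp.TrainingSession()
init = pp.pick_random(table, n=20, seed=1).refs()
for ref in init:
    session.label(ref, truth[ref], mode="random")
model = fit(list(session.labels))
acc0 = (pp.predict(model, Xt, table.feature_names) == yt).mean()
print(f"after 20 random labels:        accuracy {100 * acc0:.1f}%")

# "decision boundaries" mode: iterative querying near the boundary
for _ in range(10):
    batch = pp.boundary_candidates(model, table, n=5,
                                   labeled=set(session.labels)).refs()
    for ref in batch:
        session.label(ref, truth[ref], mode="boundary")
    model = fit(list(session.labels))
acc_b = (pp.predict(model, Xt, table.feature_names) == yt).mean()
print(f"+50 boundary-mode labels:      accuracy {100 * acc_b:.1f}%")

# comparison arm: 50 more random labels instead
rnd = list(init) + pp.pick_random(table, n=50, seed=2, labeled=init).refs()
acc_r = (pp.predict(fit(rnd), Xt, table.feature_names) == yt).mean()
print(f"+50 random labels instead:     accuracy {100 * acc_r:.1f}%")

# "correction" mode stores only disagreements with the model
img = table.image_keys()[0]
img_refs = [r for r in table.refs() if r.image == img]
user = {r: truth[r] for r in img_refs}
stored = pp.correction_pass(model, table, img, user, session)
print(f"correction pass on one image:  {len(stored)} of {len(user)} "
      "objects corrected (only those are memorized)")
print()
print("Boundary-mode querying spends each label on an object the model is")
print("uncertain about, which here beats spending them at random.")
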