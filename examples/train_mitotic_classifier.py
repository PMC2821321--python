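"""Train and validate a mitotic/normal nucleus classifier on a synthetic plate.

Renders a small plate (mitotic nuclei ~1.5x brighter, smaller and more
textured), measures intensity features from the images, runs a C/gamma grid
search with 5-fold cross-validation, and reports the confusion matrix.
"""

import numpy as np

import phenoplate as pp

spec = pp.PlateSpec(wells=("A01", "A02", "B01", "B02"), images_per_well=3,
                    image_size=96, cells_per_image=12, mitotic_fraction=0.25,
                    seed=4)
plate = pp.generate_plate(spec)
table = plate.measure(kinds=("intensity",))
truth = plate.truth_labels()

X = table.feature_matrix()
y = np.array([truth[r] for r in table.refs()])
print(f"{len(y)} nuclei, {X.shape[1]} features, "
      f"{(y == 'mitotic').sum()} mitotic / {(y == 'normal').sum()} normal")

gs = pp.grid_search(X, y, C_grid=[0.1, 1.0, 10.0], gamma_grid=[0.05, 0.5, 2.0],
                    k=5, seed=0)
C, gamma = gs.best
print(f"grid search best: C={C}, gamma={gamma} "
      f"(CV accuracy {100 * gs.best_accuracy:.1f}%)")

cv = pp.cross_validate(X, y, k=5, C=C, gamma=gamma, seed=0)
print(f"5-fold cross-validation accuracy: {100 * cv.accuracy:.1f}%")
print("confusion matrix (rows = trained class, cols = predicted):")
print(cv.confusion)

model = pp.train_model(X, y, C=C, gamma=gamma, feature_names=table.feature_names)
pp.save_model(model, "/tmp/mitotic_model.json")
back = pp.load_model("/tmp/mitotic_model.json")
same = (pp.predict(model, X, table.feature_names)
        == pp.predict(back, X, table.feature_names)).all()
print(f"model saved and reloaded; predictions identical: {same}")
print()
print("A high CV accuracy means the intensity features separate the two")
print("nuclear phenotypes; the reloaded model reproduces every prediction.")
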