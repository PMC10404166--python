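#!/usr/bin/env python
"""Recall-mode prediction maps over hypothetical synthesis conditions.

Trains the SVM dispersity (multiclass), SVM stability and binary masking
models on the full library, loads the +Curc ANN from script 04, and sweeps
a dense (TFR, lipid) grid at V_a/V_o = 3: where is a new formulation
expected to be monodisperse, to stay stable for 3 days, and what diameter
should it have?  Polydisperse zones mask the size map (grey areas).
Experimental (synthetic-library) formulations are overlaid as diamonds.
"""

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from lipoml.ann import NetworkModel, size_heatmap
from lipoml.classify import (
    ClassifierSpec,
    dispersity_table,
    plot_heatmap,
    predict_heatmap,
    stability_table,
)
from lipoml.datamodel import read_library

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--library", type=Path, default=Path("results/library.csv"))
parser.add_argument("--ann-model", type=Path, default=Path("results/ann_model_curc.json"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

lib = read_library(args.library)
tfr_grid = np.linspace(1, 16, 61)
lipid_grid = np.linspace(10, 40, 31)
bounds = {"tfr_ml_min": (1.0, 16.0), "lipid_mg_ml": (10.0, 40.0)}

Xm, ym, _ = dispersity_table(lib, "multiclass")
multi_model = ClassifierSpec("SVM", seed=args.seed).build().fit(Xm, ym)
Xb, yb, _ = dispersity_table(lib, "binary")
binary_model = ClassifierSpec("SVM", seed=args.seed).build().fit(Xb, yb)
Xs, ys, _ = stability_table(lib)
stab_model = ClassifierSpec("SVM", seed=args.seed).build().fit(Xs, ys)

panels = []
for curc in (False, True):
    for model, target in ((multi_model, "dispersity"), (stab_model, "stability")):
        g = predict_heatmap(model, tfr_grid, lipid_grid, 3.0, curc, training_bounds=bounds)
        g["target"] = target
        panels.append(g)
grid = pd.concat(panels, ignore_index=True)
grid.to_csv(args.out / "heatmaps_classification.csv", index=False)

day0 = lib.day0().frame
points = day0[day0["va_vo"] == 3.0].drop_duplicates(["tfr_ml_min", "lipid_mg_ml", "curcumin"])
fig, axes = plt.subplots(2, 2, figsize=(9, 7))
for i, curc in enumerate((False, True)):
    for j, target in enumerate(("dispersity", "stability")):
        sub = grid[(grid.curcumin == int(curc)) & (grid.target == target)]
        plot_heatmap(sub, ax=axes[i][j], experimental=points[points.curcumin == int(curc)])
        axes[i][j].set_title(f"{target}, {'+Curc' if curc else '-Curc'}")
fig.tight_layout()
fig.savefig(args.out / "heatmaps_classification.png", dpi=150)

ann_model = NetworkModel.from_dict(json.loads(args.ann_model.read_text()))
size_grid = size_heatmap(ann_model, tfr_grid, lipid_grid, 3.0, True, binary_model)
size_grid.to_csv(args.out / "heatmap_size_curc.csv", index=False)

fig, ax = plt.subplots(figsize=(5.5, 4))
shaped = size_grid.pivot(index="tfr_ml_min", columns="lipid_mg_ml", values="diameter_nm")
masked = size_grid.pivot(index="tfr_ml_min", columns="lipid_mg_ml", values="masked").to_numpy()
img = np.ma.masked_array(shaped.to_numpy(), mask=masked)
pc = ax.pcolormesh(shaped.columns, shaped.index, img, shading="nearest", cmap="plasma")
ax.set_facecolor("lightgray")  # masked (predicted polydisperse) field
fig.colorbar(pc, label="predicted diameter (nm)")
cpoints = points[points.curcumin == 1]
ax.scatter(cpoints["lipid_mg_ml"], cpoints["tfr_ml_min"], marker="D", c="white",
           edgecolors="black", s=30)
ax.set(xlabel="total lipid concentration (mg/ml)", ylabel="TFR (ml/min)",
       title="+Curc liposome size, recall mode (grey = predicted polydisperse)")
fig.tight_layout()
fig.savefig(args.out / "heatmap_size_curc.png", dpi=150)

mono_frac = 1 - size_grid["masked"].mean()
low = size_grid[size_grid.tfr_ml_min < 8]["masked"].mean()
high = size_grid[size_grid.tfr_ml_min >= 8]["masked"].mean()
print(f"monodisperse zone covers {100*mono_frac:.0f}% of the grid")
print(f"polydisperse fraction: {100*low:.0f}% below 8 ml/min vs {100*high:.0f}% above")
print(f"outputs written under {args.out}/")
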