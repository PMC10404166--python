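#!/usr/bin/env python
"""Train the 3-4-2-1 size-prediction networks and interrogate them.

One network per curcumin subset, trained on the day-0 monodisperse
per-formulation mean diameters with inputs (TFR, lipid concentration,
V_a/V_o).  Writes the per-iteration training histories (RMSE, correlation,
LRC trace), the serialized models, the Garson input-importance percentages
(published run: TFR 45%, lipid 33%, ratio 22%), the hidden-node
interrogation tables and the connection-strength diagnostic.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from lipoml.ann import (
    NetworkTopology,
    TrainingConfig,
    connection_strengths,
    hidden_node_interrogation,
    input_importance,
    monodisperse_diameter_dataset,
    train,
)
from lipoml.datamodel import read_library

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--library", type=Path, default=Path("results/library.csv"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--topology", default="3,4,2,1")
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

lib = read_library(args.library)
topology = NetworkTopology(tuple(int(s) for s in args.topology.split(",")))

for curc, tag in ((True, "curc"), (False, "empty")):
    X, y = monodisperse_diameter_dataset(lib, curcumin=curc)
    model, history = train(X, y, topology, TrainingConfig(seed=args.seed))
    history.frame().to_csv(args.out / f"ann_history_{tag}.csv", index=False)
    (args.out / f"ann_model_{tag}.json").write_text(json.dumps(model.to_dict()))
    hidden_node_interrogation(
        model, model.scaling.scale_inputs(X), model.scaling.scale_output(y)
    ).to_csv(args.out / f"ann_interrogation_{tag}.csv", index=False)
    connection_strengths(model).to_csv(args.out / f"ann_strengths_{tag}.csv", index=False)

    pred = model.predict(X)
    corr = np.corrcoef(pred, y)[0, 1]
    imp = input_importance(model)
    print(f"== {'+Curc' if curc else '-Curc'} subset ==")
    print(f"  patterns: {len(y)} monodisperse formulations")
    print(f"  best iteration: {history.best_iteration} of {len(history.train_rmse)}")
    print(f"  validation RMSE at best: {history.val_rmse.min():.4f} (scaled units)")
    print(f"  Pearson r (all patterns): {corr:.3f}  (R^2 = {corr**2:.3f})")
    print(
        f"  input importance: TFR {imp[0]:.0f}%, lipid {imp[1]:.0f}%, ratio {imp[2]:.0f}%"
    )
print(f"\nhistories, models and diagnostics written under {args.out}/")
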