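"""Supervised domain classification and prediction of unknowns.

Labelled spectra are split 60/40 (stratified); logistic regression (L2,
C=1), kNN (Euclidean, 5 neighbours) and a 50-tree random forest are
trained, evaluated by leave-one-out CV on the training block and on the
held-out test block, then asked to predict specimens of unknown affinity
(here: two spectra generated from the eukaryote profile but labelled
"unknown", standing in for problem fossils such as nematophytes).
"""

import pandas as pd

import chertspec as cs

cfg = cs.AssemblageConfig(
    n_per_group={"eukaryote": 38, "prokaryote": 9, "unknown": 2},
    unknown_source_profile="eukaryote",
    seed=42,
)
sset, truth = cs.generate_assemblage(cfg)
matrix, _, _ = cs.preprocess_pipeline(sset)
labels = pd.Series(sset.groups(), index=sset.specimen_ids)

report = cs.run_supervised_protocol(matrix, labels, fraction=0.6, seed=42)
print(f"split: {len(report.split.train_ids)} train / "
      f"{len(report.split.test_ids)} test, "
      f"{len(report.split.excluded_ids)} unknown excluded from fitting")
print("\nleave-one-out CV on the training block:")
print(report.loo.round(3))
print("\nheld-out test block:")
print(report.test.round(3))
print("\npredictions for the unknowns:")
print(report.unknown_predictions)
src = truth.loc[report.split.excluded_ids, "source_profile"].unique()
print(f"\nThe unknowns were generated from the {src[0]} profile; a unanimous "
      f"consensus matching it shows the models recover chemistry the labels "
      f"never saw.")
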