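"""Train the graph tissue-of-origin classifier on cancer samples.

Builds the epsilon-threshold sample graph over standardized,
unit-normalized multimodal profiles, trains the attention message-passing
network transductively with focal loss, and prints per-fold accuracies,
the agreement matrix and the explainer's per-group importance summary.
"""

import warnings

import numpy as np

from cfmosaic import too
from cfmosaic.features import extract_cohort_features
from cfmosaic.profiles import CANCER_CLASSES
from cfmosaic.simulate import CohortDesign, simulate_cohort_frames

design = CohortDesign(
    class_counts={c: 14 for c in CANCER_CLASSES},
    fragments_per_sample=10_000,
    master_seed=31,
)
bundle = simulate_cohort_frames(design)
features = extract_cohort_features(bundle).normalize()
labels = bundle["labels"].set_index("sample_id")["class_label"]

graph = too.build_sample_graph(features, labels, delta=0.8,
                               class_names=CANCER_CLASSES)
print(f"graph: {graph.n_nodes} nodes, {graph.A.sum() // 2} undirected edges, "
      f"{len(graph.isolated_fallback)} nearest-neighbour fallbacks")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    model, report = too.train_gcnn(
        graph, too.GCNNConfig(epochs=120, folds=5, seed=0)
    )
print(f"fold accuracies: {np.round(report.fold_accuracies, 3).tolist()} "
      f"(chance level 0.2 for five classes)")

probs, pred = too.predict_too(model, graph)
agree = too.agreement_matrix(pred, labels.loc[pred.index], CANCER_CLASSES)
print("\nagreement matrix (rows: reference class, columns: prediction):")
print(agree.round(2))

report_imp = too.explain_importance(model, graph, steps=60, seed=0)
print("\nmean per-group importance by class:")
print(report_imp.group_summary.round(2))
print("Each class's designed signature (private methylation block, copy-"
      "number segments, motif tilt) drives which groups the explainer ranks "
      "highest.")
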