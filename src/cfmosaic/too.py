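"""Stage-2 tissue-of-origin classification on a sample graph.

Samples predicted as cancer are embedded as nodes of a graph whose edges
connect samples with similar multimodal profiles: node vectors are the
nine concatenated feature groups, standardized on training nodes and then
unit-L2-normalized so pairwise Euclidean distances lie in [0, 2]; an edge
is drawn wherever the distance falls below a threshold ``delta`` (default
0.8), with a nearest-neighbour fallback for nodes that would otherwise be
isolated.  A three-layer attention message-passing network (hidden size
44, 4 heads) classifies each node into one of five cancer types.  Training
is transductive: unlabeled nodes participate in message passing but
contribute no loss.  Class imbalance is handled by focal loss with
inverse-class-frequency weights.  A feature-mask explainer scores feature
importance per class, and a class-weight-balanced random forest provides a
flat baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score

from cfmosaic import autodiff as ad
from cfmosaic.features import FEATURE_GROUPS, MultiFeatureSet

DEFAULT_DELTA = 0.8
DEFAULT_IMPORTANCE_CUTOFF = 0.9
#: per-group variance filter applied before graph building
DEFAULT_TOP_K = 200


@dataclass
class SampleGraph:
    """Node features, labels and epsilon-threshold adjacency."""

    node_ids: list[str]
    X: np.ndarray          # standardized, unit-L2-normalized node vectors
    A: np.ndarray          # symmetric boolean adjacency, zero diagonal
    y: np.ndarray          # class index per node, -1 for unlabeled
    class_names: list[str]
    feature_names: list[str]
    isolated_fallback: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(src, dst) arrays including self-loops."""
        src, dst = np.nonzero(self.A)
        loops = np.arange(self.n_nodes)
        return np.concatenate([src, loops]), np.concatenate([dst, loops])


def _variance_filter(feature_set: MultiFeatureSet, top_k: int) -> pd.DataFrame:
    """Keep the ``top_k`` highest-variance features per group, concatenated."""
    parts = []
    for g in FEATURE_GROUPS:
        mat = feature_set.matrices[g]
        if mat.shape[1] > top_k:
            keep = mat.var(axis=0).nlargest(top_k).index
            mat = mat[keep[np.argsort([mat.columns.get_loc(c) for c in keep])]]
        parts.append(mat.rename(columns=lambda c, g=g: f"{g}:{c}"))
    return pd.concat(parts, axis=1)


def build_sample_graph(
    features,
    labels: pd.Series | dict | None,
    delta: float = DEFAULT_DELTA,
    top_k: int | None = DEFAULT_TOP_K,
    class_names: list[str] | None = None,
    standardize: bool = True,
) -> SampleGraph:
    """Threshold pairwise distances on the normalized embedding.

    ``features`` is a :class:`MultiFeatureSet` (concatenated with an
    optional per-group variance filter) or an already-concatenated
    DataFrame.  ``labels`` maps sample id to class name for labeled
    (training) nodes; other nodes are unlabeled and participate only in
    message passing.  Standardization statistics come from labeled nodes
    (all nodes when none are labeled).
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if isinstance(features, MultiFeatureSet):
        frame = _variance_filter(features, top_k) if top_k else features.concatenated()
    else:
        frame = features
    if frame.isna().any().any():
        raise ValueError("node features contain NaN; impute before graph building")

    node_ids = frame.index.tolist()
    labels = {} if labels is None else dict(labels)
    if class_names is None:
        class_names = sorted(set(labels.values()))
    class_index = {c: i for i, c in enumerate(class_names)}
    y = np.array([class_index.get(labels.get(s, None), -1) for s in node_ids])

    X = frame.to_numpy(dtype=float)
    if standardize:
        train = y >= 0 if (y >= 0).any() else np.ones(len(y), dtype=bool)
        mean = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mean) / sd
    else:
        Z = X.astype(float)
    norms = np.linalg.norm(Z, axis=1)
    norms[norms == 0] = 1.0
    Z = Z / norms[:, None]

    # pairwise Euclidean distances on the unit sphere (range [0, 2])
    gram = np.clip(Z @ Z.T, -1.0, 1.0)
    d = np.sqrt(np.clip(2.0 - 2.0 * gram, 0.0, None))
    A = d < delta
    np.fill_diagonal(A, False)

    isolated = np.where(~A.any(axis=1))[0]
    fallback = []
    for i in isolated:
        di = d[i].copy()
        di[i] = np.inf
        j = int(np.argmin(di))
        A[i, j] = A[j, i] = True
        fallback.append(node_ids[i])
    if len(node_ids) == 1:
        A = np.zeros((1, 1), dtype=bool)
        fallback = []
    return SampleGraph(
        node_ids=node_ids,
        X=Z,
        A=A,
        y=y,
        class_names=list(class_names),
        feature_names=frame.columns.tolist(),
        isolated_fallback=fallback,
    )


def focal_loss(probabilities, true_labels, gamma: float = 2.0, alpha=None) -> float:
    """Mean focal loss ``-alpha_y (1 - p_y)^gamma log p_y`` over samples.

    ``probabilities`` rows must sum to 1.  ``alpha`` is a per-class weight
    vector (default all ones); at ``gamma=0`` and unit ``alpha`` this is
    exactly the cross-entropy.  Zero probabilities are clipped at 1e-12
    with a warning.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(true_labels, dtype=int)
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p_y = p[np.arange(len(y)), y]
    if (p_y <= 0).any():
        warnings.warn("zero class probabilities clipped at 1e-12")
        p_y = np.clip(p_y, 1e-12, None)
    a = np.ones(p.shape[1]) if alpha is None else np.asarray(alpha, dtype=float)
    return float(np.mean(-a[y] * (1.0 - p_y) ** gamma * np.log(p_y)))


def inverse_frequency_weights(y: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.bincount(y[y >= 0], minlength=n_classes).astype(float)
    counts[counts == 0] = 1.0
    w = 1.0 / counts
    return w * n_classes / w.sum()


@dataclass
class GCNNConfig:
    """Architecture and optimization settings of the graph classifier."""

    layers: int = 3
    hidden: int = 44
    heads: int = 4
    classes: int = 5
    gamma: float = 2.0
    alpha: np.ndarray | None = None  # default: inverse class frequency
    learning_rate: float = 1e-3
    epochs: int = 200
    folds: int = 10
    seed: int = 0
    attention: bool = True  # False: mean-aggregation graph convolution
    patience: int = 50

    def __post_init__(self) -> None:
        for name in ("layers", "hidden", "heads", "classes", "epochs", "folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


class GCNNModel:
    """Attention message-passing network with concatenated heads.

    Hidden layers concatenate the per-head outputs through an ELU; the
    final layer averages head logits into class scores.
    """

    def __init__(self, n_features: int, config: GCNNConfig, rng: np.random.Generator):
        self.config = config
        self.params: list[ad.Tensor] = []
        self.layer_shapes: list[tuple[int, int]] = []
        d_in = n_features
        for layer in range(config.layers):
            last = layer == config.layers - 1
            d_out = config.classes if last else config.hidden
            heads = []
            for _ in range(config.heads):
                scale = np.sqrt(2.0 / (d_in + d_out))
                W = ad.Tensor(rng.normal(0, scale, size=(d_in, d_out)), requires_grad=True)
                a_src = ad.Tensor(rng.normal(0, 0.1, size=(d_out, 1)), requires_grad=True)
                a_dst = ad.Tensor(rng.normal(0, 0.1, size=(d_out, 1)), requires_grad=True)
                heads.append((W, a_src, a_dst))
                self.params += [W, a_src, a_dst]
            self.layer_shapes.append((d_in, d_out))
            d_in = d_out * config.heads if not last else config.classes
        self.heads_per_layer = config.heads

    def _layer(self, h: ad.Tensor, heads, src, dst, n_nodes: int, last: bool) -> ad.Tensor:
        outs = []
        for W, a_src, a_dst in heads:
            z = ad.matmul(h, W)
            if self.config.attention:
                e_src = ad.gather(ad.matmul(z, a_src), src)
                e_dst = ad.gather(ad.matmul(z, a_dst), dst)
                e = ad.leaky_relu(ad.add(e_src, e_dst))
                # segment softmax over incoming edges of each destination
                seg_max = np.full(n_nodes, -np.inf)
                np.maximum.at(seg_max, dst, e.data[:, 0])
                e_shift = ad.sub(e, seg_max[dst][:, None])
                ex = ad.exp(e_shift)
                denom = ad.gather(ad.segment_sum(ex, dst, n_nodes), dst)
                att = ad.div(ex, denom)
                msg = ad.mul(ad.gather(z, src), att)
                agg = ad.segment_sum(msg, dst, n_nodes)
            else:
                deg = np.bincount(dst, minlength=n_nodes).astype(float)[:, None]
                agg = ad.div(ad.segment_sum(ad.gather(z, src), dst, n_nodes), deg)
            outs.append(agg)
        if last:
            total = outs[0]
            for o in outs[1:]:
                total = ad.add(total, o)
            return ad.mul(total, 1.0 / len(outs))
        return ad.elu(ad.concat(outs, axis=1))

    def forward(self, x: ad.Tensor, src, dst, n_nodes: int) -> ad.Tensor:
        """Class logits for every node."""
        h = x
        heads_per = 3 * self.heads_per_layer
        for layer in range(self.config.layers):
            heads = [
                tuple(self.params[layer * heads_per + 3 * k : layer * heads_per + 3 * k + 3])
                for k in range(self.heads_per_layer)
            ]
            h = self._layer(h, heads, src, dst, n_nodes, last=layer == self.config.layers - 1)
        return h

    def loss(self, x: ad.Tensor, graph: SampleGraph, labeled_idx: np.ndarray,
             alpha: np.ndarray) -> ad.Tensor:
        """Focal loss over the labeled nodes only (transductive)."""
        src, dst = graph.edges()
        logits = self.forward(x, src, dst, graph.n_nodes)
        probs = ad.softmax_rows(ad.gather(logits, labeled_idx))
        y = graph.y[labeled_idx]
        onehot = np.eye(self.config.classes)[y]
        p_y = ad.row_sum(ad.mul(probs, onehot))
        weight = -alpha[y][:, None]
        focal = ad.mul(weight, ad.mul(
            ad.pow_const(ad.sub(1.0, p_y), self.config.gamma),
            ad.log(ad.add(p_y, 1e-12)),
        ))
        return ad.mean_all(focal)

    def predict_proba(self, graph: SampleGraph, x: np.ndarray | None = None) -> np.ndarray:
        src, dst = graph.edges()
        inp = ad.Tensor(graph.X if x is None else x)
        logits = self.forward(inp, src, dst, graph.n_nodes).data
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


@dataclass
class TOOCVReport:
    fold_accuracies: list[float]
    best_fold: int
    converged: bool = True


def _fit(model: GCNNModel, graph: SampleGraph, labeled_idx: np.ndarray,
         config: GCNNConfig, alpha: np.ndarray) -> list[float]:
    opt = ad.Adam(model.params, lr=config.learning_rate)
    x = ad.Tensor(graph.X)
    history = []
    for _ in range(config.epochs):
        loss = model.loss(x, graph, labeled_idx, alpha)
        loss.backward()
        opt.step()
        history.append(float(loss.data))
    return history


def train_gcnn(graph: SampleGraph, config: GCNNConfig | None = None):
    """Transductive stratified 10-fold CV; the best-fold model is kept.

    In each fold the held-out labeled nodes are treated as unlabeled
    (message passing only); fold accuracy is measured on them.  Returns
    ``(model, report)`` with the model from the highest-accuracy fold.
    """
    config = config or GCNNConfig()
    labeled = np.where(graph.y >= 0)[0]
    if labeled.size == 0:
        raise ValueError("graph has no labeled nodes")
    y_lab = graph.y[labeled]
    alpha = (
        inverse_frequency_weights(graph.y, config.classes)
        if config.alpha is None
        else np.asarray(config.alpha, dtype=float)
    )
    k = min(config.folds, int(np.bincount(y_lab).min()))
    k = max(k, 2)
    skf = StratifiedKFold(k, shuffle=True, random_state=config.seed)

    best_model, best_acc, best_fold, accs = None, -1.0, -1, []
    converged = True
    for fold, (tr, te) in enumerate(skf.split(np.zeros(labeled.size), y_lab)):
        if np.unique(y_lab[tr]).size < config.classes:
            warnings.warn(f"fold {fold}: not every class present in training nodes")
        rng = np.random.default_rng(config.seed + fold)
        model = GCNNModel(graph.X.shape[1], config, rng)
        history = _fit(model, graph, labeled[tr], config, alpha)
        if len(history) > config.patience and not (
            min(history[-config.patience :]) < min(history[: -config.patience])
        ):
            converged = False
            warnings.warn(
                f"fold {fold}: loss plateaued (last {config.patience} epochs); "
                f"final loss {history[-1]:.4f}"
            )
        probs = model.predict_proba(graph)
        acc = float((probs[labeled[te]].argmax(axis=1) == y_lab[te]).mean())
        accs.append(acc)
        if acc > best_acc:
            best_model, best_acc, best_fold = model, acc, fold
    return best_model, TOOCVReport(fold_accuracies=accs, best_fold=best_fold,
                                   converged=converged)


def predict_too(model: GCNNModel, graph: SampleGraph, nodes=None):
    """Class probabilities and argmax label per requested node."""
    probs = model.predict_proba(graph)
    frame = pd.DataFrame(probs, index=graph.node_ids, columns=graph.class_names)
    if nodes is not None:
        missing = [n for n in nodes if n not in frame.index]
        if missing:
            raise KeyError(f"nodes absent from graph: {missing}")
        frame = frame.loc[list(nodes)]
    labels = frame.idxmax(axis=1)
    return frame, labels


def agreement_matrix(predicted: pd.Series, reference: pd.Series,
                     class_names: list[str]) -> pd.DataFrame:
    """Reference x predicted agreement, rows normalized to 1."""
    mat = pd.DataFrame(0.0, index=class_names, columns=class_names)
    for ref, pred in zip(reference, predicted):
        mat.loc[ref, pred] += 1
    sums = mat.sum(axis=1).replace(0, 1)
    return mat.div(sums, axis=0)


@dataclass
class ImportanceReport:
    """Per-class feature importance from the mask explainer."""

    scores: pd.DataFrame  # classes x features, values in [0, 1]
    threshold: float = DEFAULT_IMPORTANCE_CUTOFF
    important: dict[str, list[str]] = field(default_factory=dict)
    group_summary: pd.DataFrame | None = None


def explain_importance(
    model: GCNNModel,
    graph: SampleGraph,
    threshold: float = DEFAULT_IMPORTANCE_CUTOFF,
    steps: int = 120,
    learning_rate: float = 0.1,
    l1: float = 0.02,
    seed: int = 0,
) -> ImportanceReport:
    """Learn a sigmoid feature mask per class (mask-learning estimator).

    For each class the mask is optimized to keep that class's nodes
    confidently predicted from the masked features while an L1 penalty on
    the mask shrinks uninformative features; the sigmoid mask value in
    [0, 1] is the importance score, thresholded at 0.9.
    """
    src, dst = graph.edges()
    labeled = np.where(graph.y >= 0)[0]
    rows = {}
    for ci, cname in enumerate(graph.class_names):
        nodes = labeled[graph.y[labeled] == ci]
        if nodes.size == 0:
            rows[cname] = np.zeros(len(graph.feature_names))
            continue
        rng = np.random.default_rng(seed + ci)
        mask = ad.Tensor(rng.normal(0.0, 0.01, size=(1, graph.X.shape[1])),
                         requires_grad=True)
        opt = ad.Adam([mask], lr=learning_rate)
        for _ in range(steps):
            gate = ad.sigmoid(mask)
            x = ad.mul(ad.Tensor(graph.X), gate)
            logits = model.forward(x, src, dst, graph.n_nodes)
            probs = ad.softmax_rows(ad.gather(logits, nodes))
            p_c = ad.row_sum(ad.mul(probs, np.eye(model.config.classes)[ci][None, :]))
            fidelity = ad.mean_all(ad.log(ad.add(p_c, 1e-12)))
            sparsity = ad.mean_all(ad.sigmoid(mask))
            loss = ad.add(ad.mul(fidelity, -1.0), ad.mul(sparsity, l1))
            loss.backward()
            opt.step()
        rows[cname] = 1.0 / (1.0 + np.exp(-mask.data[0]))
    scores = pd.DataFrame(rows, index=graph.feature_names).T
    important = {
        c: scores.columns[scores.loc[c] > threshold].tolist() for c in scores.index
    }
    groups = [f.split(":", 1)[0] for f in graph.feature_names]
    summary = (
        scores.T.assign(group=groups).groupby("group").mean().T
    )
    return ImportanceReport(
        scores=scores, threshold=threshold, important=important, group_summary=summary
    )


def rf_too_baseline(features: pd.DataFrame, labels, seed: int = 0,
                    cv_folds: int = 10):
    """Class-weight-balanced random forest with 3-fold grid search.

    Returns ``(fitted model, fold accuracies)`` where accuracies come from
    stratified 10-fold CV.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    X = features.to_numpy(dtype=float)
    grid = {"n_estimators": [100, 300], "max_depth": [None, 10]}
    search = GridSearchCV(
        RandomForestClassifier(class_weight="balanced", random_state=seed, n_jobs=1),
        grid, cv=StratifiedKFold(3, shuffle=True, random_state=seed), n_jobs=1,
    )
    search.fit(X, y)
    k = min(cv_folds, int(pd.Series(y).value_counts().min()))
    accs = cross_val_score(
        search.best_estimator_, X, y,
        cv=StratifiedKFold(max(k, 2), shuffle=True, random_state=seed + 1),
        scoring="accuracy", n_jobs=1,
    )
    model = RandomForestClassifier(
        class_weight="balanced", random_state=seed, n_jobs=1, **search.best_params_
    ).fit(X, y)
    return model, accs
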