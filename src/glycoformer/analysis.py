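"""Structural similarity and downstream-evaluation utilities.

Two independent views of a glycan corpus are produced here:

* a Weisfeiler–Lehman (WL) subtree kernel over the raw trees — nodes are
  labeled by monosaccharide identity, bonds supply adjacency only, and ``h``
  rounds of neighborhood relabeling yield per-iteration label histograms
  whose dot products accumulate into an unnormalized kernel; cosine
  normalization then puts 1.0 on the diagonal;
* learned whole-glycan embeddings (the [Graph] token state of a pretrained
  encoder) evaluated with lightweight classifiers — an SVM and a
  gradient-boosting model — under randomized hyperparameter search with
  3-fold cross-validation on the train+validation pool, a single evaluation
  on the held-out test split, and mean +/- s.d. over replicate seeds.

Metrics are Macro-F1 (unweighted mean of per-class F1), accuracy, and for
binary tasks the area under the precision–recall curve computed with the
interpolated-precision envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import loguniform, randint
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import RandomizedSearchCV
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .graphs import GlycanGraph
from .model import GlycanEncoder, batch_tokenized
from .tokenizer import TokenizedGraph, Vocabulary, encode

__all__ = [
    "KernelMatrix", "EmbeddingMatrix", "wl_kernel", "embed_corpus",
    "benchmark_classify", "metrics", "auprc", "kernel_dendrogram",
    "pca_kmeans_clusters",
]


# ---------------------------------------------------------------------------
# WL subtree kernel

@dataclass(frozen=True)
class KernelMatrix:
    ids: tuple[str, ...]
    K: np.ndarray        # normalized, symmetric, unit diagonal
    h: int

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.K, index=list(self.ids),
                     columns=list(self.ids)).to_csv(path, sep="\t")


def _wl_histograms(graphs: Sequence[GlycanGraph], h: int):
    """Per-iteration label-count dicts for each graph, with a shared,
    order-independent label-compression table per iteration."""
    adj: list[list[list[int]]] = []
    labels: list[list[str]] = []
    for g in graphs:
        a: list[list[int]] = [[] for _ in g.nodes]
        for child, parent, _ in g.edges:
            a[child].append(parent)
            a[parent].append(child)
        adj.append(a)
        labels.append(list(g.nodes))

    all_hists: list[list[dict[str, int]]] = [[] for _ in graphs]
    for it in range(h + 1):
        for gi in range(len(graphs)):
            hist: dict[str, int] = {}
            for lab in labels[gi]:
                hist[lab] = hist.get(lab, 0) + 1
            all_hists[gi].append(hist)
        if it == h:
            break
        # relabel: new label = (own label, sorted neighbor labels), compressed
        signatures: list[list[str]] = []
        for gi in range(len(graphs)):
            sigs = []
            for v, lab in enumerate(labels[gi]):
                nbr = sorted(labels[gi][w] for w in adj[gi][v])
                sigs.append(lab + "|" + ",".join(nbr))
            signatures.append(sigs)
        table = {s: f"{it}:{j}" for j, s in enumerate(
            sorted({s for sigs in signatures for s in sigs}))}
        labels = [[table[s] for s in sigs] for sigs in signatures]
    return all_hists


def wl_kernel(
    graphs: Sequence[GlycanGraph], h: int = 3,
    ids: Sequence[str] | None = None,
) -> KernelMatrix:
    """Normalized WL subtree kernel matrix over glycan trees.

    Unnormalized ``k(g, g') = sum_{it=0..h} <hist_it(g), hist_it(g')>``;
    normalization divides by ``sqrt(k(g,g) k(g',g'))``.
    """
    if not graphs:
        raise ValueError("empty graph list")
    if any(g.n_nodes == 0 for g in graphs):
        raise ValueError("empty graph in input")
    if ids is None:
        ids = tuple(str(i) for i in range(len(graphs)))
    hists = _wl_histograms(graphs, h)

    n = len(graphs)
    raw = np.zeros((n, n))
    # sparse dot products over the union of labels per iteration
    for i in range(n):
        for j in range(i, n):
            s = 0
            for hi, hj in zip(hists[i], hists[j]):
                if len(hj) < len(hi):
                    hi, hj = hj, hi
                s += sum(c * hj.get(lab, 0) for lab, c in hi.items())
            raw[i, j] = raw[j, i] = s
    d = np.sqrt(np.diag(raw))
    K = raw / np.outer(d, d)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(ids=tuple(ids), K=K, h=h)


def kernel_dendrogram(km: KernelMatrix):
    """Average-linkage hierarchical clustering on 1 - K (reporting aid)."""
    dist = 1.0 - km.K
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return linkage(squareform(dist, checks=False), method="average")


# ---------------------------------------------------------------------------
# embeddings

@dataclass(frozen=True)
class EmbeddingMatrix:
    ids: tuple[str, ...]
    X: np.ndarray                 # (n, d) [Graph] embeddings
    checkpoint_fingerprint: str
    skipped: tuple[tuple[str, str], ...] = ()   # (id, reason)

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, index=list(self.ids))
        df.columns = [f"d{j}" for j in range(self.X.shape[1])]
        df.to_csv(path, sep="\t", index_label="id")


def embed_corpus(
    enc: GlycanEncoder,
    graphs: Sequence[GlycanGraph],
    vocab: Vocabulary,
    ids: Sequence[str] | None = None,
    batch_size: int = 64,
    fingerprint: str = "",
) -> EmbeddingMatrix:
    """Whole-glycan feature vectors: the [Graph] token's final state.

    Inference mode (no dropout), deterministic, order-preserving.  Glycans
    whose node count exceeds the identifier-bank capacity are skipped and
    recorded with a reason rather than failing the whole corpus.
    """
    if ids is None:
        ids = [str(i) for i in range(len(graphs))]
    kept_ids: list[str] = []
    tgs: list[TokenizedGraph] = []
    skipped: list[tuple[str, str]] = []
    for gid, g in zip(ids, graphs):
        if g.n_nodes > enc.cfg.max_nodes:
            skipped.append(
                (gid, f"{g.n_nodes} residues exceed capacity {enc.cfg.max_nodes}")
            )
            continue
        kept_ids.append(gid)
        tgs.append(encode(g, vocab))
    chunks = []
    for start in range(0, len(tgs), batch_size):
        batch = batch_tokenized(tgs[start:start + batch_size])
        out = enc.forward(batch)
        chunks.append(out.graph_embedding)
    X = np.vstack(chunks) if chunks else np.zeros((0, enc.cfg.d))
    return EmbeddingMatrix(ids=tuple(kept_ids), X=X,
                           checkpoint_fingerprint=fingerprint,
                           skipped=tuple(skipped))


# ---------------------------------------------------------------------------
# metrics

def auprc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision–recall curve, interpolated-precision form.

    Precision at each achievable recall level is replaced by the maximum
    precision at any recall >= that level (the PR envelope), then integrated
    stepwise over recall.  Equivalent to enumerating every score threshold.
    """
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must align")
    n_pos = int(y_true.sum())
    if n_pos == 0:
        raise ValueError("no positive examples")
    order = np.argsort(-scores, kind="stable")
    y = y_true[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep only the last index of each tied-score block
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    # envelope: running max of precision from high recall back to low
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - r_prev) * env))


def metrics(
    y_true: Sequence, y_pred: Sequence | None = None,
    scores: Sequence[float] | None = None,
) -> dict[str, float]:
    """Macro-F1 and accuracy from labels; AUPRC when binary scores given."""
    out: dict[str, float] = {}
    y_true = np.asarray(y_true)
    if y_pred is not None:
        y_pred = np.asarray(y_pred)
        if len(y_true) != len(y_pred):
            raise ValueError("length mismatch between y_true and y_pred")
        out["macro_f1"] = float(f1_score(y_true, y_pred, average="macro"))
        out["accuracy"] = float(accuracy_score(y_true, y_pred))
    if scores is not None:
        if len(y_true) != len(scores):
            raise ValueError("length mismatch between y_true and scores")
        out["auprc"] = auprc(y_true.astype(int), np.asarray(scores))
    return out


# ---------------------------------------------------------------------------
# classification harness

_SVM_SPACE = {
    "svc__kernel": ["rbf", "linear"],
    "svc__C": loguniform(1e-3, 1e2),
    "svc__gamma": loguniform(1e-4, 1e-1),
}

# gradient-boosting stand-in search space (tree-count, depth, leaves,
# learning rate and L2 ranges follow the usual boosted-tree grid)
_GBM_SPACE = {
    "max_iter": randint(100, 1001),
    "learning_rate": loguniform(0.01, 0.3),
    "max_leaf_nodes": randint(20, 151),
    "max_depth": randint(5, 21),
    "l2_regularization": loguniform(1e-2, 1e1),
}


def _make_estimator(model: str, seed: int, task_type: str):
    from sklearn.pipeline import Pipeline

    if model == "svm":
        est = Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(class_weight="balanced", random_state=seed)),
        ])
        return est, _SVM_SPACE, 10
    if model == "gbm":
        est = HistGradientBoostingClassifier(
            class_weight="balanced", random_state=seed,
            early_stopping=False,
        )
        return est, _GBM_SPACE, 15
    raise ValueError(f"unknown model {model!r}")


def benchmark_classify(
    features: EmbeddingMatrix | np.ndarray,
    labels: Sequence,
    split: dict[str, Sequence[int]],
    task_type: Literal["multiclass", "binary"] = "multiclass",
    model: Literal["svm", "gbm"] = "svm",
    n_seeds: int = 3,
    base_seed: int = 0,
    n_iter: int | None = None,
) -> pd.DataFrame:
    """Fixed-split classification benchmark on glycan embeddings.

    Hyperparameters are selected by randomized search (10 draws for the SVM,
    15 for gradient boosting) with 3-fold CV on train+validation; the best
    model is refit there and evaluated once on the test indices.  The whole
    procedure repeats over ``n_seeds`` seeds; the returned table holds the
    per-seed metrics plus a mean +/- s.d. summary row per metric.
    """
    X = features.X if isinstance(features, EmbeddingMatrix) else np.asarray(features)
    y = np.asarray(labels)
    if len(X) != len(y):
        raise ValueError("features and labels must align")
    tr = np.asarray(split["train"], dtype=int)
    va = np.asarray(split["val"], dtype=int)
    te = np.asarray(split["test"], dtype=int)
    pool = np.concatenate([tr, va])
    train_classes = set(np.unique(y[pool]))
    missing = set(np.unique(y)) - train_classes
    if missing:
        raise ValueError(f"classes absent from training pool: {sorted(missing)}")

    rows = []
    for rep in range(n_seeds):
        seed = base_seed + rep
        est, space, default_iter = _make_estimator(model, seed, task_type)
        search = RandomizedSearchCV(
            est, space, n_iter=n_iter or default_iter, cv=3,
            scoring="f1_macro" if task_type == "multiclass" else "average_precision",
            random_state=seed, n_jobs=1, refit=True,
        )
        search.fit(X[pool], y[pool])
        best = search.best_estimator_
        y_pred = best.predict(X[te])
        row = {"seed": seed, "model": model}
        row.update(metrics(y[te], y_pred))
        if task_type == "binary":
            if hasattr(best, "decision_function"):
                scores = best.decision_function(X[te])
            else:
                scores = best.predict_proba(X[te])[:, 1]
            row["auprc"] = auprc(y[te].astype(int), scores)
        rows.append(row)
    df = pd.DataFrame(rows)
    summary = {"seed": "mean±sd", "model": model}
    for col in df.columns:
        if col in ("seed", "model"):
            continue
        summary[col] = f"{df[col].mean():.4f}±{df[col].std(ddof=1):.4f}"
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)


# ---------------------------------------------------------------------------
# clustering utility (inputs to downstream motif work)

def pca_kmeans_clusters(
    X: np.ndarray, n_components: int = 50, k: int = 6, seed: int = 0
) -> np.ndarray:
    """PCA to ``min(n_components, rank)`` dims then k-means labels."""
    n_components = min(n_components, X.shape[0], X.shape[1])
    Z = PCA(n_components=n_components, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(Z)
    return km.labels_
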