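"""RBF-kernel SVM training, cross-validation and site prediction.

Classifiers are soft-margin support vector machines with a radial basis
function kernel.  ``gamma`` sets the kernel width and ``cost`` (the SVM C
parameter) the softness of the margin; both are tuned by grid search over
the usual exponential grids.  Models are evaluated with repeated
stratified five-fold cross-validation: within each run every sample is
tested exactly once and the five folds' predictions are pooled into a
single confusion matrix.

Two model layouts exist: a single whole-set classifier, or one
classifier per MDD leaf subgroup, each trained on that leaf's positives
against an equal number of negatives routed to the same leaf.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import encode
from .mdd import MddTree, assign_subgroup
from .seqio import Fragment, ProteinRecord, enumerate_lysine_fragments

#: Default tuning grids: gamma 2^-15 … 2^3 and cost 2^-5 … 2^15 in
#: powers of 4.
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))
DEFAULT_COST_GRID = tuple(2.0**e for e in range(-5, 16, 2))


@dataclass
class MetricsReport:
    """Confusion counts plus the five standard binary metrics.

    A metric whose denominator is zero is reported as ``None`` (MCC as
    0.0 with ``mcc_defined=False``).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sn: float | None
    sp: float | None
    pre: float | None
    acc: float | None
    mcc: float
    mcc_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "Sn": self.sn, "Sp": self.sp, "Pre": self.pre,
            "Acc": self.acc, "MCC": self.mcc,
        }


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> MetricsReport:
    """Sn, Sp, Pre, Acc and Matthews correlation from confusion counts.

    Sn = TP/(TP+FN); Sp = TN/(TN+FP); Pre = TP/(TP+FP);
    Acc = (TP+TN)/total; MCC = (TP·TN − FN·FP) / √((TP+FN)(TN+FP)(TP+FP)(TN+FN)).
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative, got {v}")
    total = tp + fp + tn + fn
    if total < 1:
        raise ValueError("at least one count must be positive")
    sn = tp / (tp + fn) if (tp + fn) else None
    sp = tn / (tn + fp) if (tn + fp) else None
    pre = tp / (tp + fp) if (tp + fp) else None
    acc = (tp + tn) / total
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    if denom:
        mcc = (tp * tn - fn * fp) / math.sqrt(denom)
        return MetricsReport(tp, fp, tn, fn, sn, sp, pre, acc, mcc)
    return MetricsReport(tp, fp, tn, fn, sn, sp, pre, acc, 0.0, mcc_defined=False)


@dataclass
class TrainedModel:
    """A fitted RBF-SVM plus the feature specification it was trained with."""

    scheme: str
    gamma: float
    cost: float
    classifier: SVC
    subgroup: int | None = None
    n_positive: int = 0
    n_negative: int = 0
    seed: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict(X)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.decision_function(X)


def _as_binary(y: Sequence) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "UO":
        arr = (arr == "positive").astype(int)
    return arr.astype(int)


def train_classifier(
    X: np.ndarray, y: Sequence, gamma: float, cost: float, seed: int = 0
) -> TrainedModel:
    """Fit a soft-margin RBF-SVM; both classes must be present."""
    if gamma <= 0 or cost <= 0:
        raise ValueError("gamma and cost must be positive")
    yb = _as_binary(y)
    if len(set(yb.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    clf = SVC(kernel="rbf", gamma=gamma, C=cost, random_state=seed)
    clf.fit(X, yb)
    return TrainedModel(
        scheme="", gamma=gamma, cost=cost, classifier=clf,
        n_positive=int(yb.sum()), n_negative=int((1 - yb).sum()), seed=seed,
    )


def _cv_accuracy(
    X: np.ndarray, yb: np.ndarray, gamma: float, cost: float, k: int, seed: int
) -> float:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, yb):
        clf = SVC(kernel="rbf", gamma=gamma, C=cost)
        clf.fit(X[train_idx], yb[train_idx])
        correct += int((clf.predict(X[test_idx]) == yb[test_idx]).sum())
    return correct / len(yb)


def grid_search(
    X: np.ndarray,
    y: Sequence,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    k: int = 5,
    seed: int = 1,
) -> tuple[float, float, float]:
    """Pick (gamma, cost) maximizing mean k-fold CV accuracy.

    Ties are broken toward the smallest cost, then the smallest gamma, so
    the result is deterministic.
    """
    if not gamma_grid or not cost_grid:
        raise ValueError("grids must be nonempty")
    yb = _as_binary(y)
    best: tuple[float, float, float] | None = None  # (acc, -cost, -gamma)
    for cost in sorted(cost_grid):
        for gamma in sorted(gamma_grid):
            acc = _cv_accuracy(X, yb, gamma, cost, k, seed)
            key = (acc, -cost, -gamma)
            if best is None or key > best[0]:
                best = (key, gamma, cost)
    key, gamma, cost = best
    return gamma, cost, key[0]


def cross_validate(
    X: np.ndarray,
    y: Sequence,
    gamma: float,
    cost: float,
    k: int = 5,
    runs: int = 30,
    seed: int = 1,
) -> tuple[list[MetricsReport], dict]:
    """Repeated stratified k-fold CV; one pooled confusion matrix per run.

    Returns the per-run reports and a summary with per-metric mean and
    standard deviation plus the best run (highest pooled accuracy).
    """
    yb = _as_binary(y)
    counts = np.bincount(yb, minlength=2)
    if counts.min() < k:
        raise ValueError(f"need at least k={k} samples per class, got {counts.tolist()}")
    reports: list[MetricsReport] = []
    for run in range(runs):
        run_seed = (seed + run) % (2**31 - 1)
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=run_seed)
        pred = np.empty_like(yb)
        for train_idx, test_idx in skf.split(X, yb):
            clf = SVC(kernel="rbf", gamma=gamma, C=cost)
            clf.fit(X[train_idx], yb[train_idx])
            pred[test_idx] = clf.predict(X[test_idx])
        tp = int(((pred == 1) & (yb == 1)).sum())
        fp = int(((pred == 1) & (yb == 0)).sum())
        tn = int(((pred == 0) & (yb == 0)).sum())
        fn = int(((pred == 0) & (yb == 1)).sum())
        reports.append(compute_metrics(tp, fp, tn, fn))

    def _column(attr: str) -> np.ndarray:
        return np.array([getattr(r, attr) for r in reports], dtype=float)

    best_idx = int(np.argmax(_column("acc")))
    summary = {
        "runs": runs,
        "k": k,
        "best_run": best_idx,
        "best": reports[best_idx].as_dict(),
        "mean": {m: float(np.nanmean(_column(a)))
                 for m, a in (("Sn", "sn"), ("Sp", "sp"), ("Pre", "pre"),
                              ("Acc", "acc"), ("MCC", "mcc"))},
        "sd": {m: float(np.nanstd(_column(a)))
               for m, a in (("Sn", "sn"), ("Sp", "sp"), ("Pre", "pre"),
                            ("Acc", "acc"), ("MCC", "mcc"))},
    }
    return reports, summary


def leaf_training_sets(
    tree: MddTree,
    negatives: Sequence[Fragment],
    seed: int = 1,
) -> dict[int, tuple[list[Fragment], list[Fragment]]]:
    """Per-leaf balanced (positives, negatives) fragment sets.

    Negatives are routed down the tree so each leaf model sees negatives
    with the same flank context; when too few route to a leaf, the
    shortfall is filled by a seeded random draw from the remaining
    negatives.
    """
    rng = np.random.default_rng(seed)
    routed: dict[int, list[Fragment]] = {leaf.id: [] for leaf in tree.leaves()}
    for frag in negatives:
        routed[assign_subgroup(tree, frag)].append(frag)
    out: dict[int, tuple[list[Fragment], list[Fragment]]] = {}
    for leaf in tree.leaves():
        if leaf.size < 2:
            raise ValueError(
                f"leaf {leaf.id} has {leaf.size} positives; "
                "increase max_cluster_size to get trainable subgroups"
            )
        need = leaf.size
        pool = routed[leaf.id]
        if len(pool) >= need:
            idx = rng.choice(len(pool), size=need, replace=False)
            negs = [pool[i] for i in sorted(idx)]
        else:
            negs = list(pool)
            others = [f for f in negatives if f not in set(pool)]
            extra = rng.choice(len(others), size=need - len(pool), replace=False)
            negs += [others[i] for i in sorted(extra)]
        out[leaf.id] = (list(leaf.members), negs)
    return out


def train_mdd_models(
    tree: MddTree,
    negatives: Sequence[Fragment],
    scheme: str,
    gamma: float,
    cost: float,
    seed: int = 1,
    context: encode.EncodingContext | None = None,
) -> dict[int, TrainedModel]:
    """Train one balanced classifier per MDD leaf subgroup."""
    models: dict[int, TrainedModel] = {}
    for leaf_id, (pos, negs) in leaf_training_sets(tree, negatives, seed).items():
        X = encode.encode_fragments(pos + negs, scheme, context)
        y = [1] * len(pos) + [0] * len(negs)
        model = train_classifier(X, y, gamma, cost, seed)
        model.scheme = scheme
        model.subgroup = leaf_id
        models[leaf_id] = model
    return models


def predict_sites(
    model: TrainedModel | Mapping[int, TrainedModel],
    protein: ProteinRecord,
    n: int = 7,
    context: encode.EncodingContext | None = None,
    tree: MddTree | None = None,
) -> pd.DataFrame:
    """Score every lysine in *protein*.

    With a single model every fragment is scored directly; with a
    leaf-id → model mapping each fragment is first routed through *tree*.
    Returns a DataFrame with columns protein_id, position, window,
    subgroup, score, call.
    """
    fragments = enumerate_lysine_fragments(protein, n)
    rows = []
    for frag in fragments:
        if isinstance(model, Mapping):
            if tree is None:
                raise ValueError("a leaf-map of models requires the MDD tree")
            leaf_id = assign_subgroup(tree, frag)
            leaf_model = model[leaf_id]
        else:
            leaf_id = None
            leaf_model = model
        X = encode.encode_fragments([frag], leaf_model.scheme, context)
        score = float(leaf_model.decision_scores(X)[0])
        rows.append(
            {
                "protein_id": frag.protein_id,
                "position": frag.center,
                "window": frag.window,
                "subgroup": leaf_id,
                "score": score,
                "call": "positive" if score > 0 else "negative",
            }
        )
    columns = ["protein_id", "position", "window", "subgroup", "score", "call"]
    return pd.DataFrame(rows, columns=columns)


def save_bundle(
    directory: str | Path,
    scheme: str,
    n: int,
    model: TrainedModel | None = None,
    tree: MddTree | None = None,
    leaf_models: Mapping[int, TrainedModel] | None = None,
    metadata: dict | None = None,
) -> None:
    """Persist a model bundle: manifest JSON, tree JSON, classifier dumps."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "scheme": scheme,
        "n": n,
        "kind": "mdd" if leaf_models is not None else "single",
        "metadata": metadata or {},
    }
    if leaf_models is not None:
        if tree is None:
            raise ValueError("leaf models require the MDD tree")
        tree.save_json(directory / "tree.json")
        manifest["leaves"] = sorted(leaf_models)
        for leaf_id, m in leaf_models.items():
            joblib.dump(m, directory / f"leaf_{leaf_id}.joblib")
    else:
        if model is None:
            raise ValueError("provide either a single model or leaf models")
        joblib.dump(model, directory / "model.joblib")
    with open(directory / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2)


def load_bundle(directory: str | Path):
    """Load a bundle saved by :func:`save_bundle`.

    Returns ``(manifest, model_or_leaf_map, tree_dict_or_None)``.
    """
    directory = Path(directory)
    with open(directory / "manifest.json") as handle:
        manifest = json.load(handle)
    if manifest["kind"] == "mdd":
        with open(directory / "tree.json") as handle:
            tree = MddTree.from_dict(json.load(handle))
        leaf_models = {
            leaf_id: joblib.load(directory / f"leaf_{leaf_id}.joblib")
            for leaf_id in manifest["leaves"]
        }
        return manifest, leaf_models, tree
    return manifest, joblib.load(directory / "model.joblib"), None
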