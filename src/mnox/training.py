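"""Feature-table curation, K-means label correction, and classifiers.

The training unit of exchange is a :class:`LabeledFeatureTable` of rows
(id, E, A, label) with label in {II, III, IV}.  Labels coming from curated
databases contain mistakes; ``kmeans_relabel`` replaces them with the
cluster memberships of a k=3 K-means fit in (E, A) space.  Two classifiers
are provided: a Gaussian naive Bayes fitted from per-class sample
statistics, and an entropy-criterion decision tree (fitted via
scikit-learn, then frozen into a plain node table so models serialize to
JSON and predict without scikit-learn objects).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry_features import OctahedralFeatures

logger = logging.getLogger(__name__)

#: Canonical class order used everywhere (confusion matrices, priors, ...).
LABELS: tuple[str, str, str] = ("II", "III", "IV")
LABEL_TO_CHARGE = {"II": 2, "III": 3, "IV": 4}
FEATURES = ("E", "A")

#: Variance floor (Å²) applied to per-class feature variances in GNB.
VARIANCE_FLOOR = 1e-9

MODEL_FORMAT_VERSION = 1


class TrainingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

@dataclass
class LabeledFeatureTable:
    """Rows of (record_id, E, A, label) plus optional curation metadata."""

    df: pd.DataFrame

    REQUIRED = ("id", "E", "A", "label")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise TrainingError(f"feature table missing columns {missing}")
        bad = set(self.df["label"]) - set(LABELS)
        if bad:
            raise TrainingError(f"labels outside {LABELS}: {sorted(bad)}")
        if self.df[["E", "A"]].isna().any().any():
            raise TrainingError("missing E/A values")
        if self.df["id"].duplicated().any():
            raise TrainingError("record ids are not unique")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def X(self) -> np.ndarray:
        return self.df[["E", "A"]].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=object)

    def class_counts(self) -> dict[str, int]:
        counts = self.df["label"].value_counts()
        return {lab: int(counts.get(lab, 0)) for lab in LABELS}

    def with_labels(self, labels: Sequence[str]) -> "LabeledFeatureTable":
        if len(labels) != len(self.df):
            raise TrainingError("label vector length mismatch")
        df = self.df.copy()
        df["label"] = list(labels)
        return LabeledFeatureTable(df)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledFeatureTable":
        return cls(pd.read_csv(path, dtype={"label": str, "id": str}))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def curate(
    table: LabeledFeatureTable,
    max_r_factor: float | None = 0.075,
    require_error_free: bool = False,
) -> LabeledFeatureTable:
    """Apply the curation filters; row order is preserved.

    Rows with ``r_factor >= max_r_factor`` are removed (the boundary value
    itself is excluded); rows with falsy ``error_free`` are removed when
    ``require_error_free`` is set.  Requesting a filter whose metadata
    column is absent is an explicit error.
    """
    df = table.df
    if max_r_factor is not None:
        if "r_factor" not in df.columns:
            raise TrainingError("r_factor filter requested but column 'r_factor' absent")
        df = df[df["r_factor"].astype(float) < max_r_factor]
    if require_error_free:
        if "error_free" not in df.columns:
            raise TrainingError("error_free filter requested but column 'error_free' absent")
        df = df[df["error_free"].astype(bool)]
    return LabeledFeatureTable(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# K-means label correction
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """A fitted k=3 K-means in (E, A) space with a cluster→label bijection."""

    centers: np.ndarray            # shape (3, 2), rows in cluster-index order
    cluster_to_label: dict[int, str]
    inertia: float

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.shape != (3, 2):
            raise TrainingError("expected 3 centers in 2-D")
        if sorted(self.cluster_to_label.values()) != sorted(LABELS):
            raise TrainingError("cluster→label mapping must be a bijection onto the 3 classes")

    def center_of(self, label: str) -> np.ndarray:
        for idx, lab in self.cluster_to_label.items():
            if lab == label:
                return self.centers[idx]
        raise KeyError(label)

    def assign(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d = np.linalg.norm(X[:, None, :] - self.centers[None, :, :], axis=2)
        idx = np.argmin(d, axis=1)
        return np.array([self.cluster_to_label[int(i)] for i in idx], dtype=object)


def kmeans_relabel(
    table: LabeledFeatureTable, seed: int = 0, n_init: int = 10,
) -> tuple[ClusterModel, LabeledFeatureTable]:
    """Cluster (E, A) with k=3 K-means and relabel every row by its cluster.

    Clusters are mapped to labels by descending E+A of their centers:
    longest bonds → II, shortest → IV.  The fit is run to a strict fixed
    point (tol=0), so each returned center is the mean of its assigned
    points and each point is nearest its own center.
    """
    from sklearn.cluster import KMeans

    X = table.X
    if len(np.unique(X, axis=0)) < 3:
        raise TrainingError("need at least 3 distinct (E, A) points for k=3 clustering")
    km = KMeans(n_clusters=3, n_init=n_init, random_state=seed, tol=0.0, max_iter=1000)
    assignments = km.fit_predict(X)
    order = np.argsort(-km.cluster_centers_.sum(axis=1))  # descending E+A
    mapping = {int(cluster): LABELS[rank] for rank, cluster in enumerate(order)}
    model = ClusterModel(km.cluster_centers_, mapping, float(km.inertia_))
    labels = [mapping[int(c)] for c in assignments]
    return model, table.with_labels(labels)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

@dataclass
class OxidationModel:
    """A fitted oxidation-state classifier, serializable to JSON.

    ``kind`` is ``"gnb"`` (per-class priors/means/variances over the two
    features) or ``"dt"`` (a frozen binary tree in flat-array form).
    Prediction is implemented here directly, so a model loaded from JSON
    needs no fitted third-party estimator.
    """

    kind: str
    gnb_priors: np.ndarray | None = None        # (3,) in LABELS order
    gnb_means: np.ndarray | None = None         # (3, 2)
    gnb_vars: np.ndarray | None = None          # (3, 2)
    dt_children_left: list[int] | None = None
    dt_children_right: list[int] | None = None
    dt_feature: list[int] | None = None         # -1 at leaves
    dt_threshold: list[float] | None = None
    dt_leaf_label: list[str | None] | None = None
    cluster_centers: np.ndarray | None = None
    cluster_center_labels: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    # -- prediction --------------------------------------------------------

    def _as_X(self, features) -> np.ndarray:
        if isinstance(features, OctahedralFeatures):
            X = features.as_array()[None, :]
        else:
            X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[1] != 2:
            raise TrainingError("expected two features (E, A)")
        return X

    def joint_log_likelihood(self, features) -> np.ndarray:
        if self.kind != "gnb":
            raise TrainingError("posterior only defined for gnb models")
        X = self._as_X(features)
        out = np.empty((len(X), 3))
        for c in range(3):
            var = self.gnb_vars[c]
            out[:, c] = (
                np.log(self.gnb_priors[c])
                - 0.5 * np.sum(np.log(2.0 * np.pi * var))
                - 0.5 * np.sum((X - self.gnb_means[c]) ** 2 / var, axis=1)
            )
        return out

    def predict_proba(self, features) -> np.ndarray:
        jll = self.joint_log_likelihood(features)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def _walk(self, x: np.ndarray) -> str:
        node = 0
        while self.dt_leaf_label[node] is None:
            if x[self.dt_feature[node]] <= self.dt_threshold[node]:
                node = self.dt_children_left[node]
            else:
                node = self.dt_children_right[node]
        return self.dt_leaf_label[node]

    def predict(self, features) -> np.ndarray:
        X = self._as_X(features)
        if self.kind == "gnb":
            idx = np.argmax(self.joint_log_likelihood(X), axis=1)
            return np.array([LABELS[i] for i in idx], dtype=object)
        if self.kind == "dt":
            return np.array([self._walk(x) for x in X], dtype=object)
        raise TrainingError(f"unknown model kind {self.kind!r}")

    def predict_one(self, features) -> str:
        return str(self.predict(features)[0])

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "format_version": MODEL_FORMAT_VERSION,
            "kind": self.kind,
            "labels": list(LABELS),
            "gnb": None if self.kind != "gnb" else {
                "priors": arr(self.gnb_priors),
                "means": arr(self.gnb_means),
                "variances": arr(self.gnb_vars),
            },
            "dt": None if self.kind != "dt" else {
                "children_left": self.dt_children_left,
                "children_right": self.dt_children_right,
                "feature": self.dt_feature,
                "threshold": [None if not np.isfinite(v) else v for v in self.dt_threshold],
                "leaf_label": self.dt_leaf_label,
            },
            "cluster_centers": arr(self.cluster_centers),
            "cluster_center_labels": self.cluster_center_labels,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OxidationModel":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise TrainingError(f"unsupported model format version {d.get('format_version')!r}")
        model = cls(kind=d["kind"], provenance=d.get("provenance", {}))
        if d.get("gnb"):
            model.gnb_priors = np.asarray(d["gnb"]["priors"], float)
            model.gnb_means = np.asarray(d["gnb"]["means"], float)
            model.gnb_vars = np.asarray(d["gnb"]["variances"], float)
        if d.get("dt"):
            t = d["dt"]
            model.dt_children_left = list(t["children_left"])
            model.dt_children_right = list(t["children_right"])
            model.dt_feature = list(t["feature"])
            model.dt_threshold = [float("nan") if x is None else float(x) for x in t["threshold"]]
            model.dt_leaf_label = list(t["leaf_label"])
        if d.get("cluster_centers") is not None:
            model.cluster_centers = np.asarray(d["cluster_centers"], float)
            model.cluster_center_labels = d.get("cluster_center_labels")
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "OxidationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_gnb(table: LabeledFeatureTable, provenance: dict | None = None) -> OxidationModel:
    """Gaussian naive Bayes from per-class sample statistics.

    Per class and feature the mean and (ddof=0) variance are the sample
    statistics of that class; priors are class frequencies.  Zero
    variances are floored at ``VARIANCE_FLOOR`` and logged.
    """
    X, y = table.X, table.y
    counts = table.class_counts()
    for lab in LABELS:
        if counts[lab] < 2:
            raise TrainingError(f"class {lab} has {counts[lab]} rows; >= 2 required")
    priors = np.array([counts[lab] / len(table) for lab in LABELS])
    means = np.vstack([X[y == lab].mean(axis=0) for lab in LABELS])
    vars_ = np.vstack([X[y == lab].var(axis=0, ddof=0) for lab in LABELS])
    if np.any(vars_ < VARIANCE_FLOOR):
        logger.warning("flooring %d zero/near-zero class variances at %.1e",
                       int(np.sum(vars_ < VARIANCE_FLOOR)), VARIANCE_FLOOR)
        vars_ = np.maximum(vars_, VARIANCE_FLOOR)
    return OxidationModel(
        kind="gnb", gnb_priors=priors, gnb_means=means, gnb_vars=vars_,
        provenance=provenance or {},
    )


def fit_dt(
    table: LabeledFeatureTable,
    criterion: str = "entropy",
    max_depth: int | None = None,
    seed: int = 0,
    provenance: dict | None = None,
) -> OxidationModel:
    """Entropy-criterion decision tree, frozen into a flat node table.

    Greedy binary splits maximizing information gain; leaves carry the
    majority class.  With no depth limit and no contradictory duplicate
    rows, training accuracy is 100%.
    """
    from sklearn.tree import DecisionTreeClassifier

    X, y = table.X, table.y
    if len(table) == 0:
        raise TrainingError("empty table")
    clf = DecisionTreeClassifier(criterion=criterion, max_depth=max_depth, random_state=seed)
    clf.fit(X, y)
    tree = clf.tree_
    classes = list(clf.classes_)
    leaf_label: list[str | None] = []
    for node in range(tree.node_count):
        if tree.children_left[node] == -1:
            leaf_label.append(str(classes[int(np.argmax(tree.value[node][0]))]))
        else:
            leaf_label.append(None)
    return OxidationModel(
        kind="dt",
        dt_children_left=[int(v) for v in tree.children_left],
        dt_children_right=[int(v) for v in tree.children_right],
        dt_feature=[int(v) if leaf_label[i] is None else -1
                    for i, v in enumerate(tree.feature)],
        dt_threshold=[float(v) if leaf_label[i] is None else float("nan")
                      for i, v in enumerate(tree.threshold)],
        dt_leaf_label=leaf_label,
        provenance=provenance or {},
    )


def attach_cluster_model(model: OxidationModel, cluster_model: ClusterModel) -> OxidationModel:
    """Record the cluster centers/mapping a model was trained against."""
    model.cluster_centers = cluster_model.centers.copy()
    model.cluster_center_labels = [
        cluster_model.cluster_to_label[i] for i in range(3)
    ]
    return model


def predict(model: OxidationModel, features) -> str:
    """Predict the oxidation label for one (E, A) feature pair."""
    return model.predict_one(features)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    accuracy: float
    confusion: np.ndarray                 # rows true, cols predicted, LABELS order
    fold_scores: list[float] | None = None

    @property
    def fold_mean(self) -> float | None:
        return None if self.fold_scores is None else float(np.mean(self.fold_scores))

    @property
    def fold_std(self) -> float | None:
        return None if self.fold_scores is None else float(np.std(self.fold_scores))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    from sklearn.metrics import confusion_matrix

    return confusion_matrix(y_true, y_pred, labels=list(LABELS))


def _fit(kind: str, table: LabeledFeatureTable, seed: int, **fit_kwargs) -> OxidationModel:
    if kind == "gnb":
        return fit_gnb(table, **fit_kwargs)
    if kind == "dt":
        return fit_dt(table, seed=seed, **fit_kwargs)
    raise TrainingError(f"unknown classifier kind {kind!r}")


def evaluate(
    kind: str,
    table: LabeledFeatureTable,
    scheme: str = "holdout:0.25",
    seed: int = 0,
    **fit_kwargs,
) -> EvaluationResult:
    """Evaluate a classifier under a holdout or k-fold scheme.

    ``scheme`` is ``"holdout:<test_fraction>"`` (random split) or
    ``"kfold:<k>"`` (shuffled stratified folds; mean/std over folds are
    exposed on the result).  The confusion matrix is accumulated over all
    test rows in class order (II, III, IV).
    """
    from sklearn.model_selection import StratifiedKFold, train_test_split

    if len(table) == 0:
        raise TrainingError("empty table")
    name, _, arg = scheme.partition(":")

    if name == "holdout":
        test_fraction = float(arg) if arg else 0.25
        if not 0.0 < test_fraction < 1.0:
            raise TrainingError("test fraction must be in (0, 1)")
        idx_train, idx_test = train_test_split(
            np.arange(len(table)), test_size=test_fraction, random_state=seed, shuffle=True)
        train = LabeledFeatureTable(table.df.iloc[idx_train])
        test = LabeledFeatureTable(table.df.iloc[idx_test])
        model = _fit(kind, train, seed, **fit_kwargs)
        y_pred = model.predict(test.X)
        conf = _confusion(test.y, y_pred)
        return EvaluationResult(accuracy=float(np.trace(conf) / conf.sum()), confusion=conf)

    if name == "kfold":
        k = int(arg) if arg else 10
        if k < 2:
            raise TrainingError("kfold requires k >= 2")
        min_class = min(c for c in table.class_counts().values() if c > 0)
        if k > min_class:
            raise TrainingError(f"k={k} exceeds smallest class count {min_class}")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        scores: list[float] = []
        conf = np.zeros((3, 3), dtype=int)
        for idx_train, idx_test in skf.split(table.X, table.y):
            train = LabeledFeatureTable(table.df.iloc[idx_train])
            test = LabeledFeatureTable(table.df.iloc[idx_test])
            model = _fit(kind, train, seed, **fit_kwargs)
            y_pred = model.predict(test.X)
            fold_conf = _confusion(test.y, y_pred)
            conf += fold_conf
            scores.append(float(np.trace(fold_conf) / fold_conf.sum()))
        return EvaluationResult(
            accuracy=float(np.trace(conf) / conf.sum()), confusion=conf, fold_scores=scores)

    raise TrainingError(f"unknown evaluation scheme {scheme!r}")


# ---------------------------------------------------------------------------
# decision-tree rule export
# ---------------------------------------------------------------------------

def export_dt_rules(model: OxidationModel) -> list[str]:
    """Render a decision tree as indented if/else rules, depth-first.

    Thresholds are printed with ``repr`` so the text round-trips exactly;
    :func:`parse_dt_rules` inverts this rendering.
    """
    if model.kind != "dt":
        raise TrainingError("rule export only defined for dt models")

    lines: list[str] = []

    def emit(node: int, depth: int) -> None:
        pad = "    " * depth
        if model.dt_leaf_label[node] is not None:
            lines.append(f"{pad}return {model.dt_leaf_label[node]}")
            return
        feat = FEATURES[model.dt_feature[node]]
        lines.append(f"{pad}if {feat} <= {model.dt_threshold[node]!r}:")
        emit(model.dt_children_left[node], depth + 1)
        lines.append(f"{pad}else:")
        emit(model.dt_children_right[node], depth + 1)

    emit(0, 0)
    return lines


def parse_dt_rules(lines: Sequence[str]) -> OxidationModel:
    """Rebuild a dt model from the textual rules of :func:`export_dt_rules`."""
    children_left: list[int] = []
    children_right: list[int] = []
    feature: list[int] = []
    threshold: list[float] = []
    leaf_label: list[str | None] = []

    def new_node() -> int:
        children_left.append(-1)
        children_right.append(-1)
        feature.append(-1)
        threshold.append(float("nan"))
        leaf_label.append(None)
        return len(leaf_label) - 1

    pos = 0

    def parse(depth: int) -> int:
        nonlocal pos
        pad = "    " * depth
        line = lines[pos]
        if not line.startswith(pad):
            raise TrainingError(f"bad indentation at line {pos}: {line!r}")
        body = line[len(pad):]
        node = new_node()
        if body.startswith("return "):
            pos += 1
            leaf_label[node] = body[len("return "):].strip()
            return node
        if not body.startswith("if "):
            raise TrainingError(f"cannot parse rule line {pos}: {line!r}")
        cond = body[3:].rstrip(":")
        feat_name, _, thr = cond.partition(" <= ")
        feature[node] = FEATURES.index(feat_name.strip())
        threshold[node] = float(thr)
        pos += 1
        children_left[node] = parse(depth + 1)
        if lines[pos] != f"{pad}else:":
            raise TrainingError(f"expected else at line {pos}")
        pos += 1
        children_right[node] = parse(depth + 1)
        return node

    parse(0)
    if pos != len(lines):
        raise TrainingError("trailing unparsed rule lines")
    return OxidationModel(
        kind="dt", dt_children_left=children_left, dt_children_right=children_right,
        dt_feature=feature, dt_threshold=threshold, dt_leaf_label=leaf_label)
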