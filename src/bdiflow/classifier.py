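"""Triplet-embedding response classifier with one-left-out validation.

Twenty standardized biomarkers feed a minimal fully connected network of
layer sizes 20 → 20 → 10 → 3 (two hidden layers, linear output) trained with
Adam on a triplet loss,

    L(a, p, n) = max(0, ‖f(a) − f(p)‖² − ‖f(a) − f(n)‖² + m),

so that same-grade patients embed close together and different grades are
pushed apart beyond the margin ``m``. The 3-D embedding of the training
patients is clustered with k-means (k = 3); each cluster takes the majority
grade of its training members, and a patient's class likelihoods are the
softmax of negative squared centroid distances at a temperature set to the
mean within-cluster squared distance. The dominant likelihood is the
prediction.

Validation is one-left-out (OLO): each graded patient in turn is held out,
biomarker selection / standardization / training / clustering all happen on
the remaining patients only, and the held-out patient is then scored.
Ungraded patients are classified by every fold's model and averaged; they
are never trained on and never scored. The network, its gradients, and the
Adam update are implemented directly in NumPy — the model is small enough
that an autodiff framework would add nothing but weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .biomarkers import FeatureMatrix, select_biomarkers
from .synthetic import GRADES, GRADE_ORDINAL

__all__ = [
    "NetworkConfig",
    "ClusterModel",
    "ClassLikelihoods",
    "triplet_loss",
    "init_params",
    "forward",
    "train_embedding",
    "fit_clusters",
    "fit_fold",
    "FoldModel",
    "class_likelihoods",
    "predict_class",
    "olo_cross_validate",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the embedding network and its training loop."""

    layer_sizes: tuple[int, int, int, int] = (20, 20, 10, 3)
    activation: str = "tanh"
    margin: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 500
    triplets_per_epoch: int = 128
    seed: int = 0
    squared_distances: bool = True
    kmeans_n_init: int = 10

    def __post_init__(self) -> None:
        if tuple(self.layer_sizes) != (20, 20, 10, 3):
            raise ValueError("layer_sizes are fixed at (20, 20, 10, 3)")
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if self.activation not in ("tanh", "relu"):
            raise ValueError("activation must be 'tanh' or 'relu'")


@dataclass
class ClusterModel:
    """k-means centroids in the 3-D embedding plus cluster → grade mapping."""

    centroids: np.ndarray  # (3, 3)
    cluster_to_class: dict[int, str]
    temperature: float

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class ClassLikelihoods:
    """Per-class membership likelihoods in grade order ('0', '1', '23')."""

    patient_id: str
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (3,) or np.any(self.p < 0) or np.any(self.p > 1):
            raise ValueError("p must be three probabilities")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("likelihoods must sum to 1 within 1e-9")


# ---------------------------------------------------------------------------
# network primitives
# ---------------------------------------------------------------------------


def triplet_loss(
    anchor: np.ndarray,
    positive: np.ndarray,
    negative: np.ndarray,
    margin: float,
    squared: bool = True,
) -> float:
    """Hinge triplet loss on a single (anchor, positive, negative) triple."""
    a = np.asarray(anchor, dtype=float)
    p = np.asarray(positive, dtype=float)
    n = np.asarray(negative, dtype=float)
    if squared:
        d_ap = float(np.sum((a - p) ** 2))
        d_an = float(np.sum((a - n) ** 2))
    else:
        d_ap = float(np.linalg.norm(a - p))
        d_an = float(np.linalg.norm(a - n))
    return max(0.0, d_ap - d_an + margin)


def init_params(
    layer_sizes: Sequence[int], rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Gaussian fan-in initialization: W ~ N(0, 1/fan_in), b = 0."""
    params = []
    for d_in, d_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        w = rng.standard_normal((d_in, d_out)) / np.sqrt(d_in)
        params.append((w, np.zeros(d_out)))
    return params


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(x) if kind == "tanh" else np.maximum(x, 0.0)


def forward(
    features: np.ndarray,
    params: Sequence[tuple[np.ndarray, np.ndarray]],
    activation: str = "tanh",
) -> np.ndarray:
    """Embed feature rows: affine + activation per hidden layer, linear output."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != params[0][0].shape[0]:
        raise ValueError(
            f"expected {params[0][0].shape[0]} inputs, got {x.shape[1]}"
        )
    for w, b in params[:-1]:
        x = _act(x @ w + b, activation)
    w, b = params[-1]
    return x @ w + b


def _forward_cache(x, params, activation):
    acts = [x]
    for w, b in params[:-1]:
        acts.append(_act(acts[-1] @ w + b, activation))
    w, b = params[-1]
    acts.append(acts[-1] @ w + b)
    return acts


def _sample_triplets(
    labels: np.ndarray, n_triplets: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    classes = np.unique(labels)
    by_class = {c: np.flatnonzero(labels == c) for c in classes}
    anchor_classes = [c for c in classes if by_class[c].size >= 2]
    ia = np.empty(n_triplets, dtype=int)
    ip = np.empty(n_triplets, dtype=int)
    iq = np.empty(n_triplets, dtype=int)
    choice = rng.integers(len(anchor_classes), size=n_triplets)
    for ci, c in enumerate(anchor_classes):
        sel = np.flatnonzero(choice == ci)
        if sel.size == 0:
            continue
        same = by_class[c]
        other = np.flatnonzero(labels != c)
        a_pos = rng.integers(same.size, size=sel.size)
        p_pos = (a_pos + 1 + rng.integers(same.size - 1, size=sel.size)) % same.size
        ia[sel] = same[a_pos]
        ip[sel] = same[p_pos]
        iq[sel] = other[rng.integers(other.size, size=sel.size)]
    return ia, ip, iq


def train_embedding(
    features: np.ndarray | FeatureMatrix,
    labels: Sequence[str],
    config: NetworkConfig,
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Train the embedding network with Adam on uniformly sampled triplets.

    Returns the trained parameters and the per-epoch loss trace (batch loss
    before each update). Reproducible for a fixed config seed. A class with
    fewer than two members cannot anchor a triplet and is excluded from
    anchor sampling with a warning; training with a single class present is
    an error (no valid triplets exist).
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    y = np.asarray([str(l) for l in labels])
    if x.shape[0] != y.shape[0]:
        raise ValueError("one label per feature row required")
    if x.shape[1] != config.layer_sizes[0]:
        raise ValueError(
            f"network expects {config.layer_sizes[0]} inputs, got {x.shape[1]}"
        )
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("triplet training requires at least 2 classes")
    thin = classes[counts < 2]
    if thin.size:
        warnings.warn(
            f"classes {list(thin)} have < 2 members and cannot anchor triplets",
            RuntimeWarning,
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed)
    params = init_params(config.layer_sizes, rng)
    m_state = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params]
    v_state = [(np.zeros_like(w), np.zeros_like(b)) for w, b in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    trace = np.empty(config.epochs)

    for epoch in range(config.epochs):
        ia, ip, iq = _sample_triplets(y, config.triplets_per_epoch, rng)
        acts = _forward_cache(x, params, config.activation)
        z = acts[-1]
        if config.squared_distances:
            d_ap = np.sum((z[ia] - z[ip]) ** 2, axis=1)
            d_an = np.sum((z[ia] - z[iq]) ** 2, axis=1)
        else:
            d_ap = np.linalg.norm(z[ia] - z[ip], axis=1)
            d_an = np.linalg.norm(z[ia] - z[iq], axis=1)
        viol = d_ap - d_an + config.margin
        active = viol > 0
        trace[epoch] = float(np.mean(np.maximum(viol, 0.0)))

        dz = np.zeros_like(z)
        if active.any():
            scale = 1.0 / viol.size
            a, p, q = ia[active], ip[active], iq[active]
            if config.squared_distances:
                ga = 2.0 * (z[q] - z[p]) * scale
                gp = -2.0 * (z[a] - z[p]) * scale
                gq = 2.0 * (z[a] - z[q]) * scale
            else:
                u_ap = (z[a] - z[p]) / (d_ap[active][:, None] + eps)
                u_an = (z[a] - z[q]) / (d_an[active][:, None] + eps)
                ga = (u_ap - u_an) * scale
                gp = -u_ap * scale
                gq = u_an * scale
            np.add.at(dz, a, ga)
            np.add.at(dz, p, gp)
            np.add.at(dz, q, gq)

        # backprop through the affine/activation stack
        grads: list[tuple[np.ndarray, np.ndarray]] = []
        delta = dz
        for li in range(len(params) - 1, -1, -1):
            w, _ = params[li]
            h_in = acts[li]
            grads.insert(0, (h_in.T @ delta, delta.sum(axis=0)))
            if li > 0:
                delta = delta @ w.T
                h = acts[li]
                if config.activation == "tanh":
                    delta = delta * (1.0 - h**2)
                else:
                    delta = delta * (h > 0)

        t = epoch + 1
        lr_t = config.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
        new_params = []
        for li, ((w, b), (gw, gb)) in enumerate(zip(params, grads)):
            mw, mb = m_state[li]
            vw, vb = v_state[li]
            mw = beta1 * mw + (1 - beta1) * gw
            mb = beta1 * mb + (1 - beta1) * gb
            vw = beta2 * vw + (1 - beta2) * gw**2
            vb = beta2 * vb + (1 - beta2) * gb**2
            m_state[li] = (mw, mb)
            v_state[li] = (vw, vb)
            new_params.append(
                (
                    w - lr_t * mw / (np.sqrt(vw) + eps),
                    b - lr_t * mb / (np.sqrt(vb) + eps),
                )
            )
        params = new_params

    head = max(1, config.epochs // 10)
    if trace[-head:].mean() > trace[:head].mean():
        warnings.warn(
            "triplet training did not reduce the loss "
            f"(first {head} epochs {trace[:head].mean():.4g}, "
            f"last {head} epochs {trace[-head:].mean():.4g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return params, trace


def save_params(
    params: Sequence[tuple[np.ndarray, np.ndarray]],
    config: NetworkConfig,
    path,
) -> None:
    """Serialize trained parameters plus their config to a portable JSON bundle."""
    import dataclasses
    import json
    from pathlib import Path

    bundle = {
        "config": dataclasses.asdict(config),
        "layers": [{"w": w.tolist(), "b": b.tolist()} for w, b in params],
    }
    Path(path).write_text(json.dumps(bundle) + "\n")


def load_params(path) -> tuple[list[tuple[np.ndarray, np.ndarray]], NetworkConfig]:
    """Load a bundle written by :func:`save_params`."""
    import json
    from pathlib import Path

    bundle = json.loads(Path(path).read_text())
    cfg_raw = bundle["config"]
    cfg_raw["layer_sizes"] = tuple(cfg_raw["layer_sizes"])
    config = NetworkConfig(**cfg_raw)
    params = [
        (np.asarray(layer["w"], float), np.asarray(layer["b"], float))
        for layer in bundle["layers"]
    ]
    return params, config


# ---------------------------------------------------------------------------
# clustering and likelihoods
# ---------------------------------------------------------------------------


def fit_clusters(
    embeddings: np.ndarray,
    labels: Sequence[str],
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterModel:
    """k-means on training embeddings, clusters mapped to the majority grade.

    Ties in the majority vote break toward the lower grade. The likelihood
    temperature is the mean within-cluster squared distance of the training
    fold (scale-adaptive: likelihoods harden as clusters tighten).
    """
    z = np.atleast_2d(np.asarray(embeddings, dtype=float))
    y = [str(l) for l in labels]
    if z.shape[0] != len(y):
        raise ValueError("one label per embedding required")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    assign = km.fit_predict(z)

    mapping: dict[int, str] = {}
    for c in range(k):
        members = [y[i] for i in np.flatnonzero(assign == c)]
        if members:
            grades, counts = np.unique(members, return_counts=True)
            best = counts.max()
            tied = [g for g, n in zip(grades, counts) if n == best]
            mapping[c] = min(tied, key=lambda g: GRADE_ORDINAL[g])
        else:  # pragma: no cover - sklearn reseeds empty clusters internally
            mapping[c] = "0"

    within = np.sum((z - km.cluster_centers_[assign]) ** 2, axis=1)
    tau = float(max(within.mean(), 1e-9))
    return ClusterModel(
        centroids=km.cluster_centers_, cluster_to_class=mapping, temperature=tau
    )


def class_likelihoods(
    embedding: np.ndarray, model: ClusterModel, patient_id: str = ""
) -> ClassLikelihoods:
    """Softmax of negative squared centroid distances, reported by grade."""
    x = np.asarray(embedding, dtype=float).reshape(-1)
    d2 = np.sum((model.centroids - x) ** 2, axis=1)
    logits = -d2 / model.temperature
    logits -= logits.max()
    w = np.exp(logits)
    w /= w.sum()
    p = np.zeros(3)
    for cluster, grade in model.cluster_to_class.items():
        p[GRADE_ORDINAL[grade]] += w[cluster]
    return ClassLikelihoods(patient_id=patient_id, p=p)


def predict_class(likelihoods: ClassLikelihoods) -> str:
    """Dominant likelihood wins; exact ties break toward the lower grade."""
    return GRADES[int(np.argmax(likelihoods.p))]


# ---------------------------------------------------------------------------
# one-left-out cross-validation
# ---------------------------------------------------------------------------


def _fold_seed(base_seed: int, fold: int) -> int:
    return (base_seed * 1_000_003 + fold) & 0x7FFFFFFF


@dataclass
class FoldModel:
    """Everything fitted on one training fold: selection, scaling, net, clusters."""

    selected: list[str]
    features: FeatureMatrix
    params: list[tuple[np.ndarray, np.ndarray]]
    clusters: ClusterModel
    config: NetworkConfig
    flag: str = ""

    def score(self, raw_row: np.ndarray, patient_id: str = "") -> ClassLikelihoods:
        """Embed one raw candidate row (selected-column order) and score it."""
        x = self.features.transform(np.asarray(raw_row, dtype=float))
        z = forward(x, self.params, self.config.activation)[0]
        return class_likelihoods(z, self.clusters, patient_id=patient_id)


def fit_fold(
    candidates: pd.DataFrame,
    outcomes: pd.Series,
    train_ids: Sequence[str],
    config: NetworkConfig,
    k_features: int = 20,
    selected: Sequence[str] | None = None,
    fold: int = 0,
) -> FoldModel:
    """Fit selection, standardization, embedding and clusters on one fold.

    Only rows in ``train_ids`` are ever read from ``candidates``; a held-out
    patient's features cannot influence the fold model.
    """
    train_ids = list(train_ids)
    y_train = pd.Series({p: str(outcomes[p]) for p in train_ids})
    if selected is None:
        sel, fm, _ = select_biomarkers(candidates.loc[train_ids], y_train, k_features)
    else:  # pre-chosen columns: standardize only, preserving the caller's order
        sel = list(selected)
        raw = candidates.loc[train_ids, sel].to_numpy(float)
        center = raw.mean(axis=0)
        scale = _safe_std(raw)
        fm = FeatureMatrix(
            patient_ids=train_ids,
            columns=sel,
            values=(raw - center) / scale,
            center=center,
            scale=scale,
        )
    fold_cfg = replace(config, seed=_fold_seed(config.seed, fold))
    params, _ = train_embedding(fm, list(y_train[fm.patient_ids]), fold_cfg)
    emb = forward(fm.values, params, fold_cfg.activation)
    clusters = fit_clusters(
        emb,
        list(y_train[fm.patient_ids]),
        seed=_fold_seed(config.seed, fold),
        n_init=config.kmeans_n_init,
    )
    return FoldModel(
        selected=sel, features=fm, params=params, clusters=clusters, config=fold_cfg
    )


def _safe_std(raw: np.ndarray) -> np.ndarray:
    s = raw.std(axis=0)
    s[s == 0] = 1.0
    return s


def olo_cross_validate(
    candidates: pd.DataFrame,
    outcomes: Mapping[str, str] | pd.Series,
    config: NetworkConfig | None = None,
    k_features: int = 20,
    ungraded: pd.DataFrame | None = None,
    select_in_fold: bool = True,
) -> pd.DataFrame:
    """One-left-out validation over the graded patients.

    ``candidates`` holds raw (unstandardized) biomarker candidates indexed by
    patient_id. For each graded patient, biomarker selection, feature
    standardization, embedding training and clustering run on the remaining
    graded patients only; the held-out patient is then embedded and scored.
    With ``select_in_fold=False`` the top-k selection is computed once on all
    graded patients (reproducing selection-outside-the-loop protocols, at
    the cost of selection leakage).

    Ungraded patients (``ungraded`` frame, same columns) are classified by
    every fold's model and their likelihoods averaged; they never enter a
    training fold. Returns one row per patient with the three likelihoods,
    the prediction, the truth (empty for ungraded) and a fold flag marking
    folds whose training set lost an entire class.
    """
    config = config or NetworkConfig()
    outcomes = (
        pd.Series(dict(outcomes)) if not isinstance(outcomes, pd.Series) else outcomes
    )
    graded = [p for p in candidates.index if p in outcomes.index]
    if len(graded) < 4:
        raise ValueError("OLO requires at least 4 graded patients")
    all_classes = {str(outcomes[p]) for p in graded}
    if len(all_classes) < 2:
        raise ValueError("OLO requires graded patients spanning at least 2 classes")

    global_selection: list[str] | None = None
    if not select_in_fold:
        global_selection, _, _ = select_biomarkers(
            candidates.loc[graded], outcomes, k_features
        )

    rows = []
    ungraded_acc: dict[str, np.ndarray] = {}
    for fold, held in enumerate(graded):
        train = [p for p in graded if p != held]
        flag = "" if {str(outcomes[p]) for p in train} == all_classes else "missing-class"
        fold_model = fit_fold(
            candidates,
            outcomes,
            train,
            config,
            k_features=k_features,
            selected=global_selection,
            fold=fold,
        )
        cl = fold_model.score(
            candidates.loc[held, fold_model.selected].to_numpy(float), patient_id=held
        )
        rows.append(
            {
                "patient_id": held,
                "p_grade0": cl.p[0],
                "p_grade1": cl.p[1],
                "p_grade23": cl.p[2],
                "predicted": predict_class(cl),
                "actual": str(outcomes[held]),
                "graded": True,
                "fold_flag": flag,
            }
        )

        if ungraded is not None and len(ungraded):
            for pid in ungraded.index:
                pu = fold_model.score(
                    ungraded.loc[pid, fold_model.selected].to_numpy(float), patient_id=pid
                ).p
                ungraded_acc[pid] = ungraded_acc.get(pid, 0.0) + pu

    for pid, acc in ungraded_acc.items():
        p = acc / len(graded)
        cl = ClassLikelihoods(patient_id=pid, p=p / p.sum())
        rows.append(
            {
                "patient_id": pid,
                "p_grade0": cl.p[0],
                "p_grade1": cl.p[1],
                "p_grade23": cl.p[2],
                "predicted": predict_class(cl),
                "actual": "",
                "graded": False,
                "fold_flag": "",
            }
        )
    return pd.DataFrame(rows)
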