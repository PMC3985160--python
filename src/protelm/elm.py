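"""Single-hidden-layer feedforward networks trained by the extreme learning
machine (ELM).

An SLFN with J hidden nodes computes o(x) = sum_j w_j g(a_j, b_j, x).  ELM
draws the hidden parameters (a_j, b_j) at random, never tunes them, and
solves the output weights W in closed form as the minimum-norm least-squares
solution W = H^+ T, where H is the N x J hidden-layer output matrix and T the
N x C one-against-all +-1 target matrix.  With an infinitely differentiable
activation and J = N random nodes, an SLFN can interpolate N distinct samples
exactly, which is why random features plus a linear solve suffice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

ACTIVATIONS = ("linear", "sigmoid", "gaussian")


@dataclass
class Dataset:
    """A labelled feature matrix with a fixed class ordering.

    ``class_index`` maps each label to its output column; labels are sorted
    so the mapping is reproducible across runs.
    """

    X: np.ndarray
    labels: np.ndarray
    class_index: dict[str, int]

    @classmethod
    def from_arrays(cls, X, labels) -> "Dataset":
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels, dtype=object)
        if X.ndim != 2 or X.shape[0] != labels.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        if X.shape[0] < 1:
            raise ValueError("dataset must contain at least one sample")
        classes = sorted({str(l) for l in labels})
        return cls(X=X, labels=labels, class_index={c: i for i, c in enumerate(classes)})

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_index)

    @property
    def classes(self) -> list[str]:
        return sorted(self.class_index, key=self.class_index.get)


def encode_targets(dataset: Dataset) -> np.ndarray:
    """One-against-all +-1 encoding: row i has +1 in the column of its class."""
    if dataset.n_classes < 2:
        raise ValueError("target encoding requires at least two classes")
    T = -np.ones((dataset.n_samples, dataset.n_classes))
    for i, label in enumerate(dataset.labels):
        try:
            T[i, dataset.class_index[str(label)]] = 1.0
        except KeyError:
            raise ValueError(f"label {label!r} not in class index") from None
    return T


def decode_targets(T: np.ndarray, classes: list[str]) -> np.ndarray:
    """Inverse of :func:`encode_targets` via row argmax."""
    return np.asarray([classes[i] for i in np.argmax(T, axis=1)], dtype=object)


@dataclass
class HiddenLayer:
    """Random hidden-node parameters of an SLFN.

    ``A`` holds node weights (linear/sigmoid) or centers (gaussian) row-wise;
    ``b`` holds biases, or widths for gaussian nodes (strictly positive).
    """

    kind: str
    A: np.ndarray
    b: np.ndarray
    seed: int

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


def init_hidden(J: int, d: int, kind: str = "sigmoid", seed: int = 0) -> HiddenLayer:
    """Draw J random hidden nodes: weights i.i.d. uniform on [-1, 1], biases
    uniform on [-1, 1] (gaussian widths uniform on (0, 1])."""
    if kind not in ACTIVATIONS:
        raise ValueError(f"unknown activation {kind!r}; choose from {ACTIVATIONS}")
    if J < 1 or d < 1:
        raise ValueError("J and d must be >= 1")
    rng = np.random.default_rng(seed)
    A = rng.uniform(-1.0, 1.0, size=(J, d))
    if kind == "gaussian":
        b = 1.0 - rng.random(J)  # (0, 1]
    else:
        b = rng.uniform(-1.0, 1.0, size=J)
    return HiddenLayer(kind=kind, A=A, b=b, seed=seed)


def hidden_output(X: np.ndarray, layer: HiddenLayer) -> np.ndarray:
    """Hidden-layer output matrix H with H_ij = g(a_j, b_j, x_i)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != layer.A.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != hidden layer dimension {layer.A.shape[1]}"
        )
    if layer.kind == "gaussian":
        # H_ij = exp(-b_j * ||x_i - a_j||^2)
        sq = (
            np.sum(X**2, axis=1)[:, None]
            - 2.0 * X @ layer.A.T
            + np.sum(layer.A**2, axis=1)[None, :]
        )
        return np.exp(-layer.b[None, :] * np.maximum(sq, 0.0))
    Z = X @ layer.A.T + layer.b[None, :]
    if layer.kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-Z))
    return Z  # linear


def solve_output_weights(H: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares output weights W = H^+ T.

    Solved through SVD with singular values below machine-eps * max(N, J)
    (relative to the largest) treated as zero.
    """
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    if H.shape[0] != T.shape[0]:
        raise ValueError("H and T must have the same number of rows")
    W, *_ = np.linalg.lstsq(H, T, rcond=None)
    return W


@dataclass
class SLFNModel:
    """A trained SLFN: hidden layer plus output weight matrix."""

    hidden: HiddenLayer
    W: np.ndarray
    class_index: dict[str, int]
    scaler_min: np.ndarray | None = None
    scaler_max: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def classes(self) -> list[str]:
        return sorted(self.class_index, key=self.class_index.get)

    @property
    def n_nodes(self) -> int:
        return self.hidden.n_nodes


def train_elm(
    dataset: Dataset, J: int, kind: str = "sigmoid", seed: int = 0
) -> SLFNModel:
    """Train a basic ELM: random hidden layer, closed-form output weights."""
    layer = init_hidden(J, dataset.n_features, kind=kind, seed=seed)
    H = hidden_output(dataset.X, layer)
    T = encode_targets(dataset)
    W = solve_output_weights(H, T)
    return SLFNModel(hidden=layer, W=W, class_index=dict(dataset.class_index))


def decision_matrix(model: SLFNModel, X: np.ndarray) -> np.ndarray:
    """Network outputs O = H W for each row of X (N x C)."""
    return hidden_output(X, model.hidden) @ model.W


def predict(model: SLFNModel, X: np.ndarray) -> np.ndarray:
    """Predicted class labels: per-row argmax of the decision matrix, ties
    resolved to the smallest class index."""
    O = decision_matrix(model, X)
    classes = model.classes
    return np.asarray([classes[i] for i in np.argmax(O, axis=1)], dtype=object)


def training_error(model: SLFNModel, dataset: Dataset) -> int:
    """Number of misclassified training samples."""
    pred = predict(model, dataset.X)
    return int(np.sum(pred != np.asarray([str(l) for l in dataset.labels], dtype=object)))


def accuracy(model: SLFNModel, X: np.ndarray, labels) -> float:
    """Fraction of samples whose predicted class matches the given label."""
    pred = predict(model, X)
    truth = np.asarray([str(l) for l in labels], dtype=object)
    return float(np.mean(pred == truth))


def save_model(model: SLFNModel, path) -> None:
    """Serialize a model to a single ``.npz`` archive (round-trip exact)."""
    meta = {
        "kind": model.hidden.kind,
        "seed": int(model.hidden.seed),
        "class_index": model.class_index,
        "extras": {k: v for k, v in model.extras.items() if _jsonable(v)},
    }
    arrays = {
        "A": model.hidden.A,
        "b": model.hidden.b,
        "W": model.W,
        "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    }
    if model.scaler_min is not None:
        arrays["scaler_min"] = model.scaler_min
        arrays["scaler_max"] = model.scaler_max
    if hasattr(path, "write"):
        np.savez(path, **arrays)
    else:
        # keep the caller's exact filename (numpy appends .npz to bare paths)
        with open(path, "wb") as handle:
            np.savez(handle, **arrays)


def load_model(path) -> SLFNModel:
    """Load a model serialized by :func:`save_model`."""
    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    layer = HiddenLayer(kind=meta["kind"], A=data["A"], b=data["b"], seed=meta["seed"])
    return SLFNModel(
        hidden=layer,
        W=data["W"],
        class_index={str(k): int(v) for k, v in meta["class_index"].items()},
        scaler_min=data["scaler_min"] if "scaler_min" in data else None,
        scaler_max=data["scaler_max"] if "scaler_max" in data else None,
        extras=meta.get("extras", {}),
    )


def _jsonable(value) -> bool:
    try:
        json.dumps(value)
        return True
    except TypeError:
        return False
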