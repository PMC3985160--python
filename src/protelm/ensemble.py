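"""Majority-voting ensembles of independently trained SLFNs.

V-ELM trains K basic ELMs with the same architecture and activation but
independent random hidden parameters on the same training set; VOP-ELM does
the same with OP-ELM members (which may prune to different sizes).  A test
sample is classified by each member; a C-dimensional tally collects one vote
per member and the class with the most votes wins, ties going to the
smallest class index.

A single random SLFN that predicts the correct class with higher probability
than any wrong class is, by the law of large numbers over the vote fraction,
correct with probability approaching one as K grows; the Monte-Carlo
simulation in :func:`simulate_proposition1` demonstrates this behaviour for
a given per-vote class distribution.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass
from io import BytesIO

import numpy as np
import pandas as pd

from .elm import Dataset, SLFNModel, decision_matrix, load_model, save_model, train_elm
from .opelm import RidgeContext, train_opelm

BASE_KINDS = ("elm", "opelm")


@dataclass(frozen=True)
class VoteVector:
    """Per-class vote tallies for one test sample; tallies sum to K."""

    tallies: np.ndarray

    @property
    def total(self) -> int:
        return int(self.tallies.sum())


@dataclass
class EnsembleModel:
    """K independently trained SLFNs sharing architecture and activation."""

    base_kind: str
    members: list[SLFNModel]
    master_seed: int
    tie_break: str = "smallest"

    @property
    def K(self) -> int:
        return len(self.members)

    @property
    def classes(self) -> list[str]:
        return self.members[0].classes

    @property
    def n_classes(self) -> int:
        return len(self.members[0].class_index)


def derive_member_seeds(master_seed: int, K: int) -> list[int]:
    """Independent, reproducible member seeds spawned from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(K)
    return [int(c.generate_state(1, np.uint64)[0] % (2**31)) for c in children]


def train_ensemble(
    dataset: Dataset,
    K: int,
    base_kind: str = "elm",
    J: int = 100,
    kind: str = "sigmoid",
    master_seed: int = 0,
    ctx: RidgeContext | None = None,
) -> EnsembleModel:
    """Train K members on the full dataset with distinct derived seeds.

    ``J`` is the node count for ELM members or ``J_max`` for OP-ELM members.
    Diversity comes solely from the random hidden parameters; every member
    sees the same training samples.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if base_kind not in BASE_KINDS:
        raise ValueError(f"unknown base kind {base_kind!r}; choose from {BASE_KINDS}")
    seeds = derive_member_seeds(master_seed, K)
    if base_kind == "elm":
        members = [train_elm(dataset, J, kind=kind, seed=s) for s in seeds]
    else:
        members = [train_opelm(dataset, J_max=J, kind=kind, seed=s, ctx=ctx) for s in seeds]
    return EnsembleModel(base_kind=base_kind, members=members, master_seed=master_seed)


def vote_matrix(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """N x C vote tallies: one vote per member per sample."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = model.n_classes
    tallies = np.zeros((X.shape[0], C), dtype=int)
    for member in model.members:
        winners = np.argmax(decision_matrix(member, X), axis=1)
        tallies[np.arange(X.shape[0]), winners] += 1
    return tallies


def _resolve(tallies: np.ndarray, model: EnsembleModel) -> np.ndarray:
    if model.tie_break == "random":
        rng = np.random.default_rng(model.master_seed)
        best = tallies.max(axis=1, keepdims=True)
        noise = rng.random(tallies.shape)
        return np.argmax(np.where(tallies == best, noise, -1.0), axis=1)
    return np.argmax(tallies, axis=1)  # first max = smallest class index


def vote(model: EnsembleModel, x: np.ndarray) -> tuple[str, VoteVector]:
    """Classify one sample by majority vote, returning the tally as well."""
    tallies = vote_matrix(model, np.atleast_2d(x))
    winner = _resolve(tallies, model)[0]
    return model.classes[winner], VoteVector(tallies=tallies[0])


def predict_ensemble(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Majority-vote class labels for each row of X."""
    tallies = vote_matrix(model, X)
    classes = model.classes
    return np.asarray([classes[i] for i in _resolve(tallies, model)], dtype=object)


def ensemble_accuracy(model: EnsembleModel, X: np.ndarray, labels) -> float:
    pred = predict_ensemble(model, X)
    truth = np.asarray([str(l) for l in labels], dtype=object)
    return float(np.mean(pred == truth))


def tallies_to_csv(model: EnsembleModel, X: np.ndarray, ids: list[str], path) -> None:
    """Export per-sample vote tallies as CSV (one column per class)."""
    frame = pd.DataFrame(vote_matrix(model, X), columns=model.classes)
    frame.insert(0, "id", ids)
    frame.to_csv(path, index=False)


def simulate_proposition1(
    p_correct: float,
    p_others,
    K_grid,
    trials: int = 10_000,
    seed: int = 0,
) -> dict[int, float]:
    """Monte-Carlo majority-vote accuracy for a fixed per-vote distribution.

    Each trial casts K independent votes from the categorical distribution
    (p_correct, *p_others) — class 0 being the true class — and succeeds when
    class 0 wins the majority (smallest-index tie-break).  With class 0
    strictly the most probable vote, accuracy tends to one as K grows.
    """
    p = np.asarray([p_correct, *np.atleast_1d(p_others)], dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("class probabilities must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    result: dict[int, float] = {}
    for K in K_grid:
        if K < 1:
            raise ValueError("ensemble sizes must be >= 1")
        counts = rng.multinomial(K, p, size=trials)
        result[int(K)] = float(np.mean(np.argmax(counts, axis=1) == 0))
    return result


def save_ensemble(model: EnsembleModel, path) -> None:
    """Serialize an ensemble as a zip of member archives plus metadata."""
    meta = {
        "base_kind": model.base_kind,
        "master_seed": int(model.master_seed),
        "tie_break": model.tie_break,
        "K": model.K,
    }
    with zipfile.ZipFile(path, "w") as archive:
        archive.writestr("ensemble.json", json.dumps(meta))
        for i, member in enumerate(model.members):
            buffer = BytesIO()
            save_model(member, buffer)
            archive.writestr(f"member_{i:03d}.npz", buffer.getvalue())


def load_ensemble(path) -> EnsembleModel:
    """Load an ensemble serialized by :func:`save_ensemble`."""
    with zipfile.ZipFile(path) as archive:
        meta = json.loads(archive.read("ensemble.json").decode())
        members = [
            load_model(BytesIO(archive.read(f"member_{i:03d}.npz")))
            for i in range(meta["K"])
        ]
    return EnsembleModel(
        base_kind=meta["base_kind"],
        members=members,
        master_seed=meta["master_seed"],
        tie_break=meta.get("tie_break", "smallest"),
    )
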