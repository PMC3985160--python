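"""Optimally pruned ELM (OP-ELM).

Random hidden nodes in a basic ELM are often redundant.  OP-ELM removes them
in three steps: (1) build an ELM hidden layer with ``J_max`` nodes; (2) rank
the hidden neurons by multiresponse sparse regression (MRSR), a forward
procedure that admits one regressor column at a time for the multi-output
+-1 target matrix; (3) pick the neuron count whose top-ranked prefix
minimizes the PRESS leave-one-out error

    eps_i = (t_i - h_i beta) / (1 - h_i P h_i^T),    P = (H^T H)^{-1},

the closed-form residual each sample would have if it were excluded from the
fit — an exact leave-one-out computed from a single full fit.  The pruned
model keeps the selected neurons and refits its output weights on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .elm import Dataset, HiddenLayer, SLFNModel, encode_targets, hidden_output, init_hidden, solve_output_weights

logger = logging.getLogger(__name__)

#: Leverage values this close to 1 have their PRESS denominator floored.
_LEVERAGE_FLOOR = 1e-10


@dataclass(frozen=True)
class NeuronRanking:
    """Permutation of hidden-neuron indices, most relevant first."""

    order: np.ndarray

    def __post_init__(self):
        order = np.asarray(self.order, dtype=int)
        if sorted(order.tolist()) != list(range(len(order))):
            raise ValueError("order must be a permutation of 0..J-1")
        object.__setattr__(self, "order", order)


@dataclass(frozen=True)
class PressCurve:
    """PRESS leave-one-out error per candidate neuron count k = 1..J."""

    loo_error: np.ndarray
    selected_k: int

    @classmethod
    def from_errors(cls, loo_error) -> "PressCurve":
        loo = np.asarray(loo_error, dtype=float)
        if loo.size < 1:
            raise ValueError("empty error curve")
        # np.argmin returns the first minimum: ties resolve to the smallest k
        return cls(loo_error=loo, selected_k=int(np.argmin(loo)) + 1)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"k": np.arange(1, self.loo_error.size + 1), "loo_error": self.loo_error}
        ).to_csv(path, index=False)


@dataclass
class RidgeContext:
    """Stabilization policy for (H^T H)^{-1} on ill-conditioned problems.

    A ridge ``lam = scale * trace(H^T H) / k`` is added only when the
    condition number exceeds ``cond_threshold``; well-conditioned problems
    use lam = 0 and the PRESS value is the exact leave-one-out error.
    """

    cond_threshold: float = 1e12
    scale: float = 1e-8


def mrsr_rank(H: np.ndarray, T: np.ndarray) -> NeuronRanking:
    """Rank the columns of H for the multi-output target T.

    Forward selection: starting from an empty active set, repeatedly add the
    column maximizing ``sum_c |h_j^T R|`` where R is the residual of a full
    least-squares refit on the active set (maintained through an incremental
    orthonormal basis).  Zero-variance columns are ranked last.
    """
    H = np.asarray(H, dtype=float)
    T = np.asarray(T, dtype=float)
    N, J = H.shape
    if N < 2:
        raise ValueError("ranking requires at least two samples")

    variances = H.var(axis=0)
    degenerate = [j for j in range(J) if variances[j] == 0.0]
    if degenerate:
        logger.warning("%d zero-variance hidden column(s) ranked last", len(degenerate))
    candidates = [j for j in range(J) if j not in set(degenerate)]

    order: list[int] = []
    Q = np.empty((N, 0))
    resid = T.copy()
    remaining = list(candidates)
    tol = np.finfo(float).eps * max(N, J)
    col_norms = np.linalg.norm(H, axis=0)
    scale = col_norms.max() if col_norms.size else 1.0
    while remaining:
        scores = np.abs(H[:, remaining].T @ resid).sum(axis=1)
        best = remaining[int(np.argmax(scores))]
        order.append(best)
        remaining.remove(best)
        # extend the orthonormal basis; collinear columns add nothing to the fit
        q = H[:, best] - Q @ (Q.T @ H[:, best])
        norm = np.linalg.norm(q)
        if norm > tol * max(scale, 1.0):
            q /= norm
            Q = np.column_stack([Q, q])
            resid = resid - np.outer(q, q @ resid)
    return NeuronRanking(order=np.asarray(order + degenerate, dtype=int))


def press_loo_error(
    H: np.ndarray, T: np.ndarray, ctx: RidgeContext | None = None
) -> float:
    """Mean squared PRESS leave-one-out residual of the linear fit T ~ H.

    Equivalent to retraining N times with one sample held out; computed in
    closed form from the full fit and the leverages h_i P h_i^T.  Residuals
    are averaged over samples and output columns.
    """
    if ctx is None:
        ctx = RidgeContext()
    H = np.atleast_2d(np.asarray(H, dtype=float))
    T = np.asarray(T, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    N, k = H.shape
    if k < 1:
        raise ValueError("need at least one regressor column")

    HtH = H.T @ H
    s = np.linalg.svd(H, compute_uv=False)
    lam = 0.0
    if s[-1] == 0.0 or (s[0] / s[-1]) ** 2 > ctx.cond_threshold:
        lam = ctx.scale * np.trace(HtH) / k
    P = np.linalg.inv(HtH + lam * np.eye(k))
    beta = P @ (H.T @ T)
    leverage = np.einsum("ij,jk,ik->i", H, P, H)
    denom = 1.0 - leverage
    n_degenerate = int(np.sum(denom < _LEVERAGE_FLOOR))
    if n_degenerate:
        logger.warning(
            "%d sample(s) with leverage ~1; PRESS denominator floored", n_degenerate
        )
        denom = np.maximum(denom, _LEVERAGE_FLOOR)
    residual = (T - H @ beta) / denom[:, None]
    return float(np.mean(residual**2))


def select_neuron_count(
    H_ranked: np.ndarray, T: np.ndarray, ctx: RidgeContext | None = None
) -> PressCurve:
    """PRESS error for every ranked-prefix size k = 1..J; smallest argmin wins.

    The whole curve comes from one thin QR of the ranked matrix: the QR of a
    prefix is the prefix of the QR, so prefix leverages are cumulative row
    sums of Q**2 and prefix fits grow by one rank-1 update per step.  Near
    rank deficiency the exact per-prefix computation is used instead.
    """
    if ctx is None:
        ctx = RidgeContext()
    H_ranked = np.atleast_2d(np.asarray(H_ranked, dtype=float))
    T = np.asarray(T, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    N, J = H_ranked.shape

    Q, R = np.linalg.qr(H_ranked)
    diag = np.abs(np.diag(R))
    well_conditioned = diag.min() > diag.max() * 1e-10 if diag.size else False

    if not well_conditioned:
        loo = np.array(
            [press_loo_error(H_ranked[:, :k], T, ctx) for k in range(1, J + 1)]
        )
        return PressCurve.from_errors(loo)

    G = Q.T @ T
    leverage = np.cumsum(Q**2, axis=1)
    fitted = np.zeros_like(T)
    loo = np.empty(J)
    for k in range(J):
        fitted = fitted + np.outer(Q[:, k], G[k])
        denom = np.maximum(1.0 - leverage[:, k], _LEVERAGE_FLOOR)
        loo[k] = np.mean(((T - fitted) / denom[:, None]) ** 2)
    return PressCurve.from_errors(loo)


def train_opelm(
    dataset: Dataset,
    J_max: int = 100,
    kind: str = "sigmoid",
    seed: int = 0,
    ctx: RidgeContext | None = None,
) -> SLFNModel:
    """Train an OP-ELM: build, rank, select, then refit on the kept neurons.

    The returned model's ``extras`` record the ranking, the PRESS curve and
    the selected neuron count.
    """
    if J_max < 1:
        raise ValueError("J_max must be >= 1")
    layer = init_hidden(J_max, dataset.n_features, kind=kind, seed=seed)
    H = hidden_output(dataset.X, layer)
    T = encode_targets(dataset)
    ranking = mrsr_rank(H, T)
    curve = select_neuron_count(H[:, ranking.order], T, ctx)
    keep = ranking.order[: curve.selected_k]
    pruned = HiddenLayer(kind=kind, A=layer.A[keep], b=layer.b[keep], seed=seed)
    W = solve_output_weights(H[:, keep], T)
    model = SLFNModel(hidden=pruned, W=W, class_index=dict(dataset.class_index))
    model.extras["selected_k"] = int(curve.selected_k)
    model.extras["J_max"] = int(J_max)
    model.extras["press_curve"] = curve
    model.extras["ranking"] = ranking
    return model
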