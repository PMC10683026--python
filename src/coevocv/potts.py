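"""Pseudo-likelihood Potts model and APC-corrected coupling scores.

The model assigns each aligned sequence s an unnormalised log-probability

    E(s) = sum_i v[i, s_i] + sum_{i<j} w[i, j, s_i, s_j]

with position-wise fields ``v`` and pair couplings ``w`` that are
symmetric under the simultaneous swap of positions and states,
w[i, j, a, b] = w[j, i, b, a]. Instead of the intractable full
likelihood, the fit maximises the pseudo-likelihood: the product over
positions i of the conditional probability of state s_i given the rest
of the sequence, normalised per position. Each sequence's log-term is
multiplied by its redundancy weight. Optimisation uses the Adam update
rule with an analytic gradient and an L2 penalty on both parameter
blocks.

Couplings are reduced to a single score per position pair over the
20 x 20 amino-acid block (the gap state is modelled but excluded from
the score), and the average product correction removes the row/column
background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import logsumexp, softmax

from .msa import GAP_STATE, Msa, Q

logger = logging.getLogger(__name__)

Reduction = Literal["frobenius", "abs_sum"]


@dataclass
class PottsModel:
    """Fitted fields and couplings of the pseudo-likelihood Potts model.

    Attributes
    ----------
    q : int
        Alphabet size including the gap state.
    v : (L, q) array
        Position-specific fields.
    w : (L, L, q, q) array
        Pair couplings; symmetric as ``w[i, j, a, b] == w[j, i, b, a]``
        with zero diagonal blocks ``w[i, i]``.
    column_map : (L,) int array
        Original-alignment column index per model position.
    training_log : dict
        Loss per iteration, seed and hyperparameters of the fit.
    """

    q: int
    v: np.ndarray
    w: np.ndarray
    column_map: np.ndarray
    training_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = self.v.shape[0]
        if self.v.shape != (L, self.q):
            raise ValueError("v must have shape (L, q)")
        if self.w.shape != (L, L, self.q, self.q):
            raise ValueError("w must have shape (L, L, q, q)")
        if not np.allclose(self.w, np.transpose(self.w, (1, 0, 3, 2))):
            raise ValueError("w must satisfy w[i,j,a,b] == w[j,i,b,a]")

    @property
    def length(self) -> int:
        return self.v.shape[0]


@dataclass
class CoevolutionMap:
    """Symmetric per-pair coevolution strength over retained MSA columns."""

    scores: np.ndarray
    column_map: np.ndarray
    apc_applied: bool
    reduction: str

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("scores must be a square matrix")
        if not np.allclose(s, s.T):
            raise ValueError("scores must be symmetric")
        if not np.all(np.isfinite(s)):
            raise ValueError("scores must be finite")
        self.scores = s

    def top_pairs(self, n: int) -> list[tuple[int, int, float]]:
        """Highest-scoring position pairs as (i, j, score), i < j, in
        retained-column indexing, sorted by descending score."""
        L = self.scores.shape[0]
        iu, ju = np.triu_indices(L, k=1)
        order = np.argsort(self.scores[iu, ju])[::-1]
        return [(int(iu[k]), int(ju[k]), float(self.scores[iu[k], ju[k]])) for k in order[:n]]


def _one_hot(matrix: np.ndarray, q: int) -> np.ndarray:
    n, L = matrix.shape
    x = np.zeros((n, L, q), dtype=np.float64)
    x[np.arange(n)[:, None], np.arange(L)[None, :], matrix] = 1.0
    return x


def pseudolikelihood_loss_grad(
    v: np.ndarray,
    w: np.ndarray,
    matrix: np.ndarray,
    weights: np.ndarray,
    lambda_v: float = 0.0,
    lambda_w: float = 0.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted negative log pseudo-likelihood and its analytic gradient.

    ``w`` must already satisfy the swap symmetry; the returned gradient
    preserves it (each symmetric element accumulates the contribution of
    both conditionals it appears in). ``lambda_v``/``lambda_w`` add
    ``lam * total_weight * sum(param**2)`` penalties.
    """
    n, L = matrix.shape
    q = v.shape[1]
    x = _one_hot(matrix, q).reshape(n, L * q)
    # W2[(i,a),(j,b)] = w[i,j,a,b]; symmetric with zero diagonal blocks.
    w2 = np.transpose(w, (0, 2, 1, 3)).reshape(L * q, L * q)
    logits = (x @ w2 + v.reshape(1, L * q)).reshape(n, L, q)
    log_z = logsumexp(logits, axis=2)
    picked = np.take_along_axis(logits, matrix[:, :, None].astype(int), axis=2)[:, :, 0]
    total_weight = float(weights.sum())
    nll = float(np.sum(weights[:, None] * (log_z - picked)))

    probs = softmax(logits, axis=2)
    delta = (weights[:, None, None] * (probs - x.reshape(n, L, q))).reshape(n, L * q)
    grad_v = delta.sum(axis=0).reshape(L, q)
    g2 = delta.T @ x
    g2 = g2 + g2.T
    grad_w = np.transpose(g2.reshape(L, q, L, q), (0, 2, 1, 3))
    idx = np.arange(L)
    grad_w[idx, idx] = 0.0

    if lambda_v:
        nll += lambda_v * total_weight * float(np.sum(v**2))
        grad_v = grad_v + 2.0 * lambda_v * total_weight * v
    if lambda_w:
        nll += lambda_w * total_weight * 0.5 * float(np.sum(w**2))
        # grad_w is the tied derivative of each symmetric element pair,
        # so the penalty contributes twice (once per mirrored entry).
        grad_w = grad_w + 2.0 * lambda_w * total_weight * w
    return nll, grad_v, grad_w


def fit_potts(
    msa: Msa,
    weights: np.ndarray | None = None,
    *,
    iterations: int = 300,
    learning_rate: float = 1e-4,
    init: Literal["normal", "zeros"] = "normal",
    init_scale: float = 1.0,
    init_seed: int = 0,
    lambda_v: float = 0.01,
    lambda_w: float | None = None,
    adam_beta1: float = 0.9,
    adam_beta2: float = 0.999,
    adam_eps: float = 1e-8,
) -> PottsModel:
    """Fit the Potts model to a weighted MSA by Adam.

    Parameters
    ----------
    msa : Msa
        Gap-filtered alignment (all Q states allowed; the gap is modelled
        as an explicit 21st state).
    weights : array, optional
        Per-sequence redundancy weights; uniform when omitted.
    iterations, learning_rate
        Full-batch Adam steps and step size.
    init, init_scale, init_seed
        ``"normal"`` draws all parameters from N(0, init_scale^2);
        ``"zeros"`` starts from the independent-columns model. The fit is
        deterministic given the seed.
    lambda_v, lambda_w
        L2 penalty strengths, scaled internally by the total sequence
        weight; ``lambda_w`` defaults to ``0.01 * (L - 1) * q / total_weight``
        so the pair penalty stays comparable to the field penalty at any
        alignment depth.

    Notes
    -----
    With a standard-normal initialisation the coupling block starts from
    O(1) noise that a short low-learning-rate run cannot anneal away; for
    coupling-recovery work prefer ``init="zeros"`` (or a small
    ``init_scale``) with a larger learning rate. The defaults are kept
    deliberately conservative and every choice is recorded in
    ``training_log``.
    """
    n, L = msa.matrix.shape
    if n == 0 or L == 0:
        raise ValueError("cannot fit a Potts model to an empty alignment")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,):
        raise ValueError("weights must align with the MSA records")
    total_weight = float(weights.sum())
    if lambda_w is None:
        lambda_w = 0.01 * (L - 1) * Q / total_weight

    rng = np.random.default_rng(init_seed)
    if init == "normal":
        v = rng.normal(0.0, init_scale, size=(L, Q))
        w = rng.normal(0.0, init_scale, size=(L, L, Q, Q))
    elif init == "zeros":
        v = np.zeros((L, Q))
        w = np.zeros((L, L, Q, Q))
    else:
        raise ValueError(f"unknown init {init!r}")
    # Impose the swap symmetry and kill the diagonal before the first step.
    w = 0.5 * (w + np.transpose(w, (1, 0, 3, 2)))
    w[np.arange(L), np.arange(L)] = 0.0

    m_v = np.zeros_like(v)
    s_v = np.zeros_like(v)
    m_w = np.zeros_like(w)
    s_w = np.zeros_like(w)
    losses: list[float] = []
    for t in range(1, iterations + 1):
        loss, g_v, g_w = pseudolikelihood_loss_grad(
            v, w, msa.matrix, weights, lambda_v=lambda_v, lambda_w=lambda_w
        )
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite pseudo-likelihood loss at iteration {t}; "
                f"last finite loss {losses[-1] if losses else 'n/a'}"
            )
        losses.append(loss)
        for param, grad, m, s in ((v, g_v, m_v, s_v), (w, g_w, m_w, s_w)):
            m *= adam_beta1
            m += (1 - adam_beta1) * grad
            s *= adam_beta2
            s += (1 - adam_beta2) * grad**2
            m_hat = m / (1 - adam_beta1**t)
            s_hat = s / (1 - adam_beta2**t)
            param -= learning_rate * m_hat / (np.sqrt(s_hat) + adam_eps)
        w[np.arange(L), np.arange(L)] = 0.0

    training_log = {
        "loss": losses,
        "iterations": iterations,
        "learning_rate": learning_rate,
        "init": init,
        "init_scale": init_scale,
        "init_seed": init_seed,
        "lambda_v": lambda_v,
        "lambda_w": lambda_w,
        "total_weight": total_weight,
    }
    return PottsModel(q=Q, v=v, w=w, column_map=msa.column_map.copy(), training_log=training_log)


def coupling_matrix(model: PottsModel, reduction: Reduction = "frobenius") -> CoevolutionMap:
    """Reduce the couplings to one scalar per position pair.

    Only the 20 x 20 amino-acid block contributes; the gap state is part
    of the model but not of the score. ``frobenius`` takes the 2-norm of
    each block (the common DCA convention, immune to sign cancellation);
    ``abs_sum`` sums absolute entries.
    """
    aa = model.q - 1
    block = model.w[:, :, :aa, :aa]
    if reduction == "frobenius":
        scores = np.sqrt(np.sum(block**2, axis=(2, 3)))
    elif reduction == "abs_sum":
        scores = np.sum(np.abs(block), axis=(2, 3))
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    np.fill_diagonal(scores, 0.0)
    scores = 0.5 * (scores + scores.T)
    return CoevolutionMap(
        scores=scores, column_map=model.column_map.copy(), apc_applied=False,
        reduction=reduction,
    )


def apc(matrix: np.ndarray) -> np.ndarray:
    """Average product correction: subtract the row/column background.

    S'_ij = S_ij - mean_i(S) * mean_j(S) / mean(S). The correction
    annihilates any rank-1 background u_i u_j exactly (constant matrices
    are the u_i = const special case) and leaves a row-centred matrix
    (near-zero mean) unchanged, which makes the operation idempotent. The
    result keeps its corrected diagonal; callers that expose a score map
    zero the diagonal afterwards, since self-pairs are undefined.
    """
    s = np.asarray(matrix, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("apc expects a square matrix")
    if not np.allclose(s, s.T):
        raise ValueError("apc expects a symmetric matrix")
    L = s.shape[0]
    if L < 2:
        return s.copy()
    total = s.mean()
    # Zero-mean guard: covers the all-zero matrix and already-corrected
    # input, where the correction would be a 0/0 ratio of rounding noise.
    if abs(total) <= 1e-12 * max(1.0, float(np.abs(s).max())):
        return s.copy()
    row = s.mean(axis=1)
    return s - np.outer(row, row) / total


def apply_apc(coevo: CoevolutionMap) -> CoevolutionMap:
    if coevo.apc_applied:
        logger.warning("APC already applied; applying again")
    corrected = apc(coevo.scores)
    np.fill_diagonal(corrected, 0.0)
    return CoevolutionMap(
        scores=corrected,
        column_map=coevo.column_map.copy(),
        apc_applied=True,
        reduction=coevo.reduction,
    )
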