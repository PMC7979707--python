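"""Pagel's lambda for discrete characters under the equal-rates Mk model.

lambda rescales internal branches of an ultrametric tree while preserving
every root-to-tip height: lambda = 1 leaves the tree untouched, lambda = 0
collapses shared history so tip states become independent draws. The
transition rate q and lambda are jointly maximised by bounded quasi-Newton
from several starting points, since the lambda likelihood surface is often
flat near 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .trees import TreeArrays, children_lists

_LOG_Q_BOUNDS = (-12.0, 8.0)
_LAMBDA_STARTS = (0.1, 0.5, 0.9, 0.99)
_TOL = 1e-6


def lambda_transform(tree: TreeArrays, lam: float) -> TreeArrays:
    """Pagel's lambda branch-length transform.

    Internal branch lengths are multiplied by lambda; each terminal branch is
    stretched so every root-to-tip depth keeps its original value. Requires an
    ultrametric tree for lambda < 1 (otherwise tip heights cannot all be
    preserved by stretching terminal branches alone with non-negative
    lengths guaranteed).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    if lam == 1.0:
        return tree
    if not tree.is_ultrametric():
        raise ValueError("lambda transform with lambda < 1 requires an ultrametric tree")
    depth = tree.depths()
    edge = tree.edge_length * lam
    tips = np.arange(tree.n_tips)
    parent_depth = depth[tree.parent[tips]]
    # terminal branch = original branch + unscaled share of the parent depth
    edge[tips] = tree.edge_length[tips] + (1.0 - lam) * parent_depth
    return replace(tree, edge_length=edge)


def mk_transition_matrices(t: np.ndarray, q: float, k: int) -> np.ndarray:
    """P(t) for the equal-rates Mk model with k states.

    P_ij(t) = 1/k + (delta_ij - 1/k) * exp(-k q t / (k-1)), the standard
    parameterisation in which q is the rate of leaving a state.
    """
    decay = np.exp(-k * q * np.asarray(t) / (k - 1.0))
    base = (1.0 - decay) / k
    P = np.repeat(base[..., None, None], k, axis=-2).repeat(k, axis=-1)
    idx = np.arange(k)
    P[..., idx, idx] += decay[..., None]
    return P


def mk_loglik(tree: TreeArrays, states: np.ndarray, q: float, n_states: int) -> float:
    """Felsenstein-pruning log-likelihood of tip states under ER Mk.

    ``states`` holds integer states in 0..n_states-1 aligned with
    ``tree.labels``; the root state is weighted by the uniform stationary
    distribution.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    states = np.asarray(states)
    if states.shape != (tree.n_tips,):
        raise ValueError("states must align with tree tips")
    if states.min() < 0 or states.max() >= n_states:
        raise ValueError("tip state outside 0..n_states-1")
    k = n_states
    kids = children_lists(tree)
    P = mk_transition_matrices(tree.edge_length, q, k)
    partial = np.zeros((tree.n_nodes, k))
    partial[np.arange(tree.n_tips), states] = 1.0
    log_scale = 0.0
    for i in tree.postorder:
        if i < tree.n_tips:
            continue
        L = np.ones(k)
        for c in kids[i]:
            L = L * (P[c] @ partial[c])
        s = L.max()
        if s <= 0:
            return -np.inf
        partial[i] = L / s
        log_scale += np.log(s)
    root = tree.root
    return float(np.log(partial[root].mean()) + log_scale)


@dataclass(frozen=True)
class LambdaFit:
    lambda_hat: float
    q_hat: float
    loglik: float
    converged: bool


def fit_lambda(tree: TreeArrays, states: np.ndarray, n_states: int) -> LambdaFit:
    """Joint ML fit of (q, lambda) for discrete phylogenetic signal."""
    states = np.asarray(states)
    if len(np.unique(states)) < 2:
        raise ValueError("lambda is undefined for monomorphic tip states")

    height = tree.height()
    q0 = max(1.0 / height, 1e-6)

    def nll(params: np.ndarray) -> float:
        log_q, lam = params
        lam = min(max(lam, 0.0), 1.0)
        return -mk_loglik(lambda_transform(tree, lam), states, np.exp(log_q), n_states)

    best = None
    for lam0 in _LAMBDA_STARTS:
        res = minimize(
            nll,
            x0=np.array([np.log(q0), lam0]),
            method="L-BFGS-B",
            bounds=[_LOG_Q_BOUNDS, (0.0, 1.0)],
            options={"ftol": _TOL, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    lam_hat = float(np.clip(best.x[1], 0.0, 1.0))
    return LambdaFit(
        lambda_hat=lam_hat,
        q_hat=float(np.exp(best.x[0])),
        loglik=float(-best.fun),
        converged=bool(best.success),
    )


@dataclass(frozen=True)
class LambdaSummary:
    mean: float
    sd: float
    fits: tuple[LambdaFit, ...]


def lambda_over_trees(
    trees,
    states: dict[str, int] | np.ndarray,
    n_states: int,
    n_trees: int = 30,
    seed: int | None = None,
) -> LambdaSummary:
    """Fit lambda on ``n_trees`` trees sampled without replacement.

    ``states`` may be a mapping species -> state (matched to each tree's
    labels) or an array aligned to the shared label order of all trees.
    """
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree list")
    if n_trees > len(trees):
        raise ValueError("n_trees exceeds the number of available trees")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(trees), size=n_trees, replace=False)
    fits = []
    for idx in chosen:
        tree = trees[idx]
        if isinstance(states, dict):
            s = np.array([states[lab] for lab in tree.labels])
        else:
            s = np.asarray(states)
        fits.append(fit_lambda(tree, s, n_states))
    lams = np.array([f.lambda_hat for f in fits])
    sd = float(lams.std(ddof=1)) if len(lams) > 1 else 0.0
    return LambdaSummary(mean=float(lams.mean()), sd=sd, fits=tuple(fits))


def binary_recode(states: np.ndarray, focal: int) -> np.ndarray:
    """Recode a multi-state character as focal (1) vs non-focal (0)."""
    return (np.asarray(states) == focal).astype(np.int64)
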