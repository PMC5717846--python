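"""Mk-family models for discrete characters on rooted trees.

A k-state character evolves along each branch as a continuous-time Markov
chain with generator Q.  Three nested parameterizations are supported:

- ``ER``  (equal rates): one rate, all off-diagonal entries equal;
- ``SYM`` (symmetric): one rate per unordered state pair, Q[i,j] = Q[j,i];
- ``ARD`` (all rates different): one rate per ordered pair, k(k-1) free rates.

The likelihood is computed by Felsenstein pruning with per-node scaling;
tips coded UNKNOWN contribute an all-ones partial vector (a fully ambiguous
observation).  Marginal ancestral-state posteriors come from the standard
two-pass (rootward conditional likelihoods, then tipward messages) scheme,
which is exact.  ML fitting optimizes log-rates with multiple restarts, and
nested models are compared with likelihood-ratio tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from traitpath.coding import UNKNOWN, StateAlphabet, StateCoding, DEFAULT_ALPHABET
from traitpath.treeio import Node, Tree, TreeError

__all__ = [
    "MODEL_CLASSES",
    "RateModel",
    "RootPrior",
    "LikelihoodFit",
    "LRTResult",
    "MarginalASR",
    "MkError",
    "build_q",
    "n_free_params",
    "transition_probs",
    "stationary_distribution",
    "tree_log_likelihood",
    "fit",
    "likelihood_ratio_test",
    "compare_models",
    "marginal_asr",
]

MODEL_CLASSES = ("ER", "SYM", "ARD")

RATE_LOWER = 1e-8
RATE_UPPER = 1e3


class MkError(ValueError):
    """Invalid model specification or data/tree mismatch."""


def n_free_params(model_class: str, k: int) -> int:
    if model_class == "ER":
        return 1
    if model_class == "SYM":
        return k * (k - 1) // 2
    if model_class == "ARD":
        return k * (k - 1)
    raise MkError(f"unknown model class {model_class!r}")


def _param_pairs(model_class: str, k: int) -> list[tuple[int, int]]:
    """Ordered (i, j) cells each free parameter fills (SYM fills both)."""
    if model_class == "SYM":
        return [(i, j) for i in range(k) for j in range(i + 1, k)]
    if model_class == "ARD":
        return [(i, j) for i in range(k) for j in range(k) if i != j]
    raise MkError(model_class)


@dataclass(frozen=True)
class RateModel:
    """A concrete Mk generator: class, state count, free rates and Q."""

    model_class: str
    k: int
    params: np.ndarray
    Q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.Q, dtype=float)
        if q.shape != (self.k, self.k):
            raise MkError("Q shape mismatch")
        off = q - np.diag(np.diag(q))
        if (off < 0).any():
            raise MkError("negative off-diagonal rate")
        if np.abs(q.sum(axis=1)).max() > 1e-12 * max(1.0, np.abs(q).max()):
            raise MkError("Q rows must sum to zero")


def build_q(
    model_class: str, k: int, params: Sequence[float]
) -> RateModel:
    """Construct a generator matrix from free rates.

    Parameter order: ER ``[q]``; SYM unordered pairs in lexicographic order
    ``(0,1),(0,2),...,(k-2,k-1)``; ARD ordered pairs row-major
    ``(0,1),(0,2),...,(1,0),...``.
    """
    params = np.asarray(params, dtype=float)
    expected = n_free_params(model_class, k)
    if params.shape != (expected,):
        raise MkError(
            f"{model_class} with k={k} needs {expected} rates, got {params.shape}"
        )
    if (params <= 0).any():
        raise MkError("rates must be strictly positive")
    Q = np.zeros((k, k))
    if model_class == "ER":
        Q[:] = params[0]
        np.fill_diagonal(Q, 0.0)
    elif model_class == "SYM":
        for p, (i, j) in zip(params, _param_pairs("SYM", k)):
            Q[i, j] = Q[j, i] = p
    else:
        for p, (i, j) in zip(params, _param_pairs("ARD", k)):
            Q[i, j] = p
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateModel(model_class, k, params, Q)


def stationary_distribution(model: RateModel) -> np.ndarray:
    """Stationary distribution pi with pi @ Q = 0, summing to one."""
    k = model.k
    # solve the augmented system (Q^T with normalization row)
    a = np.vstack([model.Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass(frozen=True)
class RootPrior:
    """Prior over the root state: equal, stationary, or custom weights."""

    policy: str = "equal"
    weights: np.ndarray | None = None

    def resolve(self, model: RateModel) -> np.ndarray:
        if self.policy == "equal":
            return np.full(model.k, 1.0 / model.k)
        if self.policy == "stationary":
            return stationary_distribution(model)
        if self.policy == "custom":
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (model.k,) or (w < 0).any():
                raise MkError("custom prior needs k non-negative weights")
            if abs(w.sum() - 1.0) > 1e-12:
                raise MkError("custom prior weights must sum to 1")
            return w
        raise MkError(f"unknown root prior policy {self.policy!r}")


def _as_prior(prior) -> RootPrior:
    if isinstance(prior, RootPrior):
        return prior
    if isinstance(prior, str):
        return RootPrior(prior)
    return RootPrior("custom", np.asarray(prior, dtype=float))


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------


def transition_probs(model: RateModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to one."""
    if t < 0:
        raise MkError(f"negative branch length {t}")
    return _transition_probs_batch(model, np.asarray([t], dtype=float))[0]


def _transition_probs_batch(model: RateModel, ts: np.ndarray) -> np.ndarray:
    """exp(Q t) for every t at once via eigendecomposition.

    Q is a small dense generator; for generic rate values it is
    diagonalizable and the spectral route is both exact and much faster than
    per-branch Pade exponentials during optimization.  If the eigenvector
    matrix is ill-conditioned (nearly defective Q), fall back to
    scipy's expm per branch.
    """
    if (ts < 0).any():
        raise MkError("negative branch length")
    k = model.k
    w, v = np.linalg.eig(model.Q)
    use_spectral = True
    try:
        vinv = np.linalg.inv(v)
        if np.linalg.cond(v) > 1e8:
            use_spectral = False
    except np.linalg.LinAlgError:
        use_spectral = False
    if use_spectral:
        ew = np.exp(np.multiply.outer(ts, w))  # (m, k)
        p = np.einsum("ij,mj,jl->mil", v, ew, vinv).real
    else:
        p = np.stack([expm(model.Q * t) for t in ts])
    np.clip(p, 0.0, 1.0, out=p)
    p /= p.sum(axis=2, keepdims=True)
    return p


# ---------------------------------------------------------------------------
# Pruning machinery
# ---------------------------------------------------------------------------


class TreeCharacterData:
    """Postorder-indexed view of (tree, coding) shared by likelihood, ASR
    and stochastic mapping.

    Node ``i`` in postorder; ``children[i]`` are postorder indices;
    ``tip_partial`` holds the observation vector for tips (one-hot, or ones
    for UNKNOWN).  Branch lengths are validated once here.
    """

    def __init__(self, tree: Tree, coding: StateCoding):
        self.tree = tree
        self.alphabet = coding.alphabet
        k = self.alphabet.k
        self.nodes: list[Node] = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.children: list[list[int]] = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        self.root_index = len(self.nodes) - 1
        self.branch_lengths = np.zeros(len(self.nodes))
        for i, n in enumerate(self.nodes):
            if n is tree.root:
                continue
            if n.length is None:
                raise TreeError(f"branch length absent above {n.label!r}")
            self.branch_lengths[i] = n.length
        self.tip_partial = np.zeros((len(self.nodes), k))
        self.tip_state = np.full(len(self.nodes), -1)  # -1: internal or UNKNOWN
        for i, n in enumerate(self.nodes):
            if not n.is_leaf:
                continue
            if n.label not in coding:
                raise MkError(f"tip {n.label!r} has no entry in the coding")
            symbol = coding[n.label]
            if symbol == UNKNOWN:
                self.tip_partial[i] = 1.0
            else:
                s = self.alphabet.index(symbol)
                self.tip_partial[i, s] = 1.0
                self.tip_state[i] = s

    def n_nodes(self) -> int:
        return len(self.nodes)


def _down_pass(data: TreeCharacterData, model: RateModel):
    """Per-node conditional likelihoods of the data below, with scaling.

    Returns ``(P, down, log_scale)`` where ``P[i]`` is the transition matrix
    across the branch above node i, ``down[i, s]`` the (rescaled) likelihood
    of the subtree below i given state s at i, and ``log_scale`` the total
    log of the scaling factors applied.
    """
    if model.k != data.alphabet.k:
        raise MkError("model k does not match alphabet size")
    P = _transition_probs_batch(model, data.branch_lengths)
    n = data.n_nodes()
    down = np.empty((n, model.k))
    log_scale = 0.0
    for i in range(n):
        kids = data.children[i]
        if not kids:
            down[i] = data.tip_partial[i]
            continue
        vec = np.ones(model.k)
        for c in kids:
            vec *= P[c] @ down[c]
        m = vec.max()
        if m <= 0.0:
            raise MkError("zero likelihood: data unreachable under this model")
        vec /= m
        log_scale += np.log(m)
        down[i] = vec
    return P, down, log_scale


def tree_log_likelihood(
    tree: Tree,
    coding: StateCoding,
    model: RateModel,
    prior: RootPrior | str = "equal",
) -> float:
    """Log-likelihood (nats) of the tip data under the model, by pruning."""
    data = tree if isinstance(tree, TreeCharacterData) else TreeCharacterData(tree, coding)
    _, down, log_scale = _down_pass(data, model)
    pi = _as_prior(prior).resolve(model)
    like = float(pi @ down[data.root_index])
    if like <= 0:
        raise MkError("zero likelihood at the root")
    return float(np.log(like) + log_scale)


# ---------------------------------------------------------------------------
# Fitting and model comparison
# ---------------------------------------------------------------------------


@dataclass
class LikelihoodFit:
    """ML fit of one model class to one (tree, coding) dataset."""

    model: RateModel
    lnL: float
    prior: RootPrior
    converged: bool
    n_restarts: int
    restart_lnls: list[float] = field(default_factory=list)
    message: str = ""

    @property
    def model_class(self) -> str:
        return self.model.model_class

    @property
    def n_params(self) -> int:
        return len(self.model.params)


def fit(
    tree: Tree,
    coding: StateCoding,
    model_class: str = "ER",
    prior: RootPrior | str = "equal",
    n_restarts: int = 5,
    seed: int = 0,
) -> LikelihoodFit:
    """Maximum-likelihood rates by box-constrained optimization of log-rates.

    Restarts from dispersed starting points (around the parsimony-flavoured
    guess of one change per unit of total tree length) guard against the
    flat, multimodal surfaces Mk likelihoods are known for.  Non-convergence
    is flagged on the result, not raised: the best point found is still
    reported.
    """
    if model_class not in MODEL_CLASSES:
        raise MkError(f"unknown model class {model_class!r}")
    data = TreeCharacterData(tree, coding)
    k = data.alphabet.k
    npar = n_free_params(model_class, k)
    prior = _as_prior(prior)

    def negloglik(log_rates: np.ndarray) -> float:
        model = build_q(model_class, k, np.exp(log_rates))
        try:
            return -tree_log_likelihood(data, coding, model, prior)
        except MkError:
            return 1e300

    total = max(data.branch_lengths.sum(), 1e-6)
    base = np.log(max(data.n_nodes() / (k * total), 1e-6))
    rng = np.random.default_rng(seed)
    starts = [np.full(npar, base)]
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(base + rng.uniform(-3.0, 3.0, size=npar))
    bounds = [(np.log(RATE_LOWER), np.log(RATE_UPPER))] * npar

    best = None
    restart_lnls = []
    for x0 in starts:
        res = minimize(
            negloglik,
            np.clip(x0, bounds[0][0], bounds[0][1]),
            method="L-BFGS-B",
            bounds=bounds,
        )
        restart_lnls.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    model = build_q(model_class, k, np.exp(best.x))
    return LikelihoodFit(
        model=model,
        lnL=-best.fun,
        prior=prior,
        converged=bool(best.success),
        n_restarts=len(starts),
        restart_lnls=restart_lnls,
        message=str(best.message),
    )


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio comparison of two nested fits.

    ``statistic`` is the conventional 2*(lnL_complex - lnL_simple) used for
    the chi-square p-value; the raw log-likelihood difference is reported
    alongside for transparency.
    """

    statistic: float
    delta_lnl: float
    df: int
    p: float
    simple_class: str
    complex_class: str


_NESTING = {"ER": 0, "SYM": 1, "ARD": 2}


def likelihood_ratio_test(simple: LikelihoodFit, complex: LikelihoodFit) -> LRTResult:
    if _NESTING[simple.model_class] >= _NESTING[complex.model_class]:
        raise MkError(
            f"{simple.model_class} is not nested in {complex.model_class}"
        )
    df = complex.n_params - simple.n_params
    delta = complex.lnL - simple.lnL
    if delta < -1e-6:
        raise MkError(
            "complex model fits worse than the nested simple model; "
            "refit with more restarts"
        )
    stat = max(2.0 * delta, 0.0)
    return LRTResult(
        statistic=stat,
        delta_lnl=delta,
        df=df,
        p=float(chi2.sf(stat, df)),
        simple_class=simple.model_class,
        complex_class=complex.model_class,
    )


def compare_models(
    tree: Tree,
    coding: StateCoding,
    model_classes: Sequence[str] = MODEL_CLASSES,
    prior: RootPrior | str = "equal",
    alpha: float = 0.05,
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[dict[str, LikelihoodFit], list[LRTResult], str]:
    """Fit nested model classes and pick the preferred one by LRT.

    Moving up the nesting chain, a more complex model is adopted only when
    it fits significantly better than the current choice (forward LRT at
    ``alpha``) — the parsimony-of-parameters rule used when SYM beats ER but
    ARD adds nothing.
    Returns (fits, pairwise LRT results, selected class).
    """
    classes = sorted(set(model_classes), key=_NESTING.get)
    fits = {
        mc: fit(tree, coding, mc, prior, n_restarts=n_restarts, seed=seed)
        for mc in classes
    }
    tests = []
    selected = classes[0]
    for a in range(len(classes)):
        for b in range(a + 1, len(classes)):
            tests.append(likelihood_ratio_test(fits[classes[a]], fits[classes[b]]))
    for mc in classes[1:]:
        lrt = likelihood_ratio_test(fits[selected], fits[mc])
        if lrt.p < alpha:
            selected = mc
    return fits, tests, selected


# ---------------------------------------------------------------------------
# Marginal ancestral state reconstruction
# ---------------------------------------------------------------------------


@dataclass
class MarginalASR:
    """Exact marginal posterior state probabilities at every node.

    ``probs[i]`` follows the postorder node order of ``data.nodes``.  Tips
    with a known state sit at probability one on that state; UNKNOWN tips
    get genuine posteriors.
    """

    data: TreeCharacterData
    probs: np.ndarray
    lnL: float

    def for_node(self, node: Node) -> np.ndarray:
        return self.probs[self.data.index[id(node)]]

    @property
    def root_probs(self) -> np.ndarray:
        return self.probs[self.data.root_index]

    def to_frame(self) -> pd.DataFrame:
        """One row per node: id, label, clade tip set, per-state posterior."""
        rows = []
        clades = _clade_signatures(self.data)
        for i, node in enumerate(self.data.nodes):
            row = {
                "node": i,
                "label": node.label or "",
                "is_tip": node.is_leaf,
                "clade": "|".join(clades[i]),
            }
            for s, symbol in enumerate(self.data.alphabet):
                row[f"p_{symbol}"] = self.probs[i, s]
            rows.append(row)
        return pd.DataFrame(rows)


def _clade_signatures(data: TreeCharacterData) -> list[tuple[str, ...]]:
    sigs: list[tuple[str, ...]] = [()] * data.n_nodes()
    for i, node in enumerate(data.nodes):
        if node.is_leaf:
            sigs[i] = (node.label,)
        else:
            acc: list[str] = []
            for c in data.children[i]:
                acc.extend(sigs[c])
            sigs[i] = tuple(sorted(acc))
    return sigs


def marginal_asr(
    tree: Tree,
    coding: StateCoding,
    model: RateModel,
    prior: RootPrior | str = "equal",
) -> MarginalASR:
    """Two-pass exact marginal posteriors at every node.

    Downward pass: conditional likelihood of the data below each node.
    Upward pass: the message from the rest of the tree, computed rootward to
    tipward; the posterior at a node is the normalized product of the two.
    """
    data = tree if isinstance(tree, TreeCharacterData) else TreeCharacterData(tree, coding)
    P, down, log_scale = _down_pass(data, model)
    pi = _as_prior(prior).resolve(model)
    n = data.n_nodes()
    k = model.k

    up = np.empty((n, k))
    up[data.root_index] = pi
    # precompute child messages P_c @ down_c once
    msg = np.einsum("nij,nj->ni", P, down)
    for i in range(n - 1, -1, -1):  # preorder-ish: parents before children
        kids = data.children[i]
        if not kids:
            continue
        child_msgs = [msg[c] for c in kids]
        for pos, c in enumerate(kids):
            sib = up[i].copy()
            for q, m in enumerate(child_msgs):
                if q != pos:
                    sib *= m
            vec = sib @ P[c]
            tot = vec.sum()
            if tot <= 0:
                raise MkError("zero upward message; inconsistent data")
            up[c] = vec / tot

    post = up * down
    totals = post.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise MkError("zero posterior mass at a node")
    post /= totals
    like = float(pi @ down[data.root_index])
    return MarginalASR(data=data, probs=post, lnL=float(np.log(like) + log_scale))
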