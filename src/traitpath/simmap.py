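"""Stochastic character mapping: sampling full trait histories on a tree.

A stochastic map is one draw of the complete character history — a state at
every node plus the exact change points along every branch — from its
posterior distribution given the tip data and a rate model.  Ancestral-state
summaries and directed transition counts are then Monte-Carlo averages over
many sampled maps; unlike parsimony this allows (and counts) multiple
changes per branch.

Sampling is the standard two-stage scheme: node states are drawn root-to-tip
from their joint conditional distribution (root from its marginal posterior;
each child given its parent using the pruning partials), then each branch's
internal path is drawn from the CTMC bridge conditioned on its endpoint
states — by (modified) rejection sampling with a uniformization fallback
that guarantees termination on hard branches.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma, log
from typing import Sequence

import numpy as np
import pandas as pd

from traitpath.coding import StateCoding
from traitpath.mk_model import (
    MkError,
    RateModel,
    RootPrior,
    TreeCharacterData,
    _as_prior,
    _down_pass,
)
from traitpath.treeio import Tree

__all__ = [
    "StochasticMap",
    "SimmapSummary",
    "SimmapSampler",
    "sample_history",
    "sample_histories",
    "count_transitions",
    "summarize",
    "write_simmap_newick",
]

REJECTION_CAP = 10_000


@dataclass
class StochasticMap:
    """One sampled character history.

    ``segments[i]`` covers the branch above postorder node ``i``, ordered
    parent to child, as ``(state_index, dwell_time)`` pairs; consecutive
    segments differ in state and dwell times sum to the branch length.  The
    root has no branch and an empty segment list.
    """

    data: TreeCharacterData
    node_states: np.ndarray
    segments: list[list[tuple[int, float]]]
    model: RateModel

    def n_transitions(self) -> int:
        return sum(len(s) - 1 for s in self.segments if s)


def count_transitions(smap: StochasticMap) -> np.ndarray:
    """Directed change counts: entry (i, j) = number of i->j jumps."""
    k = smap.model.k
    counts = np.zeros((k, k), dtype=int)
    for segs in smap.segments:
        for (a, _), (b, _) in zip(segs, segs[1:]):
            counts[a, b] += 1
    return counts


@dataclass
class SimmapSummary:
    """Averages over a collection of stochastic maps on one tree."""

    n_maps: int
    mean_transitions: np.ndarray  # k x k, mean directed counts
    node_state_freq: np.ndarray  # n_nodes x k, frequency each state was sampled
    time_in_state: np.ndarray  # n_nodes x k, mean fraction of branch in state
    alphabet_symbols: tuple[str, ...]

    def transitions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.mean_transitions,
            index=self.alphabet_symbols,
            columns=self.alphabet_symbols,
        )


def summarize(maps: Sequence[StochasticMap]) -> SimmapSummary:
    """Mean transition counts, node-state frequencies, and per-branch
    time-in-state fractions across maps.

    All maps must come from the same tree/coding (same postorder layout).
    """
    if not maps:
        raise MkError("need at least one map")
    data = maps[0].data
    for m in maps[1:]:
        if m.data is not data and [n.label for n in m.data.nodes] != [
            n.label for n in data.nodes
        ]:
            raise MkError("maps were sampled on different trees")
    k = maps[0].model.k
    n = data.n_nodes()
    mean_t = np.zeros((k, k))
    freq = np.zeros((n, k))
    tis = np.zeros((n, k))
    for m in maps:
        mean_t += count_transitions(m)
        freq[np.arange(n), m.node_states] += 1.0
        for i, segs in enumerate(m.segments):
            if not segs:
                continue
            total = data.branch_lengths[i]
            if total > 0:
                for state, dwell in segs:
                    tis[i, state] += dwell / total
            else:
                tis[i, segs[0][0]] += 1.0
    nm = len(maps)
    return SimmapSummary(
        n_maps=nm,
        mean_transitions=mean_t / nm,
        node_state_freq=freq / nm,
        time_in_state=tis / nm,
        alphabet_symbols=data.alphabet.symbols,
    )


class SimmapSampler:
    """Reusable sampler: pruning pass done once, then cheap repeated draws."""

    def __init__(
        self,
        tree: Tree,
        coding: StateCoding,
        model: RateModel,
        prior: RootPrior | str = "equal",
    ):
        self.data = (
            tree
            if isinstance(tree, TreeCharacterData)
            else TreeCharacterData(tree, coding)
        )
        self.model = model
        self.P, self.down, _ = _down_pass(self.data, model)
        self.pi = _as_prior(prior).resolve(model)
        self.rates = -np.diag(model.Q)
        k = model.k
        self.mu = float(self.rates.max())
        if self.mu > 0:
            self.R = np.eye(k) + model.Q / self.mu  # uniformized jump matrix
        else:
            self.R = np.eye(k)
        # jump distribution for forward simulation
        self.jump_probs = np.zeros((k, k))
        for i in range(k):
            if self.rates[i] > 0:
                self.jump_probs[i] = model.Q[i] / self.rates[i]
                self.jump_probs[i, i] = 0.0

    # -- node states ----------------------------------------------------

    def _sample_node_states(self, rng: np.random.Generator) -> np.ndarray:
        data, P, down = self.data, self.P, self.down
        states = np.full(data.n_nodes(), -1)
        w = self.pi * down[data.root_index]
        states[data.root_index] = _choice(rng, w)
        for i in range(data.n_nodes() - 1, -1, -1):  # parents before children
            s = states[i]
            for c in data.children[i]:
                states[c] = _choice(rng, P[c][s] * down[c])
        return states

    # -- endpoint-conditioned paths --------------------------------------

    def _forward(self, a: int, t: float, rng) -> list[tuple[int, float]]:
        """Unconditioned CTMC path from state ``a`` over duration ``t``."""
        segs = []
        state, elapsed = a, 0.0
        while True:
            rate = self.rates[state]
            wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if elapsed + wait >= t:
                segs.append((state, t - elapsed))
                return segs
            segs.append((state, wait))
            elapsed += wait
            state = _choice(rng, self.jump_probs[state])

    def _reject_path(self, a: int, b: int, t: float, rng):
        """Modified rejection sampling of the (a -> b, t) bridge.

        Equal endpoints: plain forward simulation, accept on a match.
        Unequal endpoints: at least one jump must occur, so the first jump
        time is drawn from the exponential truncated to (0, t) before
        resuming plain forward simulation — otherwise acceptance collapses
        on short branches.
        """
        ra = self.rates[a]
        for _ in range(REJECTION_CAP):
            if a == b:
                segs = self._forward(a, t, rng)
            else:
                if ra <= 0:
                    return None  # absorbing start can never reach b
                u = rng.random()
                tau = -log(1.0 - u * (1.0 - exp(-ra * t))) / ra
                first = _choice(rng, self.jump_probs[a])
                segs = [(a, tau)] + self._forward(first, t - tau, rng)
            if segs[-1][0] == b:
                return _merge_segments(segs)
        return None

    def _uniformization_path(self, a: int, b: int, t: float, rng):
        """Exact bridge via uniformization; terminates on any feasible pair.

        The number of candidate (possibly virtual) jumps N is drawn from its
        conditional distribution given the endpoints, intermediate states
        from the discrete bridge of the uniformized chain, jump times as
        uniform order statistics; virtual self-jumps are then erased.
        """
        if self.mu <= 0 or t == 0.0:
            if a != b:
                raise MkError(f"endpoint pair {a}->{b} unreachable on branch")
            return [(a, t)]
        from traitpath.mk_model import _transition_probs_batch

        pab = float(_transition_probs_batch(self.model, np.array([t]))[0][a, b])
        if pab <= 0.0:
            raise MkError(f"endpoint pair {a}->{b} unreachable (P=0)")
        mu_t = self.mu * t
        # sample N | endpoints
        u = rng.random()
        rpows = [np.eye(self.model.k)]
        acc = 0.0
        n = -1
        while True:
            n += 1
            if n > 0:
                rpows.append(rpows[-1] @ self.R)
            w = exp(-mu_t + n * log(mu_t) - lgamma(n + 1)) * rpows[n][a, b] / pab
            acc += w
            if u <= acc or n > 10_000:
                break
        if n == 0:
            return [(a, t)]
        # intermediate states of the discrete bridge
        states = [a]
        for m in range(1, n):
            prev = states[-1]
            wvec = self.R[prev] * rpows[n - m][:, b]
            states.append(_choice(rng, wvec))
        states.append(b)
        times = np.sort(rng.random(n)) * t
        segs = []
        bounds = [0.0] + list(times) + [t]
        for s, lo, hi in zip(states, bounds[:-1], bounds[1:]):
            segs.append((s, hi - lo))
        return _merge_segments(segs)

    def sample_branch_path(self, a: int, b: int, t: float, rng):
        segs = self._reject_path(a, b, t, rng)
        if segs is None:
            segs = self._uniformization_path(a, b, t, rng)
        return segs

    # -- full maps --------------------------------------------------------

    def sample(self, rng: np.random.Generator) -> StochasticMap:
        data = self.data
        states = self._sample_node_states(rng)
        segments: list[list[tuple[int, float]]] = [[] for _ in range(data.n_nodes())]
        for i in range(data.n_nodes()):
            if data.nodes[i] is data.tree.root:
                continue
            parent = data.index[id(data.nodes[i].parent)]
            segments[i] = self.sample_branch_path(
                int(states[parent]), int(states[i]), float(data.branch_lengths[i]), rng
            )
        return StochasticMap(
            data=data, node_states=states, segments=segments, model=self.model
        )


def _choice(rng: np.random.Generator, weights: np.ndarray) -> int:
    total = weights.sum()
    if total <= 0:
        raise MkError("cannot sample from all-zero weights")
    return int(np.searchsorted(np.cumsum(weights), rng.random() * total, side="right"))


def _merge_segments(segs: list[tuple[int, float]]) -> list[tuple[int, float]]:
    out: list[tuple[int, float]] = []
    for state, dwell in segs:
        if out and out[-1][0] == state:
            out[-1] = (state, out[-1][1] + dwell)
        else:
            out.append((state, dwell))
    return out


def sample_history(
    tree: Tree,
    coding: StateCoding,
    model: RateModel,
    prior: RootPrior | str = "equal",
    seed: int | np.random.Generator = 0,
) -> StochasticMap:
    """Draw one stochastic map; reproducible given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return SimmapSampler(tree, coding, model, prior).sample(rng)


def sample_histories(
    tree: Tree,
    coding: StateCoding,
    model: RateModel,
    prior: RootPrior | str = "equal",
    n: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[StochasticMap]:
    """Draw ``n`` independent maps from one prepared sampler."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sampler = SimmapSampler(tree, coding, model, prior)
    return [sampler.sample(rng) for _ in range(n)]


def write_simmap_newick(smap: StochasticMap) -> str:
    """Serialize one map in the simmap-annotated Newick dialect.

    Each branch length is replaced by ``{state,time:state,time:...}`` with
    segments listed parent to child.
    """
    symbols = smap.data.alphabet.symbols

    def annot(i: int) -> str:
        parts = [f"{symbols[s]},{dwell:.10g}" for s, dwell in smap.segments[i]]
        return "{" + ":".join(parts) + "}"

    def render(node) -> str:
        i = smap.data.index[id(node)]
        if node.is_leaf:
            core = _quote(node.label)
        else:
            core = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.label:
                core += _quote(node.label)
        if node.parent is not None:
            core += ":" + annot(i)
        return core

    return render(smap.data.tree.root) + ";"


def _quote(label: str) -> str:
    if any(c in label for c in " (){}[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label
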