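"""Independent brute-force oracles used to validate the DP/pruning engines.

Everything here enumerates explicitly (all internal-state assignments, all
labelings) and is deliberately written against the model definitions, not
against the package's own algorithms.
"""

from __future__ import annotations

import itertools
import random

import numpy as np

from traitpath.coding import UNKNOWN, StateCoding
from traitpath.mk_model import RateModel, _as_prior, transition_probs
from traitpath.treeio import Node, Tree


def brute_force_likelihood(
    tree: Tree, coding: StateCoding, model: RateModel, prior="equal"
) -> float:
    """Sum over all internal-state assignments; tips marginalized directly."""
    pi = _as_prior(prior).resolve(model)
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    P = {id(n): transition_probs(model, n.length) for n in nodes if n.parent}
    alphabet = coding.alphabet
    total = 0.0
    for assign in itertools.product(range(model.k), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        pr = pi[amap[id(tree.root)]]
        for n in nodes:
            if n.parent is None:
                continue
            ps = amap[id(n.parent)]
            if n.is_leaf:
                sym = coding[n.label]
                if sym != UNKNOWN:
                    pr *= P[id(n)][ps, alphabet.index(sym)]
            else:
                pr *= P[id(n)][ps, amap[id(n)]]
        total += pr
    return float(np.log(total))


def brute_force_node_posterior(
    tree: Tree, coding: StateCoding, model: RateModel, node: Node, prior="equal"
) -> np.ndarray:
    """P(node = s | tip data) by enumeration over internal assignments."""
    pi = _as_prior(prior).resolve(model)
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    P = {id(n): transition_probs(model, n.length) for n in nodes if n.parent}
    alphabet = coding.alphabet
    post = np.zeros(model.k)
    for assign in itertools.product(range(model.k), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        pr = pi[amap[id(tree.root)]]
        for n in nodes:
            if n.parent is None:
                continue
            ps = amap[id(n.parent)]
            if n.is_leaf:
                sym = coding[n.label]
                if sym != UNKNOWN:
                    pr *= P[id(n)][ps, alphabet.index(sym)]
            else:
                pr *= P[id(n)][ps, amap[id(n)]]
        post[amap[id(node)]] += pr
    return post / post.sum()


def fitch_count(tree: Tree, coding: StateCoding) -> int:
    """Fitch's 1971 set method; bifurcating trees, no UNKNOWN tips."""
    changes = 0
    sets: dict[int, frozenset[int]] = {}
    for n in tree.postorder():
        if n.is_leaf:
            sets[id(n)] = frozenset({coding.alphabet.index(coding[n.label])})
            continue
        assert len(n.children) == 2, "Fitch oracle needs bifurcating trees"
        a, b = (sets[id(c)] for c in n.children)
        inter = a & b
        if inter:
            sets[id(n)] = inter
        else:
            sets[id(n)] = a | b
            changes += 1
    return changes


def enumerate_parsimony_stats(tree: Tree, coding: StateCoding):
    """All MPRs by explicit product enumeration (small trees).

    Returns (min_cost, n_mprs, directed change totals (k,k) over all MPRs,
    per-node per-state MPR counts keyed by postorder index).
    """
    k = coding.alphabet.k
    nodes = list(tree.postorder())
    pos = {id(n): i for i, n in enumerate(nodes)}
    allowed = []
    for n in nodes:
        if n.is_leaf:
            sym = coding[n.label]
            allowed.append(
                tuple(range(k))
                if sym == UNKNOWN
                else (coding.alphabet.index(sym),)
            )
        else:
            allowed.append(tuple(range(k)))
    parents = [pos[id(n.parent)] if n.parent else None for n in nodes]
    best_cost = None
    n_best = 0
    totals = np.zeros((k, k), dtype=np.int64)
    node_counts = np.zeros((len(nodes), k), dtype=np.int64)
    for combo in itertools.product(*allowed):
        cost = sum(
            1
            for i in range(len(nodes))
            if parents[i] is not None and combo[i] != combo[parents[i]]
        )
        if best_cost is None or cost < best_cost:
            best_cost = cost
            n_best = 0
            totals[:] = 0
            node_counts[:] = 0
        if cost == best_cost:
            n_best += 1
            for i in range(len(nodes)):
                node_counts[i, combo[i]] += 1
                if parents[i] is not None and combo[i] != combo[parents[i]]:
                    totals[combo[parents[i]], combo[i]] += 1
    return best_cost, n_best, totals, node_counts


def random_tree(
    rnd: random.Random,
    n_tips: int,
    with_lengths: bool = True,
    allow_polytomies: bool = True,
    label_prefix: str = "T",
) -> Tree:
    """Random rooted topology by repeated joining; optional polytomies."""
    nodes = [Node(label=f"{label_prefix}{i}") for i in range(n_tips)]
    while len(nodes) > 1:
        m = rnd.randint(2, min(3, len(nodes))) if allow_polytomies else 2
        picks = [nodes.pop(rnd.randrange(len(nodes))) for _ in range(m)]
        parent = Node()
        for p in picks:
            parent.add_child(p)
        nodes.append(parent)
    tree = Tree(nodes[0])
    if with_lengths:
        for n in tree.postorder():
            if n.parent is not None:
                n.length = round(rnd.uniform(0.05, 2.0), 6)
    return tree


def random_coding(
    rnd: random.Random, tree: Tree, symbols=("H", "S", "A"), p_unknown: float = 0.2
) -> StateCoding:
    states = {}
    for label in tree.leaf_labels():
        if rnd.random() < p_unknown:
            states[label] = UNKNOWN
        else:
            states[label] = rnd.choice(symbols)
    return StateCoding(states)
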