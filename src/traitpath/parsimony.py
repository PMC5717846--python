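"""Unordered-state maximum parsimony with exact MPR-averaged change counts.

Sankoff's dynamic program (unit cost between distinct states, zero for
identity, branch lengths ignored, polytomies allowed) gives the minimal
number of changes.  Because many most-parsimonious reconstructions (MPRs)
usually exist, directed change counts are reported as the *uniform average
over all MPRs*: the DP is extended to carry, per node and state, the exact
number of minimal-cost labelings of the subtree and the per-type change
totals summed over them, so the average is exact (rational arithmetic) and
needs no enumeration.  An explicit enumeration path is provided as an
independent oracle for small trees.

Tips coded UNKNOWN are fully ambiguous — they may take any state, exactly as
in the likelihood treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from math import inf
from typing import Iterable

import numpy as np

from traitpath.coding import UNKNOWN, StateAlphabet, StateCoding
from traitpath.treeio import Node, Tree

__all__ = [
    "ParsimonyResult",
    "ParsimonyError",
    "sankoff_cost",
    "mpr_average_transitions",
    "node_state_assignments",
    "enumerate_reconstructions",
]


class ParsimonyError(ValueError):
    pass


class _Index:
    """Postorder node layout plus per-tip allowed state sets."""

    def __init__(self, tree: Tree, coding: StateCoding):
        self.tree = tree
        self.alphabet: StateAlphabet = coding.alphabet
        self.nodes: list[Node] = list(tree.postorder())
        self.pos = {id(n): i for i, n in enumerate(self.nodes)}
        self.children = [
            [self.pos[id(c)] for c in n.children] for n in self.nodes
        ]
        self.root = len(self.nodes) - 1
        k = self.alphabet.k
        self.allowed: list[tuple[int, ...]] = []
        for n in self.nodes:
            if not n.is_leaf:
                self.allowed.append(tuple(range(k)))
                continue
            if n.label not in coding:
                raise ParsimonyError(f"tip {n.label!r} has no entry in the coding")
            symbol = coding[n.label]
            if symbol == UNKNOWN:
                self.allowed.append(tuple(range(k)))
            else:
                self.allowed.append((self.alphabet.index(symbol),))


def _cost_vectors(index: _Index) -> list[list[float]]:
    k = index.alphabet.k
    cost: list[list[float]] = [None] * len(index.nodes)
    for i, kids in enumerate(index.children):
        if not kids:
            cost[i] = [0 if s in index.allowed[i] else inf for s in range(k)]
            continue
        vec = []
        for s in range(k):
            total = 0
            for c in kids:
                total += min(
                    cost[c][j] + (0 if j == s else 1) for j in range(k)
                )
            vec.append(total)
        cost[i] = vec
    return cost


def sankoff_cost(tree: Tree, coding: StateCoding):
    """Per-node Sankoff cost vectors and the minimal total change count.

    Returns ``(cost, min_cost)`` with ``cost`` a list over postorder nodes
    of per-state minimal subtree costs (``inf`` where a tip forbids a state).
    """
    index = _Index(tree, coding)
    cost = _cost_vectors(index)
    return cost, int(min(cost[index.root]))


@dataclass
class ParsimonyResult:
    """Exact parsimony summary over all most-parsimonious reconstructions."""

    min_cost: int
    mpr_count: int
    #: k x k directed change counts averaged uniformly over all MPRs (exact)
    avg_transitions_exact: list[list[Fraction]]
    #: per node (postorder) and state: fraction of MPRs assigning that state
    node_fractions_exact: list[list[Fraction]]
    alphabet: StateAlphabet
    nodes: list[Node]
    _pos: dict[int, int]

    @property
    def avg_transitions(self) -> np.ndarray:
        return np.array(
            [[float(x) for x in row] for row in self.avg_transitions_exact]
        )

    @property
    def node_fractions(self) -> np.ndarray:
        return np.array(
            [[float(x) for x in row] for row in self.node_fractions_exact]
        )

    def state_set(self, node: Node) -> set[str]:
        """States the node takes in at least one MPR."""
        row = self.node_fractions_exact[self._pos[id(node)]]
        return {
            self.alphabet.symbols[s] for s, f in enumerate(row) if f > 0
        }


def mpr_average_transitions(tree: Tree, coding: StateCoding) -> ParsimonyResult:
    """Minimal cost, MPR count, exact uniform-average directed change counts,
    and per-node MPR state fractions — all without enumeration.

    Downward pass per node/state: the number of minimal labelings of the
    subtree and their summed change-count matrices.  Upward pass: the number
    of ways to complete each (node, state) choice outside its subtree, giving
    per-node state frequencies across all MPRs.  Integer arithmetic is exact
    (Python integers never overflow); averages are returned as Fractions.
    """
    index = _Index(tree, coding)
    k = index.alphabet.k
    n = len(index.nodes)
    cost = _cost_vectors(index)

    zero = [[0] * k for _ in range(k)]
    count: list[list[int]] = [None] * n  # N_v(s)
    trans: list[list[list[list[int]]]] = [None] * n  # T_v(s): k x k totals
    argmin: list[list[list[int]] | None] = [None] * n  # A_c(s) per node

    for i, kids in enumerate(index.children):
        if not kids:
            count[i] = [1 if cost[i][s] == 0 else 0 for s in range(k)]
            trans[i] = [zero for _ in range(k)]
            continue
        cnt_i = []
        tr_i = []
        for s in range(k):
            if cost[i][s] == inf:
                cnt_i.append(0)
                tr_i.append(zero)
                continue
            per_child_n = []
            per_child_t = []
            for c in kids:
                best = min(cost[c][j] + (0 if j == s else 1) for j in range(k))
                nsum = 0
                tsum = [[0] * k for _ in range(k)]
                for j in range(k):
                    if cost[c][j] + (0 if j == s else 1) != best:
                        continue
                    nc = count[c][j]
                    if nc == 0:
                        continue
                    nsum += nc
                    tcj = trans[c][j]
                    for a in range(k):
                        row = tcj[a]
                        ta = tsum[a]
                        for b in range(k):
                            ta[b] += row[b]
                    if j != s:
                        tsum[s][j] += nc
                per_child_n.append(nsum)
                per_child_t.append(tsum)
            ntot = 1
            for v in per_child_n:
                ntot *= v
            ttot = [[0] * k for _ in range(k)]
            if ntot:
                for ci in range(len(kids)):
                    other = 1
                    for cj in range(len(kids)):
                        if cj != ci:
                            other *= per_child_n[cj]
                    if other == 0:
                        continue
                    tci = per_child_t[ci]
                    for a in range(k):
                        for b in range(k):
                            ttot[a][b] += tci[a][b] * other
            cnt_i.append(ntot)
            tr_i.append(ttot)
        count[i] = cnt_i
        trans[i] = tr_i

    root = index.root
    min_cost = min(cost[root])
    best_states = [s for s in range(k) if cost[root][s] == min_cost]
    mpr_count = sum(count[root][s] for s in best_states)
    if mpr_count == 0:
        raise ParsimonyError("no reconstruction exists (contradictory coding)")
    total = [[0] * k for _ in range(k)]
    for s in best_states:
        for a in range(k):
            for b in range(k):
                total[a][b] += trans[root][s][a][b]
    avg = [[Fraction(total[a][b], mpr_count) for b in range(k)] for a in range(k)]

    # upward pass: ways to complete the labeling outside each subtree
    outside: list[list[int]] = [[0] * k for _ in range(n)]
    for s in best_states:
        outside[root][s] = 1
    for i in range(n - 1, -1, -1):  # parents before children (reverse postorder)
        kids = index.children[i]
        if not kids:
            continue
        for s in range(k):
            if outside[i][s] == 0:
                continue
            # per-child optimal sets and counts given parent state s
            sets = []
            nsums = []
            for c in kids:
                best = min(cost[c][j] + (0 if j == s else 1) for j in range(k))
                js = [
                    j
                    for j in range(k)
                    if cost[c][j] + (0 if j == s else 1) == best and count[c][j] > 0
                ]
                sets.append(js)
                nsums.append(sum(count[c][j] for j in js))
            for pos, c in enumerate(kids):
                other = outside[i][s]
                for q, nsum in enumerate(nsums):
                    if q != pos:
                        other *= nsum
                if other == 0:
                    continue
                for j in sets[pos]:
                    outside[c][j] += other

    node_fracs = [
        [
            Fraction(outside[i][s] * count[i][s], mpr_count)
            for s in range(k)
        ]
        for i in range(n)
    ]
    return ParsimonyResult(
        min_cost=int(min_cost),
        mpr_count=mpr_count,
        avg_transitions_exact=avg,
        node_fractions_exact=node_fracs,
        alphabet=index.alphabet,
        nodes=index.nodes,
        _pos=index.pos,
    )


def node_state_assignments(result: ParsimonyResult, node: Node) -> dict[str, Fraction]:
    """Fraction of MPRs assigning each state to ``node``; sums to one.

    A node split evenly between two states is "equally parsimonious" — the
    half-and-half boxes of a parsimony cladogram.
    """
    if id(node) not in result._pos:
        raise ParsimonyError("node is not part of this result's tree")
    row = result.node_fractions_exact[result._pos[id(node)]]
    return {sym: row[s] for s, sym in enumerate(result.alphabet.symbols)}


def enumerate_reconstructions(tree: Tree, coding: StateCoding):
    """Explicitly enumerate all MPRs (small trees only): the test oracle.

    Returns ``(min_cost, labelings)`` where each labeling maps postorder
    node index -> state index, including tips (UNKNOWN tips range over all
    states; a tip assignment differing from its parent counts as a change,
    exactly as in the DP).
    """
    index = _Index(tree, coding)
    n = len(index.nodes)
    if sum(1 for nd in index.nodes if nd.is_leaf) > 12:
        raise ParsimonyError("enumeration oracle is for small trees")
    parents = [None] * n
    for i, kids in enumerate(index.children):
        for c in kids:
            parents[c] = i
    best_cost = None
    best: list[dict[int, int]] = []
    for combo in product(*(index.allowed[i] for i in range(n))):
        cost = 0
        for i in range(n):
            if parents[i] is not None and combo[i] != combo[parents[i]]:
                cost += 1
        if best_cost is None or cost < best_cost:
            best_cost = cost
            best = [dict(enumerate(combo))]
        elif cost == best_cost:
            best.append(dict(enumerate(combo)))
    return best_cost, best
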