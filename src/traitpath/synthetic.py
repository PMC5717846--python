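"""Synthetic trees and characters with recorded ground-truth histories.

The generator mirrors the statistical shape of a species-level sexual-mode
dataset: a clade-structured tree of ~165 animal tips, a three-state
character (hermaphrodite / separate sexes / asexual) whose states cluster
within clades because they are inherited, a small asexual minority, and a
substantial fraction of tips whose state is unknown.  Every simulation
retains the full true history (states at nodes and change points along
branches), so inference can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from traitpath.coding import UNKNOWN, StateCoding, DEFAULT_ALPHABET
from traitpath.mk_model import (
    RateModel,
    RootPrior,
    TreeCharacterData,
    _as_prior,
    build_q,
)
from traitpath.simmap import StochasticMap, _merge_segments
from traitpath.treeio import Node, Tree

__all__ = [
    "SimulatedDataset",
    "simulate_yule_tree",
    "simulate_mk",
    "mask_tips",
    "make_study_like_fixture",
    "STUDY_CLADE_SIZES",
    "STUDY_TRUE_MODEL",
]

#: clade sizes of the study-like tree: sponges, bilaterians, cnidarians,
#: ctenophores, placozoan
STUDY_CLADE_SIZES = {
    "Porifera": 62,
    "Bilateria": 60,
    "Cnidaria": 31,
    "Ctenophora": 11,
    "Placozoa": 1,
}

#: true generating model of the study-like fixture (ARD order:
#: H->S, H->A, S->H, S->A, A->H, A->S).  The separate-sexes ->
#: hermaphrodite rate exceeds the reverse, and asexuality is rare —
#: the directional structure the real data display.
STUDY_TRUE_MODEL = build_q(
    "ARD", 3, [0.35, 0.01, 0.65, 0.03, 0.02, 0.02]
)


@dataclass
class SimulatedDataset:
    """A simulated (tree, character) pair with its generating truth."""

    tree: Tree
    model: RateModel
    prior: RootPrior
    root_state: int
    history: StochasticMap
    true_coding: StateCoding
    observed_coding: StateCoding
    seed: int | None = None

    def true_transition_counts(self) -> np.ndarray:
        from traitpath.simmap import count_transitions

        return count_transitions(self.history)


def simulate_yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
    label_prefix: str = "T",
    mean_depth: float | None = None,
) -> Tree:
    """Pure-birth tree: while k lineages are alive the next split waits an
    Exp(k*birth_rate) time; simulation stops at the n-th tip, so all tips are
    contemporaneous and the root-to-tip depth is sum_{k=2..n} Exp(k*lambda).

    ``mean_depth`` rescales all branches so the root-to-tip depth equals it —
    the unit-height convention under which substitution-like rates are
    expressed per unit of tree height and stay identifiable regardless of
    tip count (an unscaled large Yule tree is deep, and a fast character
    saturates on it).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if not birth_rate > 0:
        raise ValueError("birth rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = Node()
    active = [Node(length=0.0), Node(length=0.0)]
    for child in active:
        root.add_child(child)
    k = 2
    while True:
        wait = rng.exponential(1.0 / (birth_rate * k))
        for tip in active:
            tip.length += wait
        if k == n_tips:
            break
        splitter = active[rng.integers(len(active))]
        a, b = Node(length=0.0), Node(length=0.0)
        splitter.add_child(a)
        splitter.add_child(b)
        active.remove(splitter)
        active.extend([a, b])
        k += 1
    width = max(len(str(n_tips)), 3)
    for i, tip in enumerate(active, start=1):
        tip.label = f"{label_prefix}{i:0{width}d}"
    tree = Tree(root)
    if mean_depth is not None:
        if not mean_depth > 0:
            raise ValueError("mean_depth must be positive")
        depth = float(np.mean(list(tree.depths().values())))
        for nd in tree.postorder():
            if nd.length is not None:
                nd.length *= mean_depth / depth
    return tree


def _gillespie_branch(
    start: int, t: float, Q: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, float]]:
    rates = -np.diag(Q)
    segs = []
    state, elapsed = start, 0.0
    while True:
        rate = rates[state]
        wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        if elapsed + wait >= t:
            segs.append((state, t - elapsed))
            return _merge_segments(segs)
        segs.append((state, wait))
        elapsed += wait
        w = Q[state].copy()
        w[state] = 0.0
        state = int(np.searchsorted(np.cumsum(w), rng.random() * w.sum(), side="right"))


def simulate_mk(
    tree: Tree,
    model: RateModel,
    prior: RootPrior | str = "equal",
    seed: int | np.random.Generator = 0,
) -> SimulatedDataset:
    """Forward-simulate a character down the tree, recording the history.

    The root state is drawn from the prior; each branch evolves by Gillespie
    simulation (exponential waits, jumps proportional to off-diagonal
    rates).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prior = _as_prior(prior)
    pi = prior.resolve(model)
    alphabet = DEFAULT_ALPHABET if model.k == 3 else None
    if alphabet is None or model.k != alphabet.k:
        from traitpath.coding import StateAlphabet

        alphabet = StateAlphabet(tuple(f"S{i}" for i in range(model.k)))

    nodes = list(tree.postorder())
    order = list(reversed(nodes))  # parents before children
    states: dict[int, int] = {}
    segments: dict[int, list[tuple[int, float]]] = {}
    states[id(tree.root)] = int(
        np.searchsorted(np.cumsum(pi), rng.random() * pi.sum(), side="right")
    )
    for node in order:
        if node is tree.root:
            continue
        if node.length is None:
            raise ValueError(f"branch length absent above {node.label!r}")
        segs = _gillespie_branch(states[id(node.parent)], node.length, model.Q, rng)
        segments[id(node)] = segs
        states[id(node)] = segs[-1][0]

    true_coding = StateCoding(
        {n.label: alphabet.symbols[states[id(n)]] for n in tree.leaves()},
        alphabet,
    )
    data = TreeCharacterData(tree, true_coding)
    node_states = np.array([states[id(n)] for n in data.nodes])
    seg_list = [segments.get(id(n), []) for n in data.nodes]
    history = StochasticMap(
        data=data, node_states=node_states, segments=seg_list, model=model
    )
    return SimulatedDataset(
        tree=tree,
        model=model,
        prior=prior,
        root_state=int(node_states[data.root_index]),
        history=history,
        true_coding=true_coding,
        observed_coding=true_coding,
    )


def mask_tips(
    coding: StateCoding,
    n_mask: int,
    seed: int | np.random.Generator = 0,
    clade_weights: dict[str, float] | None = None,
) -> StateCoding:
    """Set ``n_mask`` species to UNKNOWN.

    Uniform at random by default; ``clade_weights`` (prefix before the first
    underscore -> relative weight) biases masking into particular clades,
    imitating datasets where the uncharacterized species concentrate in
    poorly studied groups.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    species = list(coding.states)
    if n_mask > len(species):
        raise ValueError("cannot mask more species than exist")
    if clade_weights:
        w = np.array(
            [clade_weights.get(sp.split("_", 1)[0], 1.0) for sp in species]
        )
        w = w / w.sum()
        picks = rng.choice(len(species), size=n_mask, replace=False, p=w)
    else:
        picks = rng.choice(len(species), size=n_mask, replace=False)
    states = dict(coding.states)
    for i in picks:
        states[species[i]] = UNKNOWN
    return StateCoding(states, coding.alphabet)


def _study_tree(rng: np.random.Generator) -> Tree:
    """Clade-structured 165-tip tree with rate-heterogeneous branch lengths.

    Each clade is a Yule tree; clades hang off a ctenophore-sister backbone
    (ctenophores sister to all other animals, then sponges, then placozoan,
    then cnidarians + bilaterians).  Lognormal branch-specific rate noise
    breaks the clock, as single-gene molecular lengths do, and the whole
    tree is rescaled to mean root-to-tip depth 1.
    """
    clades = {}
    for name, size in STUDY_CLADE_SIZES.items():
        if size == 1:
            clades[name] = Node(label=f"{name}_sp001", length=0.5)
        else:
            sub = simulate_yule_tree(
                size, birth_rate=1.0, seed=rng, label_prefix=f"{name}_sp"
            )
            # normalize each clade to unit depth before placing on backbone
            depth = max(sub.depths().values())
            for nd in sub.postorder():
                if nd.length is not None:
                    nd.length /= depth
            root = sub.root
            root.length = 0.5
            clades[name] = root

    def join(a: Node, b: Node, stem: float) -> Node:
        parent = Node(length=stem)
        parent.add_child(a)
        parent.add_child(b)
        return parent

    cb = join(clades["Cnidaria"], clades["Bilateria"], 0.3)
    pcb = join(clades["Placozoa"], cb, 0.3)
    inner = join(clades["Porifera"], pcb, 0.3)
    root = Node()
    root.add_child(clades["Ctenophora"])
    root.add_child(inner)
    tree = Tree(root)
    for nd in tree.postorder():
        if nd.length is not None:
            nd.length *= rng.lognormal(0.0, 0.4)
    depths = tree.depths().values()
    scale = float(np.mean(list(depths)))
    for nd in tree.postorder():
        if nd.length is not None:
            nd.length /= scale
    return tree


def make_study_like_fixture(
    seed: int = 0,
    target_counts: tuple[int, int, int] = (54, 83, 3),  # H, S, A among observed
    n_unknown: int = 25,
    tolerance: int = 10,
    max_attempts: int = 500,
) -> SimulatedDataset:
    """A 165-tip dataset shaped like the sexual-mode study data.

    The tree has clades of 62 sponges, 60 bilaterians, 31 cnidarians, 11
    ctenophores and one placozoan.  The character evolves under
    :data:`STUDY_TRUE_MODEL` from a separate-sexes root; characters are
    re-simulated (fresh randomness, same tree) until the observed counts
    after masking ``n_unknown`` tips land within ``tolerance`` of
    ``target_counts`` (H, S, A), so every generated dataset has the study's
    composition.  Ground truth (model, root state, full history) is kept.
    """
    rng = np.random.default_rng(seed)
    tree = _study_tree(rng)
    model = STUDY_TRUE_MODEL
    prior = RootPrior("custom", np.array([0.0, 1.0, 0.0]))  # gonochoristic root
    target = np.array(target_counts)
    for _ in range(max_attempts):
        ds = simulate_mk(tree, model, prior, seed=rng)
        observed = mask_tips(ds.true_coding, n_unknown, seed=rng)
        counts = np.array(
            [
                sum(1 for v in observed.states.values() if v == s)
                for s in observed.alphabet
            ]
        )
        if (np.abs(counts - target) <= tolerance).all():
            ds.observed_coding = observed
            ds.seed = seed
            return ds
    raise RuntimeError(
        "could not hit the target state composition; "
        "the generating rates and targets are inconsistent"
    )
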