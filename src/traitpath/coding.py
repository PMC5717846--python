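"""Tip-state coding tables for sexual-mode characters.

States follow the study-style coding: ``H`` = simultaneous hermaphrodite,
``S`` = separate sexes (sequential hermaphrodites are coded ``S`` by the
table author, since each individual is a single sex at any moment of its
sexually active life), ``A`` = asexual, and ``?`` = unknown.  UNKNOWN is a
sentinel outside the alphabet: in every downstream algorithm it means "any
state", i.e. a fully ambiguous observation, never a fourth state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from traitpath.treeio import Tree

__all__ = [
    "UNKNOWN",
    "StateAlphabet",
    "StateCoding",
    "DEFAULT_ALPHABET",
    "CodingError",
    "read_state_table",
    "write_state_table",
    "summarize_counts",
    "align_with_tree",
    "ReconciliationReport",
]

UNKNOWN = "?"


class CodingError(ValueError):
    """Invalid state table (bad symbol, duplicate species, ...)."""


@dataclass(frozen=True)
class StateAlphabet:
    """Ordered set of state symbols; the UNKNOWN sentinel is not a member."""

    symbols: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise CodingError("alphabet symbols must be unique")
        if len(self.symbols) < 2:
            raise CodingError("need at least 2 states")
        if UNKNOWN in self.symbols:
            raise CodingError("the UNKNOWN sentinel cannot be a state symbol")

    @property
    def k(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def __iter__(self):
        return iter(self.symbols)


#: hermaphrodite, separate sexes, asexual
DEFAULT_ALPHABET = StateAlphabet(("H", "S", "A"))


@dataclass
class StateCoding:
    """Mapping species label -> state symbol or UNKNOWN."""

    states: dict[str, str]
    alphabet: StateAlphabet = DEFAULT_ALPHABET

    def __post_init__(self):
        for species, symbol in self.states.items():
            if symbol != UNKNOWN and symbol not in self.alphabet:
                raise CodingError(
                    f"species {species!r}: symbol {symbol!r} not in alphabet "
                    f"{self.alphabet.symbols} and not {UNKNOWN!r}"
                )

    def __getitem__(self, species: str) -> str:
        return self.states[species]

    def __contains__(self, species: str) -> bool:
        return species in self.states

    def __len__(self) -> int:
        return len(self.states)

    def is_unknown(self, species: str) -> bool:
        return self.states[species] == UNKNOWN

    def species(self) -> list[str]:
        return list(self.states)

    def with_state(self, species: str, symbol: str) -> "StateCoding":
        """Copy with one species (re)coded."""
        new = dict(self.states)
        new[species] = symbol
        return StateCoding(new, self.alphabet)

    def renamed(self, old: str, new: str) -> "StateCoding":
        states = {new if sp == old else sp: st for sp, st in self.states.items()}
        return StateCoding(states, self.alphabet)

    def restrict(self, species: Iterable[str]) -> "StateCoding":
        keep = set(species)
        return StateCoding(
            {sp: st for sp, st in self.states.items() if sp in keep},
            self.alphabet,
        )


def read_state_table(path, alphabet: StateAlphabet = DEFAULT_ALPHABET) -> StateCoding:
    """Read a CSV/TSV with columns ``species,state[,note]`` into a coding.

    The delimiter is sniffed from the extension (``.tsv``/``.tab`` = tab,
    otherwise comma).  ``?`` maps to UNKNOWN.  Raises :class:`CodingError`
    naming the offending row for unknown symbols or duplicated species.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    if "species" not in cols or "state" not in cols:
        raise CodingError(
            f"state table must have 'species' and 'state' columns, got {list(df.columns)}"
        )
    states: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        species = getattr(row, cols["species"]).strip()
        symbol = getattr(row, cols["state"]).strip()
        if species in states:
            raise CodingError(f"row {i + 2}: duplicate species {species!r}")
        if symbol != UNKNOWN and symbol not in alphabet:
            raise CodingError(
                f"row {i + 2} ({species}): unknown state symbol {symbol!r}"
            )
        states[species] = symbol
    return StateCoding(states, alphabet)


def write_state_table(coding: StateCoding, path) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.DataFrame(
        {"species": list(coding.states), "state": list(coding.states.values())}
    )
    df.to_csv(path, sep=sep, index=False)


def summarize_counts(coding: StateCoding) -> dict[str, int]:
    """Count species per symbol; UNKNOWN counted under ``"?"``."""
    if not coding.states:
        raise CodingError("empty coding")
    counts = {s: 0 for s in coding.alphabet}
    counts[UNKNOWN] = 0
    for symbol in coding.states.values():
        counts[symbol] += 1
    return counts


@dataclass
class ReconciliationReport:
    """Outcome of matching a coding table against a tree's tips.

    ``coding`` covers exactly the tree's tips: direct matches first, then
    (if enabled) genus-level fallbacks, and finally UNKNOWN for anything
    still unmatched — mirroring the convention of coding a species unknown
    when no description exists for it or a congener.
    """

    coding: StateCoding
    tips_missing_from_coding: list[str] = field(default_factory=list)
    coded_missing_from_tree: list[str] = field(default_factory=list)
    genus_fallbacks: dict[str, str] = field(default_factory=dict)  # tip -> donor species

    @property
    def clean(self) -> bool:
        return (
            not self.tips_missing_from_coding
            and not self.coded_missing_from_tree
            and not self.genus_fallbacks
        )


def _genus(label: str) -> str:
    return label.split("_", 1)[0]


def align_with_tree(
    coding: StateCoding, tree: Tree, genus_fallback: bool = False
) -> ReconciliationReport:
    """Reconcile a coding table with a tree, reporting every mismatch.

    With ``genus_fallback`` a tip absent from the table borrows the state of
    a coded congener (same prefix before the first underscore); ambiguity
    (congeners with conflicting states) falls back to UNKNOWN.  Fallback is
    off by default: taxon substitution should be a deliberate, logged act.
    """
    tips = tree.leaf_labels()
    tipset = set(tips)
    by_genus: dict[str, set[str]] = {}
    for sp, st in coding.states.items():
        if st != UNKNOWN:
            by_genus.setdefault(_genus(sp), set()).add(st)

    resolved: dict[str, str] = {}
    report = ReconciliationReport(coding=None)  # filled below
    for tip in tips:
        if tip in coding:
            resolved[tip] = coding[tip]
            continue
        if genus_fallback:
            donors = by_genus.get(_genus(tip), set())
            if len(donors) == 1:
                state = next(iter(donors))
                donor = next(
                    sp
                    for sp, st in coding.states.items()
                    if _genus(sp) == _genus(tip) and st == state
                )
                resolved[tip] = state
                report.genus_fallbacks[tip] = donor
                continue
        resolved[tip] = UNKNOWN
        report.tips_missing_from_coding.append(tip)
    report.coded_missing_from_tree = sorted(set(coding.states) - tipset)
    report.coding = StateCoding(resolved, coding.alphabet)
    return report
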