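"""Orchestration of the full factorial reconstruction analysis.

One run covers every combination of rooting scenario (e.g. ctenophore-sister
vs sponge-sister) and branch-length mode (estimated vs all-equal), and for
each cell: outgroup removal, Mk model fitting and LRT-based selection,
marginal ancestral-state reconstruction, stochastic character mapping on an
ultrametricized tree, and MPR-averaged parsimony.  Internal nodes are
matched across scenarios by their descendant tip sets so reconstructions at
homologous nodes can be compared directly.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from traitpath import mk_model, parsimony, simmap, treeio
from traitpath.coding import StateCoding, align_with_tree, read_state_table
from traitpath.treeio import Tree

__all__ = [
    "AnalysisConfig",
    "ScenarioResult",
    "AnalysisReport",
    "run_full_analysis",
    "tip_swap_sensitivity",
    "spearman_branch_compare",
]


@dataclass
class AnalysisConfig:
    """Inputs and knobs of one full analysis.

    ``trees`` maps a scenario name to a tree (or a Newick file path);
    ``coding`` is a :class:`StateCoding` or a state-table path.
    """

    trees: dict[str, Tree | str]
    coding: StateCoding | str
    outgroups: tuple[str, ...] = ()
    model_classes: tuple[str, ...] = ("ER", "SYM", "ARD")
    branch_modes: tuple[str, ...] = ("estimated", "equal")
    nsim: int = 1000
    seed: int = 0
    root_prior: str = "equal"
    n_restarts: int = 5
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            trees=dict(raw["trees"]),
            coding=raw["states"],
            outgroups=tuple(raw.get("outgroups", ())),
            model_classes=tuple(raw.get("model_classes", ("ER", "SYM", "ARD"))),
            branch_modes=tuple(raw.get("branch_modes", ("estimated", "equal"))),
            nsim=int(raw.get("nsim", 1000)),
            seed=int(raw.get("seed", 0)),
            root_prior=str(raw.get("root_prior", "equal")),
            n_restarts=int(raw.get("n_restarts", 5)),
            output_dir=raw.get("output_dir"),
        )

    def digest(self) -> str:
        parts = [
            ",".join(sorted(self.trees)),
            str(self.outgroups),
            str(self.model_classes),
            str(self.branch_modes),
            str(self.nsim),
            str(self.seed),
            self.root_prior,
        ]
        return hashlib.sha256("|".join(parts).encode()).hexdigest()[:12]


@dataclass
class ScenarioResult:
    """Everything computed for one topology x branch-length cell."""

    scenario: str
    branch_mode: str
    tree: Tree
    fits: dict[str, mk_model.LikelihoodFit]
    lrt: list[mk_model.LRTResult]
    selected: str
    asr: mk_model.MarginalASR
    simmap_summary: simmap.SimmapSummary
    parsimony: parsimony.ParsimonyResult

    @property
    def key(self) -> str:
        return f"{self.scenario}_{self.branch_mode}"


@dataclass
class AnalysisReport:
    config: AnalysisConfig
    scenarios: dict[str, ScenarioResult]
    node_comparison: pd.DataFrame


def _load_tree(value: Tree | str) -> Tree:
    return value if isinstance(value, Tree) else treeio.read_newick_file(value)


def _load_coding(value: StateCoding | str) -> StateCoding:
    return value if isinstance(value, StateCoding) else read_state_table(value)


def _log(quiet: bool, stage: str, **info) -> None:
    if not quiet:
        kv = " ".join(f"{k}={v}" for k, v in info.items())
        print(f"[traitpath] {stage} {kv}", file=sys.stderr)


def _clade_keys(asr: mk_model.MarginalASR) -> list[str]:
    return ["|".join(sig) for sig in mk_model._clade_signatures(asr.data)]


def run_full_analysis(config: AnalysisConfig, quiet: bool = True) -> AnalysisReport:
    """Run every scenario cell; deterministic given ``config.seed``.

    Per cell: drop outgroups, reconcile the coding with the tree (unmatched
    tips become UNKNOWN), fit the requested model classes on the supplied
    branch lengths and select by forward LRT, compute marginal posteriors,
    sample ``nsim`` stochastic maps on a mean-path-length ultrametricized
    copy of the tree, and run MPR-averaged parsimony (lengths ignored).
    """
    coding = _load_coding(config.coding)
    seeds = np.random.SeedSequence(config.seed).spawn(
        len(config.trees) * len(config.branch_modes)
    )
    scenarios: dict[str, ScenarioResult] = {}
    cell = 0
    for scen_name in config.trees:
        tree = _load_tree(config.trees[scen_name])
        if config.outgroups:
            tree = treeio.drop_tips(tree, config.outgroups)
        report = align_with_tree(coding, tree)
        scen_coding = report.coding
        for mode in config.branch_modes:
            cell_seed = int(seeds[cell].generate_state(1)[0] % (2**31))
            cell += 1
            work = (
                treeio.set_equal_branch_lengths(tree)
                if mode == "equal"
                else tree
            )
            _log(quiet, "fit", scenario=scen_name, mode=mode, tips=work.n_tips)
            fits, lrts, selected = mk_model.compare_models(
                work,
                scen_coding,
                config.model_classes,
                prior=config.root_prior,
                n_restarts=config.n_restarts,
                seed=cell_seed,
            )
            asr = mk_model.marginal_asr(
                work, scen_coding, fits[selected].model, config.root_prior
            )
            _log(quiet, "simmap", scenario=scen_name, mode=mode, nsim=config.nsim)
            ultra = treeio.make_ultrametric(work)
            maps = simmap.sample_histories(
                ultra,
                scen_coding,
                fits[selected].model,
                prior=config.root_prior,
                n=config.nsim,
                seed=cell_seed,
            )
            summary = simmap.summarize(maps)
            pars = parsimony.mpr_average_transitions(work, scen_coding)
            res = ScenarioResult(
                scenario=scen_name,
                branch_mode=mode,
                tree=work,
                fits=fits,
                lrt=lrts,
                selected=selected,
                asr=asr,
                simmap_summary=summary,
                parsimony=pars,
            )
            scenarios[res.key] = res

    node_comparison = _node_comparison(scenarios)
    report = AnalysisReport(
        config=config, scenarios=scenarios, node_comparison=node_comparison
    )
    if config.output_dir:
        _write_outputs(report)
    return report


def _node_comparison(scenarios: dict[str, ScenarioResult]) -> pd.DataFrame:
    """Stochastic-mapping state frequencies at internal nodes shared (by
    descendant tip set) across all scenario cells."""
    per_cell: dict[str, dict[str, np.ndarray]] = {}
    symbols = None
    for key, res in scenarios.items():
        data = res.asr.data
        symbols = data.alphabet.symbols
        sigs = mk_model._clade_signatures(data)
        freq = res.simmap_summary.node_state_freq
        per_cell[key] = {
            "|".join(sigs[i]): freq[i]
            for i, node in enumerate(data.nodes)
            if not node.is_leaf
        }
    if not per_cell:
        return pd.DataFrame()
    shared = set.intersection(*(set(d) for d in per_cell.values()))
    rows = []
    for sig in sorted(shared, key=lambda s: (s.count("|"), s)):
        row: dict[str, object] = {
            "clade_size": sig.count("|") + 1,
            "clade": sig if sig.count("|") < 6 else sig.split("|")[0] + "|...",
            "clade_full": sig,
        }
        for key, d in per_cell.items():
            for s, sym in enumerate(symbols):
                row[f"{key}:p_{sym}"] = d[sig][s]
        rows.append(row)
    return pd.DataFrame(rows)


def _write_outputs(report: AnalysisReport) -> None:
    outdir = Path(report.config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_digest": report.config.digest(),
        "seed": report.config.seed,
        "nsim": report.config.nsim,
    }
    fit_report: dict[str, object] = {"meta": meta, "scenarios": {}}
    for key, res in report.scenarios.items():
        res.asr.to_frame().to_csv(outdir / f"asr_ml_{key}.tsv", sep="\t", index=False)
        res.simmap_summary.transitions_frame().to_csv(
            outdir / f"simmap_counts_{key}.tsv", sep="\t"
        )
        symbols = res.parsimony.alphabet.symbols
        with open(outdir / f"parsimony_{key}.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "min_cost": res.parsimony.min_cost,
                    "mpr_count": str(res.parsimony.mpr_count),
                    "avg_transitions": {
                        f"{a}->{b}": float(res.parsimony.avg_transitions_exact[i][j])
                        for i, a in enumerate(symbols)
                        for j, b in enumerate(symbols)
                        if i != j
                    },
                },
                fh,
                indent=2,
            )
        fit_report["scenarios"][key] = {
            "selected": res.selected,
            "lnL": {mc: f.lnL for mc, f in res.fits.items()},
            "params": {mc: list(map(float, f.model.params)) for mc, f in res.fits.items()},
            "lrt": [
                {
                    "simple": t.simple_class,
                    "complex": t.complex_class,
                    "statistic": t.statistic,
                    "delta_lnl": t.delta_lnl,
                    "df": t.df,
                    "p": t.p,
                }
                for t in res.lrt
            ],
        }
        treeio.write_newick_file(res.tree, outdir / f"tree_{key}.nwk")
    report.node_comparison.to_csv(outdir / "node_comparison.tsv", sep="\t", index=False)
    with open(outdir / "fit_report.json", "w", encoding="utf-8") as fh:
        json.dump(fit_report, fh, indent=2)


def tip_swap_sensitivity(
    config: AnalysisConfig,
    old_label: str,
    new_label: str,
    new_state: str,
    quiet: bool = True,
) -> pd.DataFrame:
    """Effect of substituting one tip (relabel + recode) on node posteriors.

    For each topology (estimated branch lengths), the best-fitting model is
    refit after the swap and marginal posteriors recomputed; rows are
    internal nodes (matched by descendant tip set, with the swapped label
    normalized) sorted by the largest absolute posterior change.  Deep
    lineages whose coding flips (the *Xenoturbella*-style swap) can move the
    reconstruction at ancient nodes far more than anywhere else.
    """
    coding = _load_coding(config.coding)
    rows = []
    for scen_name in config.trees:
        tree = _load_tree(config.trees[scen_name])
        if config.outgroups:
            tree = treeio.drop_tips(tree, config.outgroups)
        base_coding = align_with_tree(coding, tree).coding
        swapped_tree = treeio.replace_tip(tree, old_label, new_label)
        swapped_coding = align_with_tree(
            base_coding.renamed(old_label, new_label).with_state(
                new_label, new_state
            ),
            swapped_tree,
        ).coding

        name_code = int(
            hashlib.sha256(scen_name.encode()).hexdigest()[:8], 16
        )
        seed = int(
            np.random.SeedSequence([config.seed, name_code]).generate_state(1)[0]
            % 2**31
        )
        _, _, selected = mk_model.compare_models(
            tree, base_coding, config.model_classes,
            prior=config.root_prior, n_restarts=config.n_restarts, seed=seed,
        )
        fit_a = mk_model.fit(tree, base_coding, selected, config.root_prior,
                             n_restarts=config.n_restarts, seed=seed)
        fit_b = mk_model.fit(swapped_tree, swapped_coding, selected, config.root_prior,
                             n_restarts=config.n_restarts, seed=seed)
        asr_a = mk_model.marginal_asr(tree, base_coding, fit_a.model, config.root_prior)
        asr_b = mk_model.marginal_asr(
            swapped_tree, swapped_coding, fit_b.model, config.root_prior
        )
        sigs_a = mk_model._clade_signatures(asr_a.data)
        sigs_b = mk_model._clade_signatures(asr_b.data)

        def norm(sig: tuple[str, ...]) -> str:
            return "|".join(sorted(old_label if s == new_label else s for s in sig))

        by_sig_b = {
            norm(sigs_b[i]): asr_b.probs[i]
            for i, nd in enumerate(asr_b.data.nodes)
            if not nd.is_leaf
        }
        for i, nd in enumerate(asr_a.data.nodes):
            if nd.is_leaf:
                continue
            sig = "|".join(sigs_a[i])
            if sig not in by_sig_b:
                continue
            delta = by_sig_b[sig] - asr_a.probs[i]
            row = {
                "scenario": scen_name,
                "clade_size": len(sigs_a[i]),
                "clade": sig if len(sigs_a[i]) < 6 else sigs_a[i][0] + "|...",
                "max_abs_delta": float(np.abs(delta).max()),
            }
            for s, sym in enumerate(asr_a.data.alphabet):
                row[f"delta_p_{sym}"] = float(delta[s])
            rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("max_abs_delta", ascending=False).reset_index(drop=True)
    return df


def spearman_branch_compare(
    lengths_a: dict[str, float], lengths_b: dict[str, float]
) -> dict[str, float]:
    """Spearman rank correlation between two branch-length sets.

    Compares lengths on the shared labels (average-rank ties, two-sided p
    from the t approximation) — the check that single-gene branch lengths
    rank-agree with multigene estimates.
    """
    shared = sorted(set(lengths_a) & set(lengths_b))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared labels")
    a = [lengths_a[s] for s in shared]
    b = [lengths_b[s] for s in shared]
    rho, p = stats.spearmanr(a, b)
    return {"rho": float(rho), "n": len(shared), "p": float(p)}
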