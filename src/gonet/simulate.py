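"""Simulation study: Yule trees, Poisson inversion counts, and scoring.

The protocol emulates inversion-only gene-order evolution: a pure-birth
(Yule) topology is drawn for the requested number of taxa, every branch
independently receives k ~ Poisson(lambda) inversions, and gene orders
evolve from the identity permutation of ``n_genes`` genes at the root,
each inversion reversing (and sign-flipping) an interval chosen
uniformly among all m(m+1)/2 intervals. The permutations observed at
the leaves are handed to each network method, and the resulting split
system is scored against the true tree's nontrivial splits (weights
ignored) by sensitivity and PPV.

Poisson draws of zero are kept: a branch without inversions leaves no
signal even though the true (binary) topology still counts its split,
which bounds the achievable sensitivity at small lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .binary_encoding import encode, parsimony_splits
from .consensus import ConsensusConfig, consensus_network
from .distance_networks import neighbor_net, split_decomposition
from .distances import distance_matrix
from .genomes import GenomeSet, SignedPermutation, identity_permutation
from .jackknife import JackknifeConfig, jackknife_trees
from .splits import EvaluationResult, SplitSystem, evaluate

__all__ = [
    "SimulationConfig",
    "SimulationSummary",
    "yule_tree",
    "assign_branch_inversions",
    "evolve",
    "run_experiment",
    "METHODS",
]

METHODS = ("consensus", "nnet", "splitdecomp", "psplits")


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the simulation grid.

    n_taxa: leaves per tree (typical settings: 10 or 20).
    lambda_inversions: expected inversions per branch (grid 1..10).
    n_genes: root permutation length (default 100).
    n_trees: replicates per cell (default 100).
    methods: network methods to run on each replicate.
    jackknife_replicates / jackknife_fraction / consensus_threshold:
        parameters of the consensus route (defaults 100 / 0.40 / 0.10).
    """

    n_taxa: int = 10
    lambda_inversions: float = 1.0
    n_genes: int = 100
    n_trees: int = 100
    seed: int = 0
    methods: tuple[str, ...] = METHODS
    jackknife_replicates: int = 100
    jackknife_fraction: float = 0.40
    consensus_threshold: float = 0.10

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.lambda_inversions < 0:
            raise ValueError("lambda_inversions must be >= 0")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def yule_tree(n_taxa: int, rng: np.random.Generator) -> dendropy.Tree:
    """Pure-birth topology: start from two lineages, split a uniform leaf.

    Leaves are labelled T1..Tn in a deterministic traversal order; no
    branch lengths are set.
    """
    if n_taxa < 2:
        raise ValueError("a Yule tree needs at least 2 taxa")
    tree = dendropy.Tree()
    root = tree.seed_node
    leaves = [root.new_child(), root.new_child()]
    while len(leaves) < n_taxa:
        pick = int(rng.integers(len(leaves)))
        node = leaves.pop(pick)
        leaves.append(node.new_child())
        leaves.append(node.new_child())
    tns = dendropy.TaxonNamespace()
    i = 0
    for leaf in tree.leaf_node_iter():
        i += 1
        leaf.taxon = tns.new_taxon(f"T{i}")
    tree.taxon_namespace = tns
    return tree


def assign_branch_inversions(
    tree: dendropy.Tree, lam: float, rng: np.random.Generator
) -> dendropy.Tree:
    """Draw k ~ Poisson(lam) inversions independently for every branch.

    The counts are stored as integer edge lengths. The root itself
    carries the ancestral permutation, so it has no incoming branch.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        node.edge.length = int(rng.poisson(lam))
    return tree


def _random_inversion(genes: list[int], rng: np.random.Generator) -> None:
    m = len(genes)
    r = int(rng.integers(m * (m + 1) // 2))
    i = 0
    row = m
    while r >= row:
        r -= row
        row -= 1
        i += 1
    j = i + r
    genes[i : j + 1] = [-g for g in reversed(genes[i : j + 1])]


def evolve(
    root: SignedPermutation, tree: dendropy.Tree, rng: np.random.Generator
) -> GenomeSet:
    """Evolve the root permutation down the tree; return the leaf genomes.

    Each branch applies its integer number of inversions sequentially;
    internal states are discarded.
    """
    states: dict[dendropy.Node, tuple[int, ...]] = {}
    leaves: list[SignedPermutation] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = root.genes
        else:
            genes = list(states[node.parent_node])
            for _ in range(int(node.edge.length or 0)):
                _random_inversion(genes, rng)
            states[node] = tuple(genes)
        if node.is_leaf():
            leaves.append(SignedPermutation(node.taxon.label, states[node]))
    return GenomeSet(tuple(leaves))


def _run_method(
    method: str, gs: GenomeSet, cfg: SimulationConfig, seed: int
) -> SplitSystem:
    if method == "consensus":
        trees = jackknife_trees(
            gs,
            JackknifeConfig(
                removal_fraction=cfg.jackknife_fraction,
                replicates=cfg.jackknife_replicates,
                seed=seed,
            ),
        )
        return consensus_network(trees, ConsensusConfig(cfg.consensus_threshold))
    dm = distance_matrix(gs)
    if method == "nnet":
        return neighbor_net(dm)
    if method == "splitdecomp":
        return split_decomposition(dm)
    if method == "psplits":
        return parsimony_splits(encode(gs))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class SimulationSummary:
    """Per-method evaluation results for one simulation cell."""

    config: SimulationConfig
    results: dict[str, list[EvaluationResult]] = field(default_factory=dict)
    errors: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def mean_sensitivity(self, method: str) -> float:
        vals = [r.sensitivity for r in self.results[method]]
        return float(np.mean(vals)) if vals else float("nan")

    def mean_ppv(self, method: str) -> float:
        vals = [r.ppv for r in self.results[method]]
        return float(np.mean(vals)) if vals else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method in self.config.methods:
            rows.append(
                {
                    "method": method,
                    "n_taxa": self.config.n_taxa,
                    "lambda": self.config.lambda_inversions,
                    "mean_sensitivity": self.mean_sensitivity(method),
                    "mean_ppv": self.mean_ppv(method),
                    "n_reps": len(self.results[method]),
                }
            )
        return pd.DataFrame(rows)

    def replicate_frame(self) -> pd.DataFrame:
        rows = []
        for method, results in self.results.items():
            for rep, r in enumerate(results):
                rows.append(
                    {
                        "method": method,
                        "replicate": rep,
                        "tp": r.tp,
                        "fn": r.fn,
                        "fp": r.fp,
                        "sensitivity": r.sensitivity,
                        "ppv": r.ppv,
                    }
                )
        return pd.DataFrame(rows)


def run_experiment(cfg: SimulationConfig) -> SimulationSummary:
    """Run one simulation cell end to end, fully determined by cfg.seed.

    Every replicate's leaf genomes are fed to all selected methods, so
    the methods are compared on identical inputs. A method failure on a
    replicate is recorded in ``errors`` and skipped, not fatal.
    """
    summary = SimulationSummary(cfg, {m: [] for m in cfg.methods},
                                {m: [] for m in cfg.methods})
    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(cfg.n_trees)
    root = identity_permutation(cfg.n_genes)
    for rep in range(cfg.n_trees):
        rng = np.random.default_rng(children[rep])
        tree = yule_tree(cfg.n_taxa, rng)
        assign_branch_inversions(tree, cfg.lambda_inversions, rng)
        gs = evolve(root, tree, rng)
        jk_seed = int(rng.integers(2**31 - 10**6))
        for method in cfg.methods:
            try:
                network = _run_method(method, gs, cfg, jk_seed)
                summary.results[method].append(evaluate(network, tree))
            except Exception as exc:  # recorded, not fatal
                summary.errors[method].append((rep, repr(exc)))
    return summary


def run_grid(
    lambdas: Sequence[float], base: SimulationConfig
) -> pd.DataFrame:
    """Run one cell per lambda (same base config) and stack the summaries."""
    frames = []
    for lam in lambdas:
        cfg = SimulationConfig(
            n_taxa=base.n_taxa,
            lambda_inversions=lam,
            n_genes=base.n_genes,
            n_trees=base.n_trees,
            seed=base.seed + int(round(lam * 1000)),
            methods=base.methods,
            jackknife_replicates=base.jackknife_replicates,
            jackknife_fraction=base.jackknife_fraction,
            consensus_threshold=base.consensus_threshold,
        )
        frames.append(run_experiment(cfg).to_frame())
    return pd.concat(frames, ignore_index=True)
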