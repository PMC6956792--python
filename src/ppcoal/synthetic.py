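"""Synthetic posterior/trace generation and the metadata file.

Bayesian SNP species-tree inference is external to this package: its
outputs (a posterior sample of species trees and a trace log) are our
inputs. The generator here emulates those outputs so the whole
pipeline can be exercised — and its simulation-study harness run —
without any external inference program. A synthetic posterior is a
cloud of trees around a center tree: each sample optionally receives
one random NNI rearrangement (probability ``topology_jitter``) and
multiplies every branch length by independent lognormal noise with
coefficient of variation ``length_jitter_cv``; trace likelihoods are
i.i.d. normal.

What this does not emulate: MCMC autocorrelation, correlated
branch-length errors, and any systematic bias of real inference under
model misfit. Harness results built on it validate the checking
machinery, not the behaviour of any particular inference program.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .treeio import PosteriorTreeSet, SampleMap, SpeciesTree, TraceLog, parse_newick

__all__ = [
    "SyntheticPosteriorConfig",
    "generate_synthetic_posterior",
    "nni_neighbor",
    "MetadataConfig",
    "read_metadata",
    "write_metadata",
]


@dataclass
class SyntheticPosteriorConfig:
    """Parameters of the synthetic posterior cloud."""

    center_tree: SpeciesTree
    n_samples: int = 100
    topology_jitter: float = 0.0
    length_jitter_cv: float = 0.0
    likelihood_mean: float = -5000.0
    likelihood_sd: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.topology_jitter <= 1:
            raise ValueError("topology_jitter must be a probability")
        if self.length_jitter_cv < 0:
            raise ValueError("length_jitter_cv must be >= 0")
        if self.likelihood_sd < 0:
            raise ValueError("likelihood_sd must be >= 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


def nni_neighbor(tree: SpeciesTree, rng: np.random.Generator) -> SpeciesTree:
    """One random nearest-neighbour-interchange move on an internal edge.

    Picks an internal (non-root) edge uniformly, then swaps one child
    of its head node with the node's sibling. Branch lengths travel
    with their subtrees; the altered nodes keep their depths. Trees
    with fewer than 4 tips have no internal edge and are returned
    unchanged (as a copy).
    """
    out = tree.copy()
    t = out.tree
    internal_edges = [
        nd
        for nd in t.preorder_node_iter()
        if nd.parent_node is not None and not nd.is_leaf()
    ]
    if not internal_edges:
        return out
    # around the root a swap can leave the unrooted topology unchanged,
    # so prefer edges whose parent is itself below the root
    deep = [nd for nd in internal_edges if nd.parent_node.parent_node is not None]
    candidates = deep or internal_edges
    head = candidates[int(rng.integers(len(candidates)))]
    parent = head.parent_node
    sib = next(ch for ch in parent.child_nodes() if ch is not head)
    child = head.child_nodes()[int(rng.integers(2))]
    # swap `child` (under head) with `sib` (under parent); each moved
    # subtree keeps its node depths (clamped at 0 on skewed trees)
    new_child_len = head.edge.length + child.edge.length
    new_sib_len = max(0.0, sib.edge.length - head.edge.length)
    head.remove_child(child)
    parent.remove_child(sib)
    head.add_child(sib)
    sib.edge.length = new_sib_len
    parent.add_child(child)
    child.edge.length = new_child_len
    return SpeciesTree(t, unit=tree.unit)


def generate_synthetic_posterior(
    cfg: SyntheticPosteriorConfig,
) -> tuple[PosteriorTreeSet, TraceLog]:
    """Generate a synthetic posterior tree sample and matching trace log.

    Deterministic under ``cfg.seed``. The lognormal branch noise has
    mean 1 and coefficient of variation ``length_jitter_cv``, so
    expected branch lengths equal the center tree's.
    """
    rng = np.random.default_rng(cfg.seed)
    cv = cfg.length_jitter_cv
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    mu = -0.5 * sigma2  # E[lognormal] = 1
    trees: list[SpeciesTree] = []
    for _ in range(cfg.n_samples):
        t = cfg.center_tree.copy()
        if cfg.topology_jitter > 0 and rng.random() < cfg.topology_jitter:
            t = nni_neighbor(t, rng)
        if cv > 0:
            for nd in t.tree.preorder_node_iter():
                if nd.edge.length is not None:
                    nd.edge.length *= float(rng.lognormal(mu, sigma))
        trees.append(t)
    likelihoods = rng.normal(cfg.likelihood_mean, cfg.likelihood_sd, cfg.n_samples)
    table = pd.DataFrame(
        {
            "Sample": np.arange(cfg.n_samples),
            "posterior": likelihoods,  # flat-prior stand-in
            "likelihood": likelihoods,
            "prior": np.zeros(cfg.n_samples),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small synthetic sets are intentional
        ts = PosteriorTreeSet(trees, source=f"synthetic(seed={cfg.seed})")
    return ts, TraceLog(table, likelihood_column="likelihood")


# ---------------------------------------------------------------------------
# metadata file


@dataclass
class MetadataConfig:
    """Run metadata: SNP count, mutation rate, samples per species."""

    n_snps: int
    mutation_rate: float
    samples_per_species: dict[str, int]

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be > 0")


def write_metadata(meta: MetadataConfig, path: str | Path) -> None:
    lines = [
        f"n_snps\t{meta.n_snps}",
        f"mutation_rate\t{meta.mutation_rate:g}",
    ]
    for sp in sorted(meta.samples_per_species):
        lines.append(f"samples\t{sp}\t{meta.samples_per_species[sp]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path: str | Path) -> MetadataConfig:
    n_snps = None
    mutation_rate = None
    samples: dict[str, int] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        key = parts[0]
        if key == "n_snps":
            n_snps = int(parts[1])
        elif key == "mutation_rate":
            mutation_rate = float(parts[1])
        elif key == "samples":
            samples[parts[1]] = int(parts[2])
        else:
            raise ValueError(f"unknown metadata key {key!r}")
    if n_snps is None or mutation_rate is None or not samples:
        raise ValueError("metadata must define n_snps, mutation_rate and samples")
    return MetadataConfig(n_snps, mutation_rate, samples)
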