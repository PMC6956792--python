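"""Species-tree, trace-log and sample-map I/O.

Posterior species-tree sets come out of Bayesian SNP phylogenetics runs
(e.g. SNAPP) as Newick one-tree-per-line files or NEXUS trees blocks;
trace logs are BEAST-style tab-delimited tables. This module reads both,
applies burn-in, and samples trees from the posterior either uniformly
(an evenly spaced stride) or at random.

Trees are stored rooted, as written: SNAPP species trees are rooted and
the downstream coalescent simulation needs the root.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SpeciesTree",
    "PosteriorTreeSet",
    "TraceLog",
    "SampleMap",
    "parse_newick",
    "write_newick",
    "read_tree_set",
    "read_trace_log",
    "read_sample_map",
    "write_sample_map",
    "sample_posterior_trees",
]

#: Posteriors smaller than this trigger a warning: the predictive
#: distribution is then resampled from too few parameter draws.
MIN_RECOMMENDED_POSTERIOR = 100


class TreeParseError(ValueError):
    """Malformed Newick/NEXUS input."""


@dataclass
class SpeciesTree:
    """A rooted binary species tree with branch lengths.

    Wraps a :class:`dendropy.Tree`. Branch-length units (substitutions,
    generations, coalescent units) are recorded as free-form metadata and
    interpreted by :func:`ppcoal.simulate.build_demography`.
    """

    tree: dendropy.Tree
    unit: str = "unspecified"

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            raise TreeParseError("duplicate tip labels: %s" % sorted(labels))
        if any(not lab for lab in labels):
            raise TreeParseError("empty tip label")
        for nd in self.tree.preorder_node_iter():
            n_child = len(nd.child_nodes())
            if n_child not in (0, 2):
                raise TreeParseError(
                    "tree is not strictly binary: node with %d children" % n_child
                )
            if nd.edge.length is not None and nd.edge.length < 0:
                raise TreeParseError("negative branch length %r" % nd.edge.length)

    # -- basic accessors -------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def copy(self) -> "SpeciesTree":
        return SpeciesTree(self.tree.clone(depth=1), unit=self.unit)

    # -- geometry --------------------------------------------------------

    def node_depths(self) -> dict[dendropy.Node, float]:
        """Distance from the root to each node (root depth 0)."""
        depths: dict[dendropy.Node, float] = {}
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is None:
                depths[nd] = 0.0
            else:
                depths[nd] = depths[nd.parent_node] + (nd.edge.length or 0.0)
        return depths

    def node_ages(self) -> dict[dendropy.Node, float]:
        """Age of each node: its maximum distance to a descendant tip.

        For an ultrametric tree this is the usual node height; for a
        slightly non-ultrametric tree (e.g. jittered posterior samples)
        the max rule still yields ages that increase rootward, which is
        what the coalescent simulator needs.
        """
        ages: dict[dendropy.Node, float] = {}
        for nd in self.tree.postorder_node_iter():
            if nd.is_leaf():
                ages[nd] = 0.0
            else:
                ages[nd] = max(
                    ages[ch] + (ch.edge.length or 0.0) for ch in nd.child_nodes()
                )
        return ages

    def root_age(self) -> float:
        return self.node_ages()[self.tree.seed_node]

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        """True when all root-to-tip path lengths agree within ``tol``."""
        depths = self.node_depths()
        tip_depths = [depths[lf] for lf in self.tree.leaf_node_iter()]
        return max(tip_depths) - min(tip_depths) <= tol

    def mrca_age(self, label_a: str, label_b: str) -> float:
        """Age of the most recent common ancestor of two tips."""
        ages = self.node_ages()
        mrca = self.tree.mrca(taxon_labels=[label_a, label_b])
        return ages[mrca]

    # -- serialization ---------------------------------------------------

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()
        return s

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SpeciesTree({self.n_tips} tips, unit={self.unit!r})"


@dataclass
class PosteriorTreeSet:
    """An ordered sample of species trees from one posterior distribution."""

    trees: list[SpeciesTree]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("posterior tree set must contain at least one tree")
        ref = frozenset(self.trees[0].tip_labels)
        for i, t in enumerate(self.trees):
            if frozenset(t.tip_labels) != ref:
                raise ValueError(
                    f"tree {i} has tip set {sorted(t.tip_labels)} differing "
                    f"from tree 0 ({sorted(ref)})"
                )
        if len(self.trees) < MIN_RECOMMENDED_POSTERIOR:
            warnings.warn(
                f"posterior holds only {len(self.trees)} trees; at least "
                f"{MIN_RECOMMENDED_POSTERIOR} are recommended for resampling",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i: int) -> SpeciesTree:
        return self.trees[i]

    def __iter__(self):
        return iter(self.trees)

    @property
    def tip_labels(self) -> list[str]:
        return sorted(self.trees[0].tip_labels)


@dataclass
class TraceLog:
    """Numeric MCMC trace table with a designated likelihood column."""

    table: pd.DataFrame
    likelihood_column: str = "likelihood"

    def __post_init__(self) -> None:
        if self.likelihood_column not in self.table.columns:
            raise KeyError(
                f"likelihood column {self.likelihood_column!r} not found; "
                f"available columns: {list(self.table.columns)}"
            )
        if not pd.api.types.is_numeric_dtype(self.table[self.likelihood_column]):
            raise TypeError(
                f"column {self.likelihood_column!r} is not numeric"
            )

    @property
    def likelihoods(self) -> np.ndarray:
        return self.table[self.likelihood_column].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SampleMap:
    """Assignment of sampled individuals to species."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.species) < 2:
            raise ValueError("sample map must cover at least 2 species")

    @property
    def species(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def individuals_of(self, species: str) -> list[str]:
        return [ind for ind, sp in self.assignments.items() if sp == species]

    @property
    def individuals(self) -> list[str]:
        return list(self.assignments)


# ---------------------------------------------------------------------------
# parsing


def parse_newick(text: str, unit: str = "unspecified") -> SpeciesTree:
    """Parse a single rooted Newick statement into a :class:`SpeciesTree`."""
    text = text.strip()
    if not text.endswith(";"):
        raise TreeParseError(
            f"Newick statement must end in ';' (offset {len(text)})"
        )
    _check_parentheses(text)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeParseError(f"malformed Newick: {exc}") from exc
    return SpeciesTree(tree, unit=unit)


def _check_parentheses(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise TreeParseError(
                    f"unbalanced ')' at character offset {offset}"
                )
    if depth != 0:
        raise TreeParseError(
            f"{depth} unclosed '(' at end of statement (offset {len(text)})"
        )


def write_newick(tree: SpeciesTree) -> str:
    return tree.to_newick()


def read_tree_set(
    path: str | Path,
    format: str = "newick-lines",
    burnin_fraction: float = 0.0,
    unit: str = "unspecified",
) -> PosteriorTreeSet:
    """Read a posterior tree sample from a file, discarding burn-in.

    ``format`` is ``newick-lines`` (one Newick statement per line) or
    ``nexus-trees`` (a NEXUS trees block, translate table honoured).
    The first ``ceil(burnin_fraction * N)`` trees are discarded.
    """
    if not 0 <= burnin_fraction < 1:
        raise ValueError(f"burnin_fraction must be in [0, 1), got {burnin_fraction}")
    path = Path(path)
    if format == "newick-lines":
        trees = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            trees.append(parse_newick(line, unit=unit))
    elif format == "nexus-trees":
        tl = dendropy.TreeList.get(path=str(path), schema="nexus",
                                   rooting="force-rooted",
                                   preserve_underscores=True)
        trees = [SpeciesTree(t, unit=unit) for t in tl]
    else:
        raise ValueError(f"unknown tree-set format {format!r}")
    if not trees:
        raise TreeParseError(f"no trees found in {path}")
    n_drop = math.ceil(burnin_fraction * len(trees))
    kept = trees[n_drop:]
    if not kept:
        raise ValueError("burn-in removed every tree")
    ref = frozenset(kept[0].tip_labels)
    for i, t in enumerate(kept):
        if frozenset(t.tip_labels) != ref:
            raise TreeParseError(f"tree {i + n_drop} has a different tip set")
    return PosteriorTreeSet(kept, source=str(path))


def write_tree_set(ts: PosteriorTreeSet, path: str | Path) -> None:
    """Write one Newick statement per line."""
    Path(path).write_text("".join(t.to_newick() + "\n" for t in ts))


def read_trace_log(
    path: str | Path,
    likelihood_column: str = "likelihood",
    burnin_fraction: float = 0.0,
) -> TraceLog:
    """Read a BEAST-style tab-delimited trace log.

    Lines starting with ``#`` are comments. Burn-in rows are removed by
    the same ceil rule as :func:`read_tree_set`.
    """
    if not 0 <= burnin_fraction < 1:
        raise ValueError(f"burnin_fraction must be in [0, 1), got {burnin_fraction}")
    df = pd.read_csv(path, sep="\t", comment="#")
    n_drop = math.ceil(burnin_fraction * len(df))
    df = df.iloc[n_drop:].reset_index(drop=True)
    return TraceLog(df, likelihood_column=likelihood_column)


def write_trace_log(log: TraceLog, path: str | Path) -> None:
    log.table.to_csv(path, sep="\t", index=False)


def read_sample_map(path: str | Path) -> SampleMap:
    """Read a two-column (individual<TAB>species) map file."""
    assignments: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"bad sample-map line: {line!r}")
        ind, sp = parts
        if ind in assignments:
            raise ValueError(f"individual {ind!r} mapped twice")
        assignments[ind] = sp
    return SampleMap(assignments)


def write_sample_map(sm: SampleMap, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{ind}\t{sp}\n" for ind, sp in sm.assignments.items())
    )


# ---------------------------------------------------------------------------
# posterior sampling


def uniform_stride_indices(n_total: int, n: int) -> list[int]:
    """Evenly spaced indices over ``[0, n_total - 1]`` including endpoints."""
    if n == 1:
        return [0]
    return [round(i * (n_total - 1) / (n - 1)) for i in range(n)]


def sample_posterior_trees(
    ts: PosteriorTreeSet,
    n: int,
    mode: str = "uniform",
    seed: int | None = None,
) -> PosteriorTreeSet:
    """Sample ``n`` trees from a posterior, uniformly spaced or at random.

    ``uniform`` takes an evenly spaced stride over the retained sample
    (both endpoints included); ``random`` draws without replacement under
    ``seed``. Output trees follow index order.
    """
    if not 1 <= n <= len(ts):
        raise ValueError(f"cannot sample {n} trees from a posterior of {len(ts)}")
    if mode == "uniform":
        idx = uniform_stride_indices(len(ts), n)
    elif mode == "random":
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(ts), size=n, replace=False).tolist())
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return PosteriorTreeSet([ts.trees[i] for i in idx],
                                source=f"{ts.source}[{mode} n={n}]")
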