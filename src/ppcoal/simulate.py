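"""Structured-coalescent SNP simulation under a species tree.

Implements the multispecies coalescent (MSCM): gene genealogies evolve
backward in time inside the species tree, with any pair of lineages in a
population of diploid effective size ``Ne`` coalescing at rate
``1/(2*Ne)`` per generation, and the lineages of two daughter species
merging into their ancestral population at each speciation time.

An optional secondary-contact extension (MSCM+m) adds symmetric gene
flow between one pair of extant species: forward in time, ``m`` migrants
per generation from each side, which backward in time moves each lineage
between the two populations at rate ``m/(2*Ne)`` while the contact
window is open.

Each SNP is an independent single-site genealogy carrying exactly one
mutation, placed on an edge drawn with probability proportional to edge
length (infinite-sites, one segregating site per locus). Because no edge
subtends the full sample, every emitted locus is polymorphic by
construction — mirroring the SNP ascertainment of the biallelic
datasets this package checks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .treeio import SampleMap, SpeciesTree

__all__ = [
    "MigrationEvent",
    "DemographicModel",
    "SimulationConfig",
    "SNPMatrix",
    "build_demography",
    "simulate_gene_tree",
    "drop_single_mutation",
    "simulate_snp_matrix",
    "draw_mscm_m_scenario",
    "GeneTreeNode",
    "total_branch_length",
]


@dataclass(frozen=True)
class MigrationEvent:
    """Symmetric secondary-contact gene flow between two extant species.

    ``rate_m`` is the forward-time number of migrants exchanged per
    generation (each direction); ``start_time`` is how far back the
    contact window reaches: looking backward, migration is active on
    ``[0, start_time]`` generations.
    """

    species_a: str
    species_b: str
    rate_m: float
    start_time: float

    def __post_init__(self) -> None:
        if self.species_a == self.species_b:
            raise ValueError("migration requires two distinct species")
        if self.rate_m <= 0:
            raise ValueError(f"rate_m must be > 0, got {self.rate_m}")
        if self.start_time <= 0:
            raise ValueError(f"start_time must be > 0, got {self.start_time}")


@dataclass
class DemographicModel:
    """Species tree plus population sizes and optional migration.

    Branch lengths of ``tree`` are in generations. ``ne`` is the diploid
    effective size applied to every branch; ``ne_overrides`` may remap
    individual populations, keyed by the frozenset of tip labels that
    subtend the branch (a single label for a terminal branch).
    An empty ``migrations`` list is the pure MSCM.
    """

    tree: SpeciesTree
    ne: float
    migrations: list[MigrationEvent] = field(default_factory=list)
    ne_overrides: Mapping[frozenset, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError(f"ne must be > 0, got {self.ne}")
        for v in self.ne_overrides.values():
            if v <= 0:
                raise ValueError("every ne override must be > 0")


@dataclass
class SimulationConfig:
    """What to simulate: locus count, sampling design, metadata.

    ``mutation_rate`` is metadata passed through to writers: the SNP
    generator conditions on exactly one mutation per retained locus, so
    mu does not alter the genotypes, matching how SNP-only datasets are
    specified by a count of segregating sites rather than by mu.
    """

    n_snps: int
    samples_per_species: Mapping[str, int]
    mutation_rate: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for sp, k in self.samples_per_species.items():
            if k < 1:
                raise ValueError(f"species {sp!r} must have >= 1 sample")


class SNPMatrix:
    """Individuals x loci biallelic (0/1 haploid) genotype matrix."""

    def __init__(
        self,
        genotypes: np.ndarray,
        individuals: Sequence[str],
        sample_map: SampleMap,
    ) -> None:
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if genotypes.shape[0] != len(individuals):
            raise ValueError("one row per individual required")
        if not np.isin(genotypes, (0, 1)).all():
            raise ValueError("haploid genotypes must be 0/1")
        missing = [i for i in individuals if i not in sample_map.assignments]
        if missing:
            raise ValueError(f"individuals missing from sample map: {missing}")
        self.genotypes = genotypes
        self.individuals = list(individuals)
        self.sample_map = sample_map

    @property
    def locus_count(self) -> int:
        return self.genotypes.shape[1]

    @property
    def species(self) -> list[str]:
        return self.sample_map.species

    def species_rows(self, species: str) -> np.ndarray:
        idx = [
            i
            for i, ind in enumerate(self.individuals)
            if self.sample_map.assignments[ind] == species
        ]
        return np.array(idx, dtype=int)

    def polymorphic_mask(self) -> np.ndarray:
        s = self.genotypes.sum(axis=0)
        return (s > 0) & (s < self.genotypes.shape[0])

    def diploid_view(self) -> np.ndarray:
        """Pair consecutive haploid rows within species into 0/1/2 genotypes."""
        rows = []
        for sp in self.species:
            idx = self.species_rows(sp)
            if len(idx) % 2:
                raise ValueError(
                    f"species {sp!r} has an odd haploid count; cannot pair"
                )
            for a, b in zip(idx[0::2], idx[1::2]):
                rows.append(self.genotypes[a] + self.genotypes[b])
        return np.array(rows, dtype=np.int8)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SNPMatrix({len(self.individuals)} individuals x "
            f"{self.locus_count} loci, {len(self.species)} species)"
        )


# ---------------------------------------------------------------------------
# demography construction


def build_demography(
    tree: SpeciesTree,
    ne: float,
    migrations: Sequence[MigrationEvent] = (),
    time_unit: str = "generations",
    ne_overrides: Mapping[frozenset, float] | None = None,
) -> DemographicModel:
    """Validate and assemble a demographic model from a species tree.

    ``time_unit='coalescent-units'`` rescales branch lengths by ``2*ne``
    generations (diploid) before storage; ``'generations'`` stores them
    as given. Migration events are checked against the tree: both
    species must be tips, and the contact window may not predate the
    pair's common ancestor.
    """
    if time_unit not in ("generations", "coalescent-units"):
        raise ValueError(f"unknown time_unit {time_unit!r}")
    work = tree.copy()
    if time_unit == "coalescent-units":
        for nd in work.tree.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length *= 2.0 * ne
    work.unit = "generations"
    tips = set(work.tip_labels)
    for mig in migrations:
        for lab in (mig.species_a, mig.species_b):
            if lab not in tips:
                raise ValueError(f"migration references unknown species {lab!r}")
        mrca = work.mrca_age(mig.species_a, mig.species_b)
        if mig.start_time > mrca:
            raise ValueError(
                f"migration between {mig.species_a!r} and {mig.species_b!r} "
                f"starts {mig.start_time} generations ago, older than their "
                f"common ancestor at {mrca}"
            )
    return DemographicModel(
        tree=work,
        ne=ne,
        migrations=list(migrations),
        ne_overrides=dict(ne_overrides or {}),
    )


class _SimPlan:
    """Flattened event schedule for the per-locus Gillespie simulation."""

    __slots__ = ("n_pops", "tip_pop", "merges", "two_ne", "migs", "rate_changes")

    def __init__(self, model: DemographicModel):
        tree = model.tree.tree
        ages = model.tree.node_ages()
        # population ids: one per tree node, leaves first in sorted label order
        labels = sorted(model.tree.tip_labels)
        self.tip_pop = {lab: i for i, lab in enumerate(labels)}
        node_pop: dict = {}
        clade: dict = {}
        for lf in tree.leaf_node_iter():
            node_pop[lf] = self.tip_pop[lf.taxon.label]
            clade[lf] = frozenset([lf.taxon.label])
        next_id = len(labels)
        internals = sorted(
            (nd for nd in tree.preorder_internal_node_iter()),
            key=lambda nd: ages[nd],
        )
        merges = []
        for nd in internals:
            node_pop[nd] = next_id
            ch = nd.child_nodes()
            clade[nd] = clade[ch[0]] | clade[ch[1]]
            next_id += 1
        self.n_pops = next_id
        for nd in internals:
            ch = nd.child_nodes()
            merges.append((ages[nd], node_pop[ch[0]], node_pop[ch[1]], node_pop[nd]))
        self.merges = sorted(merges)
        self.two_ne = [2.0 * model.ne] * self.n_pops
        for nd, pid in node_pop.items():
            override = model.ne_overrides.get(clade[nd])
            if override is not None:
                self.two_ne[pid] = 2.0 * override
        # migration entries: (pop_a, pop_b, per-lineage backward rate, end time)
        parent_age = {
            lab: ages[lf.parent_node] if lf.parent_node is not None else 0.0
            for lab, lf in ((l.taxon.label, l) for l in tree.leaf_node_iter())
        }
        self.migs = []
        for mig in model.migrations:
            pa = self.tip_pop[mig.species_a]
            pb = self.tip_pop[mig.species_b]
            # contact closes when it is scheduled to, or when either
            # species merges into its ancestor, whichever is earlier
            end = min(
                mig.start_time,
                parent_age[mig.species_a],
                parent_age[mig.species_b],
            )
            rate = mig.rate_m / (2.0 * model.ne)
            self.migs.append((pa, pb, rate, end))
        changes = {m[0] for m in self.merges} | {m[3] for m in self.migs}
        self.rate_changes = sorted(changes)


class GeneTreeNode:
    """Node of a simulated gene genealogy (times in generations)."""

    __slots__ = ("time", "children", "tip")

    def __init__(self, time: float, tip: int = -1, children: tuple = ()):
        self.time = time
        self.tip = tip
        self.children = children

    def tips_below(self) -> list[int]:
        out: list[int] = []
        stack = [self]
        while stack:
            nd = stack.pop()
            if nd.tip >= 0:
                out.append(nd.tip)
            else:
                stack.extend(nd.children)
        return out


def total_branch_length(root: GeneTreeNode) -> float:
    total = 0.0
    stack = [root]
    while stack:
        nd = stack.pop()
        for ch in nd.children:
            total += nd.time - ch.time
            stack.append(ch)
    return total


def simulate_gene_tree(
    model: DemographicModel,
    samples_per_species: Mapping[str, int],
    rng: np.random.Generator,
) -> GeneTreeNode:
    """Simulate one gene genealogy under the (possibly migrating) MSCM.

    Haploid sample lineages start at time 0 in their species' tip
    population; tip indices number the samples species-by-species in
    sorted species order. Returns the root node (its ``time`` is the
    TMRCA in generations).

    Competing exponentials: within each population holding ``k``
    lineages, coalescence fires at total rate ``k*(k-1)/2 / (2*Ne)``;
    while a contact window is open each lineage in either partner
    population migrates at rate ``m/(2*Ne)``. Rates are piecewise
    constant between speciation times and window closings, so the walk
    stops and re-draws at each such boundary.
    """
    plan = _SimPlan(model)
    for sp in samples_per_species:
        if sp not in plan.tip_pop:
            raise ValueError(f"species {sp!r} is not a tip of the species tree")

    pops: list[list[GeneTreeNode]] = [[] for _ in range(plan.n_pops)]
    tip_index = 0
    for sp in sorted(samples_per_species):
        for _ in range(samples_per_species[sp]):
            pops[plan.tip_pop[sp]].append(GeneTreeNode(0.0, tip=tip_index))
            tip_index += 1
    n_live = tip_index
    if n_live < 2:
        raise ValueError("need at least 2 sampled lineages")

    merges = list(plan.merges)
    migs = list(plan.migs)
    t = 0.0
    exponential = rng.exponential
    random = rng.random
    while n_live > 1:
        # piecewise-constant rates: coalescence per pop, migration per window
        coal_rates = []
        total = 0.0
        for pid, lineages in enumerate(pops):
            k = len(lineages)
            if k >= 2:
                r = k * (k - 1) / 2.0 / plan.two_ne[pid]
                coal_rates.append((pid, r))
                total += r
        mig_rates = []
        for pa, pb, rate, end in migs:
            if t < end:
                ra = len(pops[pa]) * rate
                rb = len(pops[pb]) * rate
                if ra > 0:
                    mig_rates.append((pa, pb, ra))
                    total += ra
                if rb > 0:
                    mig_rates.append((pb, pa, rb))
                    total += rb
        next_change = merges[0][0] if merges else np.inf
        for end in (m[3] for m in migs):
            if t < end < next_change:
                next_change = end
        if total > 0.0:
            t_event = t + exponential(1.0 / total)
        else:
            t_event = np.inf
        if t_event >= next_change:
            t = next_change
            while merges and merges[0][0] <= t:
                _, c1, c2, parent = merges.pop(0)
                pops[parent].extend(pops[c1])
                pops[parent].extend(pops[c2])
                pops[c1] = []
                pops[c2] = []
            migs = [m for m in migs if m[3] > t]
            continue
        t = t_event
        u = random() * total
        for pid, r in coal_rates:
            if u < r:
                lineages = pops[pid]
                i = int(random() * len(lineages))
                j = int(random() * (len(lineages) - 1))
                if j >= i:
                    j += 1
                a = lineages[i]
                b = lineages[j]
                for idx in sorted((i, j), reverse=True):
                    lineages.pop(idx)
                lineages.append(GeneTreeNode(t, children=(a, b)))
                n_live -= 1
                break
            u -= r
        else:
            for src, dst, r in mig_rates:
                if u < r:
                    lineages = pops[src]
                    i = int(random() * len(lineages))
                    pops[dst].append(lineages.pop(i))
                    break
                u -= r
    for lineages in pops:
        if lineages:
            return lineages[0]
    raise AssertionError("unreachable: no root lineage")  # pragma: no cover


def drop_single_mutation(
    root: GeneTreeNode, n_tips: int, rng: np.random.Generator
) -> np.ndarray:
    """Place one mutation on the genealogy and return the 0/1 tip column.

    The mutated edge is drawn with probability proportional to its
    length among all edges below the root. The root itself carries no
    edge and a binary root's children each subtend proper tip subsets,
    so the resulting site is always polymorphic.
    """
    edges: list[tuple[float, GeneTreeNode]] = []
    stack = [root]
    total = 0.0
    while stack:
        nd = stack.pop()
        for ch in nd.children:
            length = nd.time - ch.time
            total += length
            edges.append((length, ch))
            stack.append(ch)
    if total <= 0.0:
        raise ValueError("genealogy has zero total branch length")
    target = rng.random() * total
    chosen = edges[-1][1]
    for length, nd in edges:
        if target < length:
            chosen = nd
            break
        target -= length
    column = np.zeros(n_tips, dtype=np.int8)
    column[chosen.tips_below()] = 1
    return column


def _locus_rng(seed: int, locus: int) -> np.random.Generator:
    # counter-derived streams: adding loci never reshuffles earlier ones
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(locus,))
    )


def simulate_snp_matrix(
    model: DemographicModel, config: SimulationConfig
) -> SNPMatrix:
    """Simulate ``config.n_snps`` independent polymorphic SNP loci.

    Each locus gets its own genealogy and exactly one mutation; loci use
    counter-derived random streams from ``config.seed``, so the same
    seed reproduces the matrix exactly and extending ``n_snps`` appends
    loci without altering earlier ones.
    """
    species = sorted(config.samples_per_species)
    individuals: list[str] = []
    assignments: dict[str, str] = {}
    for sp in species:
        for k in range(config.samples_per_species[sp]):
            name = f"{sp}_{k}"
            individuals.append(name)
            assignments[name] = sp
    n_tips = len(individuals)
    columns = np.empty((n_tips, config.n_snps), dtype=np.int8)
    for locus in range(config.n_snps):
        rng = _locus_rng(config.seed, locus)
        root = simulate_gene_tree(model, config.samples_per_species, rng)
        columns[:, locus] = drop_single_mutation(root, n_tips, rng)
    return SNPMatrix(columns, individuals, SampleMap(assignments))


def draw_mscm_m_scenario(
    tree: SpeciesTree,
    ne: float,
    rng: np.random.Generator,
    rate_range: tuple[float, float] = (0.5, 5.0),
    contact_fraction: float = 1.25,
) -> DemographicModel:
    """Draw a random secondary-contact violation scenario (MSCM+m).

    One unordered pair of extant species is chosen uniformly, the
    migration rate uniformly over ``rate_range`` (migrants/generation),
    and the contact window opens ``contact_fraction * 2 * ne``
    generations ago — the default 1.25 gives a window of 2.5*Ne
    generations, half the shallowest split of the 6-species reference
    design.
    """
    labels = sorted(tree.tip_labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 species to draw a migrating pair")
    pairs = list(itertools.combinations(labels, 2))
    a, b = pairs[int(rng.integers(len(pairs)))]
    lo, hi = rate_range
    rate = float(rng.uniform(lo, hi))
    start = contact_fraction * 2.0 * ne
    model = build_demography(
        tree, ne, migrations=[MigrationEvent(a, b, rate, start)]
    )
    model.provenance = f"mscm+m pair=({a},{b}) m={rate:.4f} start={start:g}"
    return model
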