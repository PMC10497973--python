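"""Censored multispecies-coalescent gene-tree simulation within a species tree.

Gene lineages are traced tip-to-root through the species tree; within a
species-tree edge carrying k lineages, coalescence waiting times are drawn
Exponential(rate = k(k-1)/2) in coalescent units, coalescences exceeding
the edge duration are deferred to the parent edge, and the lineages
surviving to the species-tree root coalesce with unbounded time.

Ploidy rescaling: organellar genomes are effectively haploid and
uniparentally inherited, so species-tree branch lengths expressed in
nuclear diploid coalescent units are multiplied by 4 before simulation
(2 under the biparental-inheritance sensitivity setting).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .trees import Node, RootedTree, TreeError

__all__ = ["SimulationConfig", "simulate_gene_tree", "simulate_null_trees"]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Settings for a batch of gene-tree simulations.

    Identical (config, species tree) pairs produce bit-identical
    simulated tree sequences; replicates use deterministically derived
    RNG substreams so each is reproducible independently of order.
    """

    n_sims: int = 1000
    ploidy_factor: float = 4.0
    seed: int = 0
    samples_per_species: int = 1

    def __post_init__(self):
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not self.ploidy_factor > 0:
            raise ValueError("ploidy_factor must be > 0")
        if self.samples_per_species < 1:
            raise ValueError("samples_per_species must be >= 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


class _Lineage:
    """An active gene lineage: a finished subtree plus the pending edge
    length accumulated since its most recent node."""

    __slots__ = ("node", "age", "min_label")

    def __init__(self, node: Node, min_label: str):
        self.node = node
        self.age = 0.0
        self.min_label = min_label


def _replicate_rng(config: SimulationConfig, replicate_index: int) -> np.random.Generator:
    seed = config.seed & 0xFFFFFFFFFFFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, replicate_index & 0xFFFFFFFFFFFFFFFF]))


def _pick_pair(rng: np.random.Generator, k: int) -> tuple[int, int]:
    # uniform over unordered pairs; decode a flat index into (i, j), i < j
    m = int(rng.integers(k * (k - 1) // 2))
    i = 0
    step = k - 1
    while m >= step:
        m -= step
        i += 1
        step -= 1
    return i, i + 1 + m


def _coalesce_in_edge(
    lineages: list[_Lineage], duration: float | None, rng: np.random.Generator
) -> list[_Lineage]:
    """Run the censored coalescent for one species-tree edge.

    ``duration=None`` means the unbounded interval above the root.
    Lineages are kept sorted by smallest descendant label so the pair
    enumeration is deterministic; the draw itself is uniform random.
    """
    lineages = sorted(lineages, key=lambda l: l.min_label)
    elapsed = 0.0
    while len(lineages) >= 2:
        k = len(lineages)
        rate = k * (k - 1) / 2.0
        wait = rng.exponential(1.0 / rate)
        if duration is not None and elapsed + wait >= duration:
            break
        elapsed += wait
        for lin in lineages:
            lin.age += wait
        i, j = _pick_pair(rng, k)
        a, b = lineages[i], lineages[j]
        parent = Node()
        a.node.length = a.age
        b.node.length = b.age
        parent.add_child(a.node)
        parent.add_child(b.node)
        merged = _Lineage(parent, min(a.min_label, b.min_label))
        del lineages[j]
        lineages[i] = merged
        # resort is unnecessary: min labels only shrink at position i,
        # but keep canonical order for deterministic pair decoding
        lineages.sort(key=lambda l: l.min_label)
    if duration is not None:
        remaining = duration - elapsed
        for lin in lineages:
            lin.age += remaining
    return lineages


def simulate_gene_tree(
    species_tree: RootedTree, config: SimulationConfig, replicate_index: int = 0
) -> RootedTree:
    """Simulate one gene tree contained within ``species_tree``.

    The species tree must be strictly bifurcating with every edge length
    present (coalescent units, already ploidy-rescaled by the caller —
    :func:`simulate_null_trees` applies the factor for you).  Leaf labels
    are the species labels, suffixed ``_i`` when ``samples_per_species``
    > 1.  The result is ultrametric whenever the species tree is, and
    every gene-tree coalescence is at least as old as the species-tree
    divergence of the species it spans.
    """
    if not species_tree.is_bifurcating():
        raise TreeError("species tree must be strictly bifurcating for simulation")
    if not species_tree.has_all_lengths():
        raise TreeError("species tree has missing edge lengths")
    rng = _replicate_rng(config, replicate_index)
    m = config.samples_per_species

    pool: dict[int, list[_Lineage]] = {}
    for snode in species_tree.postorder():
        if snode.is_leaf:
            if m == 1:
                lineages = [_Lineage(Node(snode.label), snode.label)]
            else:
                lineages = [
                    _Lineage(Node(f"{snode.label}_{i + 1}"), f"{snode.label}_{i + 1}")
                    for i in range(m)
                ]
        else:
            lineages = []
            for child in snode.children:
                lineages.extend(pool.pop(id(child)))
        duration = None if snode.parent is None else snode.length
        pool[id(snode)] = _coalesce_in_edge(lineages, duration, rng)

    (final,) = pool[id(species_tree.root)]
    final.node.length = None
    return RootedTree(final.node)


def simulate_null_trees(
    species_tree: RootedTree, config: SimulationConfig
) -> list[RootedTree]:
    """Simulate ``config.n_sims`` gene trees under the ILS null.

    The species tree is rescaled by ``config.ploidy_factor`` exactly once
    before simulation.
    """
    from .trees import scale_branch_lengths

    scaled = scale_branch_lengths(species_tree, config.ploidy_factor)
    return [
        simulate_gene_tree(scaled, config, replicate_index=r)
        for r in range(config.n_sims)
    ]
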