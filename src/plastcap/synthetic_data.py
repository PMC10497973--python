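"""Synthetic inputs for exercising the full pipeline without external data.

Provides (i) Yule (pure-birth) species trees, (ii) coalescent plastome
genealogies carrying a controlled number of capture (regraft) events,
and (iii) toy CDS sequence sets with intact / premature-stop / deleted
variants.  Capture is modeled as a topological replacement of the
recipient's plastome lineage: the recipient leaf is detached and
regrafted onto the donor's pendant edge, becoming the donor's sister.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .msc_sim import SimulationConfig, simulate_null_trees
from .trees import Node, RootedTree, TreeError, scale_branch_lengths

__all__ = [
    "CaptureEvent",
    "SyntheticCase",
    "simulate_yule_species_tree",
    "inject_capture",
    "generate_case",
    "make_cds_set",
]


@dataclasses.dataclass(frozen=True)
class CaptureEvent:
    """One plastome transfer: the recipient's lineage is regrafted onto
    the donor's pendant edge at ``attach_fraction`` of its length above
    the donor tip."""

    donor: str
    recipient: str
    attach_fraction: float = 0.5

    def __post_init__(self):
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")
        if not 0.0 < self.attach_fraction < 1.0:
            raise ValueError("attach_fraction must be in (0, 1)")


@dataclasses.dataclass(frozen=True)
class SyntheticCase:
    species_tree: RootedTree
    plastome_tree: RootedTree
    events: tuple[CaptureEvent, ...]
    seed: int

    def __post_init__(self):
        if self.species_tree.label_set() != self.plastome_tree.label_set():
            raise TreeError("plastome and species trees must share a leaf set")

    def config_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "n_species": self.species_tree.n_leaves,
                "events": [dataclasses.asdict(e) for e in self.events],
            },
            indent=2,
        )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_yule_species_tree(
    n_species: int, birth_rate: float, seed=0
) -> RootedTree:
    """Ultrametric bifurcating tree from a pure-birth process.

    Waiting times between birth events are Exponential(birth_rate x
    current lineage count); after the n-th lineage appears, one more
    waiting time is appended so tips sit strictly below the last split.
    Leaves are labelled sp01..spNN.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not birth_rate > 0:
        raise ValueError("birth_rate must be > 0")
    rng = _as_rng(seed)

    root = Node()
    active = [root.add_child(Node(length=0.0)), root.add_child(Node(length=0.0))]
    while True:
        k = len(active)
        wait = rng.exponential(1.0 / (birth_rate * k))
        for tip in active:
            tip.length += wait
        if k == n_species:
            break
        parent = active.pop(int(rng.integers(k)))
        a = parent.add_child(Node(length=0.0))
        b = parent.add_child(Node(length=0.0))
        active.extend([a, b])
    width = max(2, len(str(n_species)))
    for i, tip in enumerate(active, start=1):
        tip.label = f"sp{i:0{width}d}"
    return RootedTree(root)


def _detach_leaf(tree: RootedTree, leaf: Node) -> None:
    """Remove a leaf and suppress the resulting unifurcation (the old
    parent); collapses the root if it is left with one child."""
    parent = leaf.parent
    if parent is None:
        raise TreeError("cannot detach the only node of a tree")
    parent.children.remove(leaf)
    leaf.parent = None
    if len(parent.children) == 1:
        child = parent.children[0]
        if parent.parent is None:
            child.parent = None
            child.length = None
            tree.root = child
        else:
            child.length = (child.length or 0.0) + (parent.length or 0.0)
            gp = parent.parent
            gp.children[gp.children.index(parent)] = child
            child.parent = gp


def inject_capture(
    gene_tree: RootedTree, events: list[CaptureEvent] | tuple[CaptureEvent, ...], seed=None
) -> RootedTree:
    """Apply capture events in order, each regrafting the recipient leaf
    as sister to the donor with matching heights (preserves
    ultrametricity).  Leaf count and labels are conserved.
    """
    t = gene_tree.copy()
    for ev in events:
        donor = t.find_leaf(ev.donor)
        recipient = t.find_leaf(ev.recipient)
        _detach_leaf(t, recipient)
        if donor.parent is None:
            raise TreeError(
                f"donor {ev.donor!r} became the whole tree; cannot regraft"
            )
        if not donor.length or donor.length <= 0:
            raise TreeError(f"donor {ev.donor!r} has zero/missing pendant length")
        attach_height = ev.attach_fraction * donor.length
        joint = Node(length=donor.length - attach_height)
        parent = donor.parent
        parent.children[parent.children.index(donor)] = joint
        joint.parent = parent
        joint.add_child(donor)
        donor.length = attach_height
        joint.add_child(recipient)
        recipient.length = attach_height
        recipient.children = []
    t.validate()
    return t


def generate_case(
    n_species: int,
    birth_rate: float = 1.0,
    depth_scale: float = 2.0,
    k_events: int = 0,
    ploidy_factor: float = 4.0,
    seed: int = 0,
    attach_fraction: float = 0.5,
) -> SyntheticCase:
    """Species tree via Yule (rescaled to root depth ``depth_scale``),
    plastome tree via the contained coalescent on the ploidy-rescaled
    species tree, then ``k_events`` captures with uniformly drawn
    donor/recipient pairs (recipients distinct, donor != recipient).
    Deterministic for fixed arguments.
    """
    if k_events < 0:
        raise ValueError("k_events must be >= 0")
    if k_events >= n_species:
        raise ValueError("k_events must be < n_species (recipients are distinct)")
    ss = np.random.SeedSequence(seed & 0xFFFFFFFFFFFFFFFF)
    ss_yule, ss_msc, ss_events = ss.spawn(3)

    species = simulate_yule_species_tree(
        n_species, birth_rate, seed=np.random.default_rng(ss_yule)
    )
    species = scale_branch_lengths(species, depth_scale / species.depth())

    msc_seed = int(ss_msc.generate_state(1, dtype=np.uint64)[0])
    cfg = SimulationConfig(n_sims=1, ploidy_factor=ploidy_factor, seed=msc_seed)
    plastome = simulate_null_trees(species, cfg)[0]

    rng = np.random.default_rng(ss_events)
    labels = sorted(species.label_set())
    recipients = [str(r) for r in rng.choice(labels, size=k_events, replace=False)]
    events = []
    for recipient in recipients:
        donors = [l for l in labels if l != recipient]
        donor = donors[int(rng.integers(len(donors)))]
        events.append(CaptureEvent(donor, recipient, attach_fraction))
    plastome = inject_capture(plastome, events)
    return SyntheticCase(species, plastome, tuple(events), seed)


# ---------------------------------------------------------------------
# Toy CDS sets

_NONSTOP_CODONS = None


def _nonstop_codons() -> list[str]:
    global _NONSTOP_CODONS
    if _NONSTOP_CODONS is None:
        stops = {"TAA", "TAG", "TGA"}
        _NONSTOP_CODONS = sorted(
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in stops
        )
    return _NONSTOP_CODONS


def make_cds_set(
    n_codons: int,
    samples: dict[str, tuple[str, int | float | None]],
    seed=0,
) -> tuple[str, dict[str, str]]:
    """Build a reference CDS plus per-sample variants with planted status.

    ``samples`` maps sample name to (status, detail): ("intact", None),
    ("premature_stop", codon_index 1-based, strictly inside the CDS), or
    ("large_deletion", fraction of the reference retained).  Returns
    (reference, {sample: sequence}).  The reference is n_codons of
    stop-free codons followed by a TAA terminator.
    """
    if n_codons < 2:
        raise ValueError("n_codons must be >= 2")
    rng = _as_rng(seed)
    codons = _nonstop_codons()
    body = [codons[int(rng.integers(len(codons)))] for _ in range(n_codons)]
    reference = "".join(body) + "TAA"
    n_total = n_codons + 1  # incl. terminator

    out = {}
    for name, (status, detail) in samples.items():
        if status == "intact":
            out[name] = reference
        elif status == "premature_stop":
            pos = int(detail)
            if not 1 <= pos < n_total:
                raise ValueError(f"stop codon index {pos} outside CDS body")
            seq = list(body + ["TAA"])
            seq[pos - 1] = "TAA"
            out[name] = "".join(seq)
        elif status == "large_deletion":
            frac = float(detail)
            keep = int(frac * len(reference))
            keep -= keep % 3  # keep in frame
            out[name] = reference[: max(keep, 3)]
        else:
            raise ValueError(f"unknown status {status!r}")
    return reference, out
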