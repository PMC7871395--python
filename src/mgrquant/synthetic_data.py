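"""Synthetic gene-order datasets with known rearrangement histories.

Rearrangement events are placed on a phylogeny: per branch the event count
is Poisson(rate x branch length), events are applied sequentially from root
to tip, and descendants inherit ancestral arrangements — so rearranged
genomes are phylogenetically clustered by construction. Five event types
are modelled: tandem duplication (a block duplicated in place), TDRL
(tandem duplication followed by random loss of one copy of each duplicated
gene), transposition (a block excised and reinserted elsewhere), inversion
(a block reversed in place), and single-gene loss.

Event placement follows *hotspot weights*, a probability mass over the
genes of the reference arrangement; the default concentrates mass on the
two empirical rearrangement hotspots of the vertebrate mitogenome — the
nad5–CR segment (Region 1) and the IQM–WANCY segment (Region 2). Every
simulation returns a ground-truth event log whose replay reproduces the tip
orders exactly, enabling parameter-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .gene_order_io import GeneOrder, ReferenceArrangement, TYPICAL_VERTEBRATE

log = logging.getLogger("mgrquant")

EVENT_TYPES = ("tandem_duplication", "tdrl", "transposition", "inversion", "loss")

#: Default per-branch-length-unit rates. TDRL is the dominant, widely
#: accepted mechanism for mitogenome rearrangement and gets the largest
#: share; loss and inversion are comparatively uncommon in vertebrate
#: mitogenomes. The absolute scale is a placeholder (real rates unknown).
DEFAULT_RATES: dict[str, float] = {
    "tandem_duplication": 0.25,
    "tdrl": 0.35,
    "transposition": 0.20,
    "inversion": 0.10,
    "loss": 0.10,
}

#: Region 1 interior (between anchors nad4 and rrnS): nad5-nad6-cob + CR.
REGION1_SPAN: tuple[str, ...] = (
    "H", "S2", "L2", "nad5", "nad6", "E", "cob", "T", "P", "CR", "F",
)
#: Region 2 interior (between anchors nad1 and cox1): IQM-nad2-WANCY.
REGION2_SPAN: tuple[str, ...] = (
    "I", "Q", "M", "nad2", "W", "A", "N", "C", "Y",
)
#: Closed spans (anchors included): events confined to a region interior can
#: perturb at most the flanks of the two anchor genes beyond it.
REGION1_CLOSED: tuple[str, ...] = ("nad4", *REGION1_SPAN, "rrnS")
REGION2_CLOSED: tuple[str, ...] = ("nad1", *REGION2_SPAN, "cox1")


def default_hotspot_weights(
    reference: ReferenceArrangement = TYPICAL_VERTEBRATE,
    region1_mass: float = 0.45,
    region2_mass: float = 0.45,
) -> dict[str, float]:
    """Hotspot mass over reference genes: ``region1_mass`` spread over the
    nad5–CR segment, ``region2_mass`` over IQM–WANCY, the remainder uniform
    over all other genes."""
    labels = reference.labels()
    r1 = [g for g in REGION1_SPAN if g in labels]
    r2 = [g for g in REGION2_SPAN if g in labels and g not in r1]
    rest = [g for g in labels if g not in r1 and g not in r2]
    weights = {g: region1_mass / len(r1) for g in r1}
    weights.update({g: region2_mass / len(r2) for g in r2})
    leftover = 1.0 - region1_mass - region2_mass
    if rest and leftover > 0:
        weights.update({g: leftover / len(rest) for g in rest})
    else:
        weights.update({g: 0.0 for g in rest})
    total = sum(weights.values())
    return {g: w / total for g, w in weights.items()}


@dataclass(frozen=True)
class EventModel:
    """Rates (events per branch-length unit) per event type, plus hotspot
    placement weights over reference genes, and the RNG seed."""

    rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    hotspot_weights: Mapping[str, float] | None = None  # None -> default hotspots
    seed: int = 0
    span_mean: float = 2.0   # geometric mean block length (genes)
    span_max: int = 6

    def __post_init__(self) -> None:
        for etype, rate in self.rates.items():
            if etype not in EVENT_TYPES:
                raise ValueError(f"unknown event type: {etype!r}")
            if rate < 0:
                raise ValueError(f"negative rate for {etype!r}")
        if self.hotspot_weights is not None:
            total = sum(self.hotspot_weights.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"hotspot weights sum to {total}, not 1")

    @property
    def total_rate(self) -> float:
        return sum(self.rates.values())

    def scaled(self, factor: float) -> "EventModel":
        """Same model with all event rates multiplied by ``factor``."""
        return replace(self, rates={e: r * factor for e, r in self.rates.items()})


@dataclass(frozen=True)
class EventRecord:
    branch_id: str
    event_type: str
    span: tuple[str, ...]        # labels of the affected block
    detail: tuple                 # replay parameters (see _apply_tokens)
    resulting_order: tuple[str, ...]


@dataclass
class EventLog:
    """Ground-truth history: replaying it from the root order reproduces
    every tip order exactly."""

    root_tokens: tuple[str, ...]
    records: list[EventRecord]
    branch_events: dict[str, list[int]]  # branch id -> indices into records

    def events_on(self, branch_id: str) -> list[EventRecord]:
        return [self.records[i] for i in self.branch_events.get(branch_id, [])]


class EventRejected(ValueError):
    """An event would produce an invalid order (e.g. loss below length 2)."""


# ---------------------------------------------------------------------------
# Event operators (token-level)
# ---------------------------------------------------------------------------

def _apply_tokens(
    tokens: tuple[str, ...],
    event_type: str,
    start: int,
    length: int,
    rng: np.random.Generator | None,
    insert_at: int | None = None,
    keep_first: tuple[bool, ...] | None = None,
) -> tuple[tuple[str, ...], tuple]:
    """Apply one event to a circular token sequence.

    The sequence is rotated so the span starts at index 0 (rotation is
    immaterial for a circular order). Returns the new tokens plus the replay
    detail actually used: ``(start, length, insert_at, keep_first)``.
    """
    n = len(tokens)
    if not 0 <= start < n:
        raise ValueError(f"span start {start} out of range")
    length = min(length, n - 1) if event_type != "loss" else length
    rot = tokens[start:] + tokens[:start]  # block is rot[0:length]
    block = rot[:length]
    rest = rot[length:]
    if event_type == "tandem_duplication":
        out = block + block + rest
    elif event_type == "tdrl":
        # tandem copy, then delete one of the two copies of each block gene
        if keep_first is None:
            if rng is None:
                raise ValueError("tdrl needs an rng or explicit keep_first")
            keep_first = tuple(bool(b) for b in rng.integers(0, 2, size=length))
        first = tuple(g for g, k in zip(block, keep_first) if k)
        second = tuple(g for g, k in zip(block, keep_first) if not k)
        out = first + second + rest
    elif event_type == "transposition":
        if insert_at is None:
            if rng is None:
                raise ValueError("transposition needs an rng or explicit insert_at")
            insert_at = int(rng.integers(1, len(rest) + 1))
        if not 0 <= insert_at <= len(rest):  # 0 and len(rest) are identity moves
            raise ValueError(f"insert position {insert_at} out of range")
        out = rest[:insert_at] + block + rest[insert_at:]
    elif event_type == "inversion":
        out = tuple(reversed(block)) + rest
    elif event_type == "loss":
        if length != 1:
            raise EventRejected("loss events remove single genes only")
        if n - 1 < 2:
            raise EventRejected("loss would shrink the order below 2 genes")
        out = rest
    else:
        raise ValueError(f"unknown event type: {event_type!r}")
    return out, (start, length, insert_at, keep_first)


def apply_event(
    order: GeneOrder,
    event_type: str,
    span: tuple[int, int],
    rng: np.random.Generator | None = None,
) -> GeneOrder:
    """Apply one rearrangement event to a gene order.

    ``span`` is ``(start_position, length)`` in the circular order. The rng
    supplies the random choices of TDRL (which copy of each duplicated gene
    is lost) and transposition (reinsertion point). Raises
    :class:`EventRejected` for a loss that would leave fewer than 2 genes.
    """
    start, length = span
    tokens, _ = _apply_tokens(order.labels(), event_type, start, length, rng)
    return GeneOrder.from_tokens(order.species_id, tokens, taxon=order.taxon,
                                 alphabet=None)


# ---------------------------------------------------------------------------
# Tree-level simulation
# ---------------------------------------------------------------------------

def _position_weights(
    tokens: Sequence[str], weights: Mapping[str, float]
) -> np.ndarray:
    w = np.array([weights.get(t, 0.0) for t in tokens], dtype=float)
    if w.sum() <= 0:
        w = np.ones(len(tokens))
    return w / w.sum()


def _draw_span(
    tokens: tuple[str, ...],
    weights: Mapping[str, float],
    model: EventModel,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw a span start (hotspot-weighted) and a geometric length (mean
    ``span_mean``, truncated at ``span_max``); the span is also truncated at
    the first zero-weight gene so that concentrated hotspot mass confines
    events to the hotspot."""
    pw = _position_weights(tokens, weights)
    start = int(rng.choice(len(tokens), p=pw))
    length = min(int(rng.geometric(1.0 / model.span_mean)), model.span_max, len(tokens) - 1)
    has_cold = any(weights.get(t, 0.0) == 0.0 for t in tokens)
    if has_cold:
        trunc = 0
        for i in range(length):
            if weights.get(tokens[(start + i) % len(tokens)], 0.0) == 0.0:
                break
            trunc += 1
        length = max(1, trunc)
    return start, length


def simulate_tree_dataset(
    model: EventModel,
    tree: dendropy.Tree | str,
    root: ReferenceArrangement = TYPICAL_VERTEBRATE,
    taxon: Sequence[str] = ("Simulated", "Simulated"),
) -> tuple[list[GeneOrder], EventLog]:
    """Evolve the root arrangement along a tree with branch lengths.

    Per branch, the event count is Poisson(total rate x branch length);
    event types are drawn proportionally to their rates, placements from the
    hotspot weights. Tips inherit ancestral orders; identical seeds yield
    identical datasets. Returns the tip orders (species_id = tip label) and
    the ground-truth event log.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = np.random.default_rng(model.seed)
    weights = (dict(model.hotspot_weights) if model.hotspot_weights is not None
               else default_hotspot_weights(root))
    etypes = [e for e in EVENT_TYPES if model.rates.get(e, 0.0) > 0]
    eprobs = np.array([model.rates[e] for e in etypes], dtype=float)
    total = eprobs.sum()
    eprobs = eprobs / total if total > 0 else eprobs

    records: list[EventRecord] = []
    branch_events: dict[str, list[int]] = {}
    state: dict[int, tuple[str, ...]] = {id(tree.seed_node): root.labels()}
    counter = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tokens = state[id(node.parent_node)]
        blen = node.edge.length or 0.0
        branch_id = (node.taxon.label if node.taxon else node.label or f"branch{counter}")
        counter += 1
        n_events = int(rng.poisson(total * blen)) if total > 0 and blen > 0 else 0
        idxs: list[int] = []
        for _ in range(n_events):
            etype = str(rng.choice(etypes, p=eprobs)) if etypes else None
            if etype is None:
                break
            for _attempt in range(20):  # rejected events are resampled
                start, length = _draw_span(tokens, weights, model, rng)
                if etype == "loss":
                    length = 1
                if etype == "transposition":
                    # reinsert before a hotspot-weighted position of the
                    # remaining order, keeping events inside the hotspot
                    rot = tokens[start:] + tokens[:start]
                    rest = rot[length:]
                    rw = _position_weights(rest, weights)
                    insert_at = int(rng.choice(len(rest), p=rw))
                else:
                    insert_at = None
                try:
                    new_tokens, detail = _apply_tokens(
                        tokens, etype, start, length, rng, insert_at=insert_at
                    )
                except EventRejected:
                    continue
                span_labels = tuple(
                    tokens[(start + i) % len(tokens)] for i in range(length)
                )
                records.append(EventRecord(branch_id, etype, span_labels, detail, new_tokens))
                idxs.append(len(records) - 1)
                tokens = new_tokens
                break
        state[id(node)] = tokens
        if idxs:
            branch_events.setdefault(branch_id, []).extend(idxs)

    tips = [
        GeneOrder.from_tokens(
            leaf.taxon.label, state[id(leaf)], taxon=taxon, alphabet=None
        )
        for leaf in tree.leaf_node_iter()
    ]
    return tips, EventLog(root.labels(), records, branch_events)


def replay_log(log: EventLog, tree: dendropy.Tree | str) -> dict[str, tuple[str, ...]]:
    """Re-apply the logged events along the tree (no randomness) and return
    the tip token sequences — must equal the simulated tip orders."""
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    state: dict[int, tuple[str, ...]] = {id(tree.seed_node): log.root_tokens}
    counter = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tokens = state[id(node.parent_node)]
        branch_id = (node.taxon.label if node.taxon else node.label or f"branch{counter}")
        counter += 1
        for rec in log.events_on(branch_id):
            start, length, insert_at, keep_first = rec.detail
            tokens, _ = _apply_tokens(
                tokens, rec.event_type, start, length, None,
                insert_at=insert_at, keep_first=keep_first,
            )
        state[id(node)] = tokens
    return {leaf.taxon.label: state[id(leaf)] for leaf in tree.leaf_node_iter()}


def random_coalescent_tree(
    n_tips: int, seed: int, prefix: str = "sp"
) -> dendropy.Tree:
    """A random Kingman-coalescent tree (ultrametric, heights ~O(1)),
    adequate as a neutral backbone for simulation tests."""
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = np.random.default_rng(seed)
    lineages: list[tuple[str, float]] = [(f"{prefix}{i}", 0.0) for i in range(n_tips)]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += float(rng.exponential(2.0 / (k * (k - 1))))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha), (nb, hb) = lineages[i], lineages[j]
        merged = (f"({na}:{t - ha:.6f},{nb}:{t - hb:.6f})", t)
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
    newick = lineages[0][0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick")
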