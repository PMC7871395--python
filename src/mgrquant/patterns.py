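"""Arrangement patterns: canonicalization, census, and local projections.

Two genomes share an arrangement pattern when, linearized to start at the
same gene, their circular gene-label sequences are identical. Patterns
observed at least 3 times in a sample are *major* arrangements; those seen
twice (*double*) or once (*single*) are *rare*. A *global* pattern uses all
genes + CR; *local* patterns restrict the comparison, either to a label
subset (e.g. the 13 protein-coding genes) or to the span between two anchor
genes (the rearrangement-hotspot regions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .gene_order_io import GeneOrder, PCGS, ReferenceArrangement
from .qmgr_core import GenomeScore

log = logging.getLogger("mgrquant")

#: Fallback priority when the requested start gene is absent from a genome.
START_PRIORITY: tuple[str, ...] = ("F", "rrnS", "cox1", "nad5")


@dataclass(frozen=True)
class CanonicalArrangement:
    """Rotation-invariant representation of a circular label sequence."""

    tokens: tuple[str, ...]
    start_rule: str  # the gene rotated to, or "lexmin"


def _min_rotation(tokens: tuple[str, ...]) -> tuple[str, ...]:
    n = len(tokens)
    doubled = tokens + tokens
    return min(tuple(doubled[i:i + n]) for i in range(n))


def canonicalize(order: GeneOrder, start_gene: str = "F") -> CanonicalArrangement:
    """Rotate the circular label sequence to a deterministic start.

    Starts at the first occurrence of ``start_gene``; if that gene is absent
    the fixed priority list (F, rrnS, cox1, nad5) is tried; if all are
    absent, the lexicographically minimal rotation is used. When the chosen
    start gene is duplicated, the occurrence giving the lexicographically
    minimal tuple wins, so the result is deterministic for any input.
    """
    tokens = order.labels()
    n = len(tokens)
    for gene in (start_gene, *START_PRIORITY):
        positions = [i for i, t in enumerate(tokens) if t == gene]
        if not positions:
            continue
        doubled = tokens + tokens
        best = min(tuple(doubled[i:i + n]) for i in positions)
        return CanonicalArrangement(best, gene)
    return CanonicalArrangement(_min_rotation(tokens), "lexmin")


# ---------------------------------------------------------------------------
# Local projections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """A local span delimited by two anchor genes (exclusive), optionally
    restricted to a label subset after extraction."""

    name: str
    left: str
    right: str
    keep: frozenset[str] | None = None


#: nad5-nad6-cob cluster + CR hotspot (between nad4 and rrnS).
REGION1 = RegionSpec("region1", "nad4", "rrnS")
#: IQM and WANCY tRNA clusters around nad2 (between nad1 and cox1).
REGION2 = RegionSpec("region2", "nad1", "cox1")
#: Protein-coding hotspot: the nad5/nad6/cob order upstream of the CR.
REGION3 = RegionSpec("region3", "nad4", "CR", keep=frozenset({"nad5", "nad6", "cob"}))

REGIONS: dict[str, RegionSpec] = {r.name: r for r in (REGION1, REGION2, REGION3)}


class RegionAnchorError(ValueError):
    """A region anchor is missing or duplicated in a genome."""


def project(order: GeneOrder, keep: Iterable[str]) -> GeneOrder:
    """Drop occurrences whose label is outside ``keep``, preserving the
    circular relative order of the survivors (copy indices re-derived)."""
    keep = frozenset(keep)
    if not keep:
        raise ValueError("projection label set is empty")
    survivors = [occ for occ in order.occurrences if occ.label in keep]
    if len(survivors) < 2:
        raise ValueError(
            f"{order.species_id}: projection leaves {len(survivors)} occurrence(s); "
            "need >= 2 for a circular order"
        )
    return GeneOrder.from_tokens(
        order.species_id,
        [o.label for o in survivors],
        taxon=order.taxon,
        strands=[o.strand for o in survivors],
        alphabet=None,
    )


def extract_region(order: GeneOrder, region: RegionSpec) -> tuple[str, ...]:
    """The (possibly empty) circular span strictly between the region's
    anchors, in reading direction, optionally filtered to ``region.keep``.

    Raises :class:`RegionAnchorError` when an anchor is missing or
    duplicated — such genomes are excluded from region censuses.
    """
    labels = order.labels()
    for anchor in (region.left, region.right):
        c = labels.count(anchor)
        if c != 1:
            raise RegionAnchorError(
                f"{order.species_id}: anchor {anchor!r} occurs {c} times; "
                f"cannot extract {region.name}"
            )
    n = len(labels)
    i = labels.index(region.left)
    span: list[str] = []
    j = (i + 1) % n
    while labels[j] != region.right:
        span.append(labels[j])
        j = (j + 1) % n
    if region.keep is not None:
        span = [t for t in span if t in region.keep]
    return tuple(span)


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternClass:
    arrangement: CanonicalArrangement
    members: tuple[str, ...]          # species_ids, input order
    count: int
    klass: str                        # major | double | single
    pattern_rank: int | None          # 1..k among majors, by descending count

    @property
    def is_rare(self) -> bool:
        return self.klass in ("double", "single")


@dataclass
class PatternCensus:
    """Equivalence classes of identical canonicalized arrangements."""

    scope: str
    classes: list[PatternClass]
    excluded: list[str] = field(default_factory=list)  # species dropped (anchors/projection)

    @property
    def n_genomes(self) -> int:
        return sum(c.count for c in self.classes)

    def rare_species(self) -> list[str]:
        return [sp for c in self.classes if c.is_rare for sp in c.members]

    def class_of(self, species_id: str) -> PatternClass:
        for c in self.classes:
            if species_id in c.members:
                return c
        raise KeyError(species_id)


def _classify(count: int) -> str:
    return "major" if count >= 3 else "double" if count == 2 else "single"


def census(
    orders: Sequence[GeneOrder],
    scope: str = "global",
    region: RegionSpec | None = None,
    start_gene: str = "F",
) -> PatternCensus:
    """Merge and count genomes with identical canonical arrangements.

    ``scope`` is ``global`` (all genes + CR), ``pcg_only`` (project to the 13
    protein-coding genes first) or ``region`` (extract the span of
    ``region`` first; genomes with missing/duplicated anchors are excluded
    with a warning). Classes are ranked: majors (count >= 3) get ranks
    1..k in descending count, ties broken by first appearance in the input.
    """
    if not orders:
        raise ValueError("census needs at least one gene order")
    if scope == "region" and region is None:
        raise ValueError("scope='region' requires a RegionSpec")
    keyed: dict[tuple[str, ...], list[str]] = {}
    canon_of: dict[tuple[str, ...], CanonicalArrangement] = {}
    excluded: list[str] = []
    for order in orders:
        if scope == "global":
            canon = canonicalize(order, start_gene)
        elif scope == "pcg_only":
            try:
                canon = canonicalize(project(order, PCGS), start_gene)
            except ValueError as exc:
                log.warning("census(pcg_only): %s", exc)
                excluded.append(order.species_id)
                continue
        elif scope == "region":
            try:
                span = extract_region(order, region)
            except RegionAnchorError as exc:
                log.warning("census(%s): %s", region.name, exc)
                excluded.append(order.species_id)
                continue
            canon = CanonicalArrangement(span, f"anchor:{region.left}")
        else:
            raise ValueError(f"unknown census scope: {scope!r}")
        keyed.setdefault(canon.tokens, []).append(order.species_id)
        canon_of.setdefault(canon.tokens, canon)
    # descending count, ties by first-seen input order (dict preserves it)
    ordered = sorted(keyed.items(), key=lambda kv: -len(kv[1]))
    classes: list[PatternClass] = []
    rank = 0
    for tokens, members in ordered:
        klass = _classify(len(members))
        if klass == "major":
            rank += 1
        classes.append(
            PatternClass(canon_of[tokens], tuple(members), len(members), klass,
                         rank if klass == "major" else None)
        )
    return PatternCensus(scope if scope != "region" else region.name, classes, excluded)


@dataclass(frozen=True)
class RareSummary:
    mean_rs: float | None
    per_species: dict[str, int]
    min_species: str | None
    max_species: str | None


def rare_rs_summary(
    pattern_census: PatternCensus, scores: Sequence[GenomeScore]
) -> RareSummary:
    """Mean genome RS over species in rare (single/double) pattern classes,
    with the extreme species identified; empty summary when no species is
    rare."""
    by_id = {s.species_id: s.rs for s in scores}
    rare = pattern_census.rare_species()
    missing = [sp for sp in rare if sp not in by_id]
    if missing:
        raise ValueError(f"no genome score for rare species: {missing}")
    if not rare:
        return RareSummary(None, {}, None, None)
    per = {sp: by_id[sp] for sp in rare}
    return RareSummary(
        sum(per.values()) / len(per),
        per,
        min(per, key=per.__getitem__),
        max(per, key=per.__getitem__),
    )
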