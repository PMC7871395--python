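"""Rearrangement scores (RS) and rearrangement frequencies (RF).

The quantification works on gene adjacencies. Against a reference
arrangement in which every gene is single-copy, each gene occurrence in a
genome is scored by how many of its two nearest flanking neighbours differ
from the reference flanks of that gene: RS per occurrence is 0, 1 or 2. The
genome RS is the sum over all occurrences (CR included). Within a taxonomic
group, the rearrangement frequency of a gene is its accumulated RS divided
by the maximum attainable (2 per occurrence), as a percentage:

    RF(g) = 100 * sum(RS of occurrences of g) / (2 * n_occurrences(g))

Genes never observed in a group have undefined RF (reported missing, not 0).
Two comparison modes are provided: ``ordered`` (default; left flank compared
with reference left, right with right) and ``unordered`` (flank pairs
compared as unordered multisets — never stricter than ordered).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Literal, Sequence

from .gene_order_io import GeneOrder, ReferenceArrangement

log = logging.getLogger("mgrquant")

Mode = Literal["ordered", "unordered"]


@dataclass(frozen=True)
class GeneScore:
    """Flank-change score of one gene occurrence (rs = left + right, 0..2)."""

    species_id: str
    label: str
    copy_index: int
    left_changed: int
    right_changed: int

    @property
    def rs(self) -> int:
        return self.left_changed + self.right_changed


@dataclass(frozen=True)
class GenomeScore:
    """Genome-level RS: sum of per-occurrence scores.

    ``n_rearranged_genes`` counts occurrences with rs > 0;
    ``n_rearranged_labels`` counts distinct gene labels with rs > 0 (a
    tandem-duplicated gene contributes two scored occurrences but one label).
    """

    species_id: str
    rs: int
    n_rearranged_genes: int
    n_rearranged_labels: int


def neighbor_context(order: GeneOrder, position: int) -> tuple[str, str]:
    """Circular (left, right) neighbour labels of the occurrence at
    ``position``; for position 0 the left neighbour is the last element."""
    n = len(order)
    if n < 2:
        raise ValueError("neighbour context undefined for orders shorter than 2")
    if not 0 <= position < n:
        raise IndexError(f"position {position} out of range for order of length {n}")
    labels = order.labels()
    return labels[position - 1], labels[(position + 1) % n]


def score_gene(
    order: GeneOrder,
    position: int,
    reference: ReferenceArrangement,
    mode: Mode = "ordered",
) -> GeneScore:
    """Score one occurrence against the reference flanks of its label.

    Every occurrence of a duplicated label is scored independently against
    the single reference context of that label; neighbour *labels* are
    compared, not copy identities, so a tandem duplicate whose neighbour is
    another copy of itself matches a same-label reference flank only if the
    reference flank carries that label.
    """
    occ = order.occurrences[position]
    ref_left, ref_right = reference.neighbors(occ.label)
    obs_left, obs_right = neighbor_context(order, position)
    if mode == "ordered":
        left_changed = int(obs_left != ref_left)
        right_changed = int(obs_right != ref_right)
    elif mode == "unordered":
        # greedy maximum matching on 2-element multisets is exact
        pool = [ref_left, ref_right]
        if obs_left in pool:
            pool.remove(obs_left)
            left_changed = 0
        else:
            left_changed = 1
        right_changed = int(obs_right not in pool)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return GeneScore(order.species_id, occ.label, occ.copy_index, left_changed, right_changed)


def gene_scores(
    order: GeneOrder, reference: ReferenceArrangement, mode: Mode = "ordered"
) -> list[GeneScore]:
    return [score_gene(order, i, reference, mode) for i in range(len(order))]


def score_genome(
    order: GeneOrder, reference: ReferenceArrangement, mode: Mode = "ordered"
) -> GenomeScore:
    """Genome RS: accumulate the per-occurrence scores of all genes.

    Lost genes have no occurrences and contribute nothing directly; their
    absence is captured through the changed flanks of surviving neighbours.
    """
    scores = gene_scores(order, reference, mode)
    rs = sum(s.rs for s in scores)
    hit = [s for s in scores if s.rs > 0]
    return GenomeScore(order.species_id, rs, len(hit), len({s.label for s in hit}))


# ---------------------------------------------------------------------------
# RF tables
# ---------------------------------------------------------------------------

@dataclass
class RFTable:
    """Per-gene rearrangement frequency within one group.

    Maps each reference gene label to ``(accumulated_rs, occurrence_count,
    rf_percent)``; ``rf_percent`` is None (missing) when the gene has no
    occurrences in the group.
    """

    group: str
    reference: str
    mode: str
    rows: dict[str, tuple[int, int, float | None]]

    def rf(self, label: str) -> float | None:
        return self.rows[label][2]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"gene": g, "accumulated_rs": a, "occurrence_count": c,
                 "rf_percent": float("nan") if rf is None else rf}
                for g, (a, c, rf) in self.rows.items()
            ]
        ).set_index("gene")


def _group_key(order: GeneOrder, group_by: str) -> str | None:
    if group_by == "all":
        return "all"
    ranks = {"order": 0, "family": 1}
    idx = ranks.get(group_by)
    if idx is None:
        raise ValueError(f"unknown grouping rank: {group_by!r}")
    if idx >= len(order.taxon):
        return None
    return order.taxon[idx]


def rf_table(
    orders: Sequence[GeneOrder],
    reference: ReferenceArrangement,
    group_by: str = "all",
    mode: Mode = "ordered",
) -> list[RFTable]:
    """Accumulate per-gene RS over each group and convert to RF percentages.

    The denominator is 2 x occurrence count, so duplicated genes enlarge the
    maximum attainable RS of their label; rf_percent is carried in full
    precision and rounded to 2 decimals only on rendering.
    """
    if not orders:
        raise ValueError("rf_table needs at least one gene order")
    groups: dict[str, list[GeneOrder]] = defaultdict(list)
    for order in orders:
        key = _group_key(order, group_by)
        if key is None:
            log.warning("%s: no %r rank in taxon metadata; omitted from RF grouping",
                        order.species_id, group_by)
            continue
        groups[key].append(order)
    tables: list[RFTable] = []
    for group, members in groups.items():
        acc: dict[str, int] = defaultdict(int)
        cnt: dict[str, int] = defaultdict(int)
        for order in members:
            for s in gene_scores(order, reference, mode):
                acc[s.label] += s.rs
                cnt[s.label] += 1
        rows: dict[str, tuple[int, int, float | None]] = {}
        for label in reference.labels():
            c = cnt.get(label, 0)
            a = acc.get(label, 0)
            rows[label] = (a, c, None if c == 0 else 100.0 * a / (2 * c))
        tables.append(RFTable(group, reference.name, mode, rows))
    return tables


def conserved_segments(
    rf: RFTable, reference: ReferenceArrangement
) -> list[tuple[str, ...]]:
    """Maximal circular runs (length >= 2) of reference-adjacent genes whose
    RF is exactly 0, ordered by length descending.

    Consecutive adjacent genes that were never rearranged anywhere in the
    group form a conserved segment of the genome. Genes with undefined RF
    (absent from the group) break a run.
    """
    labels = reference.labels()
    n = len(labels)
    is_zero = [rf.rows[lab][2] == 0.0 for lab in labels]
    if all(is_zero):
        return [tuple(labels)]
    if not any(is_zero):
        return []
    # rotate so the scan starts on a non-zero gene; runs never span the seam
    start = next(i for i, z in enumerate(is_zero) if not z)
    runs: list[tuple[str, ...]] = []
    run: list[str] = []
    for k in range(1, n + 1):
        i = (start + k) % n
        if is_zero[i]:
            run.append(labels[i])
        elif run:
            if len(run) >= 2:
                runs.append(tuple(run))
            run = []
    if len(run) >= 2:
        runs.append(tuple(run))
    runs.sort(key=len, reverse=True)
    return runs
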