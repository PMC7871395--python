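"""Phylogenetic structure of rearranged genomes.

Three questions are addressed given a rooted, dated phylogeny whose tips are
the sampled species:

* are rearranged genomes phylogenetically clustered? — per-clade upper-tail
  hypergeometric enrichment of the binary tip label, Bonferroni-corrected
  over the internal nodes tested, summarised by the minimum adjusted p;
* is the rarity of rare arrangements explained by sparse taxon sampling? —
  a single hypergeometric test of the overlap between rare-arrangement
  species and species from thinly sampled families (<= 2 species);
* how old can a shared arrangement pattern be? — the age of the most recent
  common ancestor (MRCA) of the species carrying it, read as the *latest*
  possible origin of the pattern (identical arrangements are assumed
  homologous, not convergent).

Divergence times are inputs (ultrametric branch lengths or a sidecar node
age table); no tree inference or dating is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
from scipy.stats import hypergeom

log = logging.getLogger("mgrquant")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N population, K successes, n draws)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentResult:
    node_id: str
    clade_size: int
    k: int            # labeled tips inside the clade
    N: int            # tips in the tree (population)
    K: int            # labeled tips in the tree
    p: float
    adj_p: float      # Bonferroni over tested nodes, capped at 1


class LabeledTree:
    """A rooted tree with species tips, optional node ages (Ma), and an
    optional binary tip labeling (e.g. rearranged vs typical)."""

    def __init__(
        self,
        tree: dendropy.Tree,
        ages: Mapping[str, float] | None = None,
        labels: Iterable[str] = (),
    ):
        self.tree = tree
        self.tree.is_rooted = True  # MRCA semantics need an explicit root
        self.tree.update_bipartitions(suppress_unifurcations=False)
        self.labels: set[str] = set(labels)
        tips = self.tip_names()
        if len(tips) != len(set(tips)):
            raise ValueError("tip names are not unique")
        stray = self.labels - set(tips)
        if stray:
            raise ValueError(f"labeled species are not tips: {sorted(stray)}")
        self._ages = dict(ages) if ages is not None else None
        if self._ages is None:
            # ultrametric input: node age = distance to the farthest tip
            try:
                self.tree.calc_node_ages(ultrametricity_precision=1e-4)
            except Exception:
                self.tree.calc_node_ages(ultrametricity_precision=False)

    @classmethod
    def from_newick(
        cls,
        source: str | Path,
        ages: Mapping[str, float] | None = None,
        labels: Iterable[str] = (),
    ) -> "LabeledTree":
        src = str(source)
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=src, schema="newick")
        else:
            tree = dendropy.Tree.get(path=src, schema="newick")
        return cls(tree, ages=ages, labels=labels)

    def tip_names(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def node_age(self, node: dendropy.Node) -> float:
        if self._ages is not None:
            label = node.label if node.label else (node.taxon.label if node.taxon else None)
            if label is None or label not in self._ages:
                raise KeyError(f"no age for node {label!r} in the age table")
            return float(self._ages[label])
        return float(node.age)

    def mrca(self, species: Iterable[str]) -> dendropy.Node:
        species = list(species)
        node = self.tree.mrca(taxon_labels=species)
        if node is None:
            raise ValueError(f"no MRCA found for {species}")
        return node


def read_ages_table(path: str | Path) -> dict[str, float]:
    """Sidecar node-age table: TSV of ``node_label <TAB> age_Ma``."""
    ages: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).open(encoding="utf-8"), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, value = line.split("\t")[:2]
        ages[name] = float(value)
    return ages


def clade_enrichment(
    tree: LabeledTree, labels: Iterable[str] | None = None
) -> tuple[list[EnrichmentResult], float]:
    """Per-clade hypergeometric enrichment of a binary tip label.

    For every internal node whose clade holds between 2 and N-1 tips, the
    number k of labeled tips inside the clade of size n is compared with
    drawing n tips at random from the N-tip, K-labeled population:
    p = sum_{i=k..min(n,K)} C(K,i) C(N-K, n-i) / C(N,n). Bonferroni adjusts
    over the nodes tested; returns all results plus the minimum adjusted p.
    Degenerate labelings (all or none labeled) give p = 1 everywhere.
    """
    labeled = set(labels) if labels is not None else set(tree.labels)
    tips = tree.tip_names()
    N = len(tips)
    K = len(labeled & set(tips))
    degenerate = K == 0 or K == N
    results: list[EnrichmentResult] = []
    for idx, node in enumerate(tree.tree.preorder_internal_node_iter()):
        clade = [leaf.taxon.label for leaf in node.leaf_iter()]
        n = len(clade)
        if not 2 <= n <= N - 1:
            continue
        k = sum(1 for t in clade if t in labeled)
        p = 1.0 if degenerate else hypergeom_upper_tail(k, N, K, n)
        node_id = node.label or f"node{idx}"
        results.append(EnrichmentResult(node_id, n, k, N, K, p, p))
    m = len(results)
    results = [
        EnrichmentResult(r.node_id, r.clade_size, r.k, r.N, r.K, r.p,
                         min(1.0, r.p * m))
        for r in results
    ]
    min_adj = min((r.adj_p for r in results), default=1.0)
    return results, min_adj


def sampling_density_test(
    rare_species: Iterable[str], family_of: Mapping[str, str]
) -> EnrichmentResult:
    """Do rare arrangements concentrate in thinly sampled families?

    Population: all species in the family table; successes: species whose
    family contributed <= 2 sampled species; draws: the rare-arrangement
    species. Upper-tail hypergeometric p on the observed overlap.
    """
    rare = list(dict.fromkeys(rare_species))
    missing = [sp for sp in rare if sp not in family_of]
    if missing:
        raise ValueError(f"species without family annotation: {missing}")
    N = len(family_of)
    fam_sizes: dict[str, int] = {}
    for fam in family_of.values():
        fam_sizes[fam] = fam_sizes.get(fam, 0) + 1
    sparse = {sp for sp, fam in family_of.items() if fam_sizes[fam] <= 2}
    K = len(sparse)
    n = len(rare)
    k = sum(1 for sp in rare if sp in sparse)
    p = hypergeom_upper_tail(k, N, K, n)
    return EnrichmentResult("sampling_density", n, k, N, K, p, p)


def mrca_age(tree: LabeledTree, species: Iterable[str]) -> float:
    """Age (Ma) of the MRCA of the species sharing a pattern — the latest
    possible origin time of that pattern. Requires >= 2 species (a single
    genome bounds nothing)."""
    species = list(species)
    if len(species) < 2:
        raise ValueError("need >= 2 species to bound a pattern's origin")
    return tree.node_age(tree.mrca(species))
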