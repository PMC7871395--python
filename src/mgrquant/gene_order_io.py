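"""Gene alphabet, reference arrangements, and gene-order input/output.

The unit of analysis is a *gene order*: the circular sequence of the 13
protein-coding genes, 2 rRNAs, 22 tRNAs and the control region (CR, treated
as a single gene) of one mitochondrial genome. Orders are read either from a
simple tab-separated table (one genome per row) or from GenBank flat files,
whose features are sorted by position and mapped onto the closed 38-token
alphabet.

Naming convention for the duplicated leucine/serine tRNAs is POSITIONAL, not
anticodon-based: L1 is the leucine tRNA downstream of rrnL (= Leu(UUR)), L2
the one adjacent to nad5 (= Leu(CUN)); S1 follows cox1 (= Ser(UCN)), S2
follows trnH (= Ser(AGY)). This inverts the anticodon tag convention used by
some annotation pipelines (where trnL1 = CUN); the synonym table accepts
anticodon-qualified spellings of both.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger("mgrquant")

# ---------------------------------------------------------------------------
# Alphabet
# ---------------------------------------------------------------------------

PCGS: tuple[str, ...] = (
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "cox1", "cox2", "cox3", "cob", "atp6", "atp8",
)
RRNAS: tuple[str, ...] = ("rrnS", "rrnL")
TRNAS: tuple[str, ...] = (
    "A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
    "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y",
)
CONTROL_REGION = "CR"

#: The closed 38-token alphabet: 13 PCGs + 2 rRNAs + 22 tRNAs + CR.
MITO_ALPHABET: frozenset[str] = frozenset(PCGS) | frozenset(RRNAS) | frozenset(TRNAS) | {CONTROL_REGION}

_AA3_TO_1 = {
    "ala": "A", "cys": "C", "asp": "D", "glu": "E", "phe": "F", "gly": "G",
    "his": "H", "ile": "I", "lys": "K", "met": "M", "asn": "N", "pro": "P",
    "gln": "Q", "arg": "R", "thr": "T", "val": "V", "trp": "W", "tyr": "Y",
}

# Positional convention: L1 = Leu(UUR) (after rrnL), L2 = Leu(CUN) (next to
# nad5); S1 = Ser(UCN) (after cox1), S2 = Ser(AGY) (after trnH).
_LEU_SER_CODONS = {
    "uur": "L1", "uua": "L1", "uug": "L1", "taa": "L1",
    "cun": "L2", "tag": "L2",
    "ucn": "S1", "tga": "S1",
    "agy": "S2", "agc": "S2", "agn": "S2", "gct": "S2",
}


def _build_synonyms() -> dict[str, str]:
    syn: dict[str, str] = {}
    for token in MITO_ALPHABET:
        syn[token.lower()] = token
    # protein-coding genes
    for nd, nad in (("nd1", "nad1"), ("nd2", "nad2"), ("nd3", "nad3"),
                    ("nd4", "nad4"), ("nd4l", "nad4L"), ("nd5", "nad5"),
                    ("nd6", "nad6")):
        syn[nd] = nad
    for alias, token in (("co1", "cox1"), ("coi", "cox1"), ("coxi", "cox1"),
                         ("co2", "cox2"), ("coii", "cox2"), ("coxii", "cox2"),
                         ("co3", "cox3"), ("coiii", "cox3"), ("coxiii", "cox3"),
                         ("cytb", "cob"), ("cyt b", "cob"), ("cob", "cob"),
                         ("atpase6", "atp6"), ("atpase 6", "atp6"),
                         ("atpase8", "atp8"), ("atpase 8", "atp8")):
        syn[alias] = token
    # rRNAs
    for alias, token in (("12s", "rrnS"), ("12s rrna", "rrnS"), ("rns", "rrnS"),
                         ("s-rrna", "rrnS"), ("12s ribosomal rna", "rrnS"),
                         ("small subunit ribosomal rna", "rrnS"),
                         ("16s", "rrnL"), ("16s rrna", "rrnL"), ("rnl", "rrnL"),
                         ("l-rrna", "rrnL"), ("16s ribosomal rna", "rrnL"),
                         ("large subunit ribosomal rna", "rrnL")):
        syn[alias] = token
    # control region
    for alias in ("d-loop", "dloop", "control region", "cr", "a+t rich region",
                  "at-rich region", "putative control region"):
        syn[alias] = CONTROL_REGION
    # tRNAs: trnX, tRNA-Xxx, and anticodon-qualified Leu/Ser
    for aa3, one in _AA3_TO_1.items():
        syn[f"trn{one.lower()}"] = one
        syn[f"trna-{aa3}"] = one
    for codon, token in _LEU_SER_CODONS.items():
        for stem in ("trnl", "trna-leu"):
            if token.startswith("L"):
                syn[f"{stem}({codon})"] = token
        for stem in ("trns", "trna-ser"):
            if token.startswith("S"):
                syn[f"{stem}({codon})"] = token
    syn["trnl1"] = "L1"
    syn["trnl2"] = "L2"
    syn["trns1"] = "S1"
    syn["trns2"] = "S2"
    return syn


SYNONYMS: dict[str, str] = _build_synonyms()


class UnknownGeneError(ValueError):
    """A token does not map to any member of the closed gene alphabet."""


def normalize_label(token: str) -> str:
    """Map an input token onto the 38-token alphabet (case-insensitive).

    Raises :class:`UnknownGeneError` for tokens outside the alphabet; unknown
    tokens are never silently dropped. The undefined token ``V1`` that
    appears in some published arrangement strings is mapped to ``V`` with a
    warning.
    """
    key = token.strip().lower()
    if key in SYNONYMS:
        return SYNONYMS[key]
    if key == "v1":
        warnings.warn("token 'V1' is undefined; interpreting as trnV", stacklevel=2)
        return "V"
    raise UnknownGeneError(f"unknown gene token: {token!r}")


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneOccurrence:
    """One occurrence of a gene in a genome.

    ``copy_index`` is 1-based and ordinal among same-label occurrences in
    reading order, so duplicated genes are distinguishable.
    """

    label: str
    copy_index: int = 1
    strand: str = "?"  # '+', '-' or '?'


@dataclass(frozen=True)
class GeneOrder:
    """A circular, ordered sequence of gene occurrences for one species.

    The last element is adjacent to the first. Orders may lack genes (loss)
    and may contain repeated labels (duplication).
    """

    species_id: str
    occurrences: tuple[GeneOccurrence, ...]
    taxon: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.occurrences) < 2:
            raise ValueError(
                f"{self.species_id}: a circular gene order needs >= 2 occurrences"
            )
        seen: dict[str, int] = {}
        for occ in self.occurrences:
            seen[occ.label] = seen.get(occ.label, 0) + 1
            if occ.copy_index != seen[occ.label]:
                raise ValueError(
                    f"{self.species_id}: copy_index of {occ.label} not consecutive "
                    f"from 1 in reading order"
                )

    def __len__(self) -> int:
        return len(self.occurrences)

    def labels(self) -> tuple[str, ...]:
        return tuple(occ.label for occ in self.occurrences)

    def tokens(self, strand_sensitive: bool = False) -> tuple[str, ...]:
        """Label sequence; with ``strand_sensitive`` minus-strand genes get a
        leading ``-``."""
        if not strand_sensitive:
            return self.labels()
        return tuple(
            ("-" + occ.label) if occ.strand == "-" else occ.label
            for occ in self.occurrences
        )

    def rotated(self, offset: int) -> "GeneOrder":
        """Same circular order linearized starting ``offset`` positions later."""
        n = len(self.occurrences)
        offset %= n
        labels = self.labels()[offset:] + self.labels()[:offset]
        strands = tuple(o.strand for o in self.occurrences)
        strands = strands[offset:] + strands[:offset]
        return GeneOrder.from_tokens(
            self.species_id, labels, taxon=self.taxon, strands=strands,
            alphabet=None,
        )

    @classmethod
    def from_tokens(
        cls,
        species_id: str,
        tokens: Sequence[str],
        taxon: Sequence[str] = (),
        strands: Sequence[str] | None = None,
        alphabet: frozenset[str] | None = MITO_ALPHABET,
    ) -> "GeneOrder":
        """Build an order from plain label tokens, assigning copy indices in
        reading order.

        ``alphabet=None`` skips membership validation (used for toy alphabets
        in simulation-free analyses); with the default alphabet, tokens are
        normalized through the synonym table first.
        """
        if not tokens:
            raise ValueError(f"{species_id}: empty token list")
        counts: dict[str, int] = {}
        occs = []
        for i, tok in enumerate(tokens):
            strand = strands[i] if strands is not None else "?"
            if tok.startswith("-") and len(tok) > 1:
                strand, tok = "-", tok[1:]
            label = normalize_label(tok) if alphabet is not None else tok
            if alphabet is not None and label not in alphabet:
                raise UnknownGeneError(f"unknown gene token: {tok!r}")
            counts[label] = counts.get(label, 0) + 1
            occs.append(GeneOccurrence(label, counts[label], strand))
        return cls(species_id, tuple(occs), tuple(taxon))


@dataclass(frozen=True)
class ReferenceArrangement:
    """A named benchmark arrangement in which every gene label is unique, so
    each gene has exactly one reference left/right neighbour."""

    name: str
    order: GeneOrder
    _neighbors: dict[str, tuple[str, str]] = field(
        default_factory=dict, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        labels = self.order.labels()
        if len(set(labels)) != len(labels):
            raise ValueError(f"reference {self.name!r} has duplicated labels")
        n = len(labels)
        for i, lab in enumerate(labels):
            self._neighbors[lab] = (labels[i - 1], labels[(i + 1) % n])

    def labels(self) -> tuple[str, ...]:
        return self.order.labels()

    def __contains__(self, label: str) -> bool:
        return label in self._neighbors

    def neighbors(self, label: str) -> tuple[str, str]:
        """Reference (left, right) flanking labels of ``label``."""
        try:
            return self._neighbors[label]
        except KeyError:
            raise KeyError(f"{label!r} absent from reference {self.name!r}") from None


_VERTEBRATE_TOKENS = (
    "F", "rrnS", "V", "rrnL", "L1", "nad1", "I", "Q", "M", "nad2",
    "W", "A", "N", "C", "Y", "cox1", "S1", "D", "cox2", "K",
    "atp8", "atp6", "cox3", "G", "nad3", "R", "nad4L", "nad4", "H", "S2",
    "L2", "nad5", "nad6", "E", "cob", "T", "P", "CR",
)

# Differs from the vertebrate order only inside the nad4 -> rrnS span: the
# L2-T-P-F tRNA cluster is relocated 3' of the control region (LTPF cluster).
_NEOBATRACHIAN_TOKENS = (
    "F", "rrnS", "V", "rrnL", "L1", "nad1", "I", "Q", "M", "nad2",
    "W", "A", "N", "C", "Y", "cox1", "S1", "D", "cox2", "K",
    "atp8", "atp6", "cox3", "G", "nad3", "R", "nad4L", "nad4", "H", "S2",
    "nad5", "nad6", "E", "cob", "CR", "L2", "T", "P",
)

#: Ancestral vertebrate mitochondrial gene order (37 genes + CR).
TYPICAL_VERTEBRATE = ReferenceArrangement(
    "vertebrate", GeneOrder.from_tokens("typical_vertebrate", _VERTEBRATE_TOKENS)
)

#: Derived order of most neobatrachian frogs (LTPF cluster 3' of the CR).
TYPICAL_NEOBATRACHIAN = ReferenceArrangement(
    "neobatrachian", GeneOrder.from_tokens("typical_neobatrachian", _NEOBATRACHIAN_TOKENS)
)

REFERENCES: dict[str, ReferenceArrangement] = {
    "vertebrate": TYPICAL_VERTEBRATE,
    "neobatrachian": TYPICAL_NEOBATRACHIAN,
}


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------
# UTF-8, tab-separated, '#' comment lines. Columns:
#   species_id <TAB> taxon ranks joined by ';' <TAB> comma-separated tokens
# A leading '-' on a token marks the minus strand.


def read_gene_orders(path: str | Path, dialect: str = "tsv") -> list[GeneOrder]:
    """Read gene orders from the package's TSV dialect.

    Raises :class:`UnknownGeneError` naming the offending row and token, and
    ``ValueError`` for malformed/empty rows.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect: {dialect!r}")
    path = Path(path)
    orders: list[GeneOrder] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            species_id, taxon_field, token_field = parts[0], parts[1], parts[2]
            taxon = tuple(t.strip() for t in taxon_field.split(";") if t.strip())
            tokens = [t.strip() for t in token_field.split(",") if t.strip()]
            if not tokens:
                raise ValueError(f"{path}:{lineno}: empty token list for {species_id!r}")
            try:
                orders.append(GeneOrder.from_tokens(species_id, tokens, taxon=taxon))
            except UnknownGeneError as exc:
                raise UnknownGeneError(f"{path}:{lineno}: {exc}") from None
    return orders


def write_gene_orders(orders: Iterable[GeneOrder], path: str | Path) -> None:
    """Write orders in the TSV dialect; round-trips losslessly through
    :func:`read_gene_orders` (strand preserved, copy indices re-derived)."""
    orders = list(orders)
    if not orders:
        raise ValueError("refusing to write an empty gene-order table")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# species_id\ttaxon\tgene_order\n")
        for order in orders:
            fh.write(
                f"{order.species_id}\t{';'.join(order.taxon)}\t"
                f"{','.join(order.tokens(strand_sensitive=True))}\n"
            )


# ---------------------------------------------------------------------------
# GenBank flat files
# ---------------------------------------------------------------------------

_FEATURE_TYPES = {"CDS", "tRNA", "rRNA", "D-loop", "misc_feature"}


def _feature_label(feature) -> str | None:
    """Map a GenBank feature onto the alphabet, or None if unmappable."""
    quals = feature.qualifiers
    candidates: list[str] = []
    product = (quals.get("product") or [None])[0]
    gene = (quals.get("gene") or [None])[0]
    note = (quals.get("note") or [None])[0]
    if feature.type == "D-loop":
        return CONTROL_REGION
    if product:
        candidates.append(product)
    if gene:
        candidates.append(gene)
    if note and feature.type == "misc_feature":
        candidates.append(note)
    # Ambiguous Leu/Ser products: disambiguate by anticodon/codon qualifiers.
    codon = (quals.get("codon_recognized") or quals.get("anticodon") or [None])[0]
    for cand in candidates:
        key = cand.strip().lower()
        if key in ("trna-leu", "trnl", "trna-ser", "trns") and codon:
            key = f"{key}({codon.strip().lower()})"
        if key in SYNONYMS:
            return SYNONYMS[key]
        try:
            return normalize_label(cand)
        except UnknownGeneError:
            continue
    return None


def read_genbank_order(path: str | Path) -> GeneOrder:
    """Parse a GenBank flat file into a :class:`GeneOrder`.

    Features are sorted by start coordinate (a feature spanning the origin is
    placed first); pseudogene-flagged features and the light-strand
    replication origin (O_L) are excluded, as their annotations are too
    inconsistent to compare; a CR token is emitted once per annotated
    control-region feature. Overlapping duplicate annotations of the same
    gene keep the first and log a warning.
    """
    from Bio import SeqIO

    path = Path(path)
    record = SeqIO.read(str(path), "genbank")
    seq_len = len(record.seq)
    entries: list[tuple[int, int, str, str]] = []  # (start, end, label, strand)
    for feat in record.features:
        if feat.type == "rep_origin":
            continue  # O_L: excluded by design
        if feat.type not in _FEATURE_TYPES:
            continue
        if "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers:
            continue
        label = _feature_label(feat)
        if label is None:
            if feat.type != "misc_feature":
                log.warning("%s: unmappable %s feature at %s", path.name, feat.type, feat.location)
            continue
        start = int(feat.location.start)
        end = int(feat.location.end)
        strand = "+" if feat.location.strand == 1 else "-" if feat.location.strand == -1 else "?"
        if end < start or (len(feat.location.parts) > 1 and int(feat.location.parts[0].start) > int(feat.location.parts[-1].end)):
            start -= seq_len  # spans the origin: linearize first
        entries.append((start, end, label, strand))
    if not entries:
        raise ValueError(f"{path}: no mappable gene features")
    entries.sort(key=lambda e: (e[0], e[1]))
    # drop overlapping duplicate annotations of the same gene (keep first)
    kept: list[tuple[int, int, str, str]] = []
    for start, end, label, strand in entries:
        if kept and kept[-1][2] == label and start < kept[-1][1]:
            log.warning("%s: overlapping duplicate annotation of %s; keeping first", path.name, label)
            continue
        kept.append((start, end, label, strand))
    tokens = [label for _, _, label, _ in kept]
    strands = [strand for _, _, _, strand in kept]
    species = record.annotations.get("organism") or record.id or path.stem
    return GeneOrder.from_tokens(str(species), tokens, strands=strands)
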