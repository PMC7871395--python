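"""Shared fixtures: small gene orders and programmatically built GenBank files."""

from __future__ import annotations

import pytest

from mgrquant import PCGS, TYPICAL_VERTEBRATE, GeneOrder


@pytest.fixture
def vertebrate_tokens() -> list[str]:
    return list(TYPICAL_VERTEBRATE.labels())


@pytest.fixture
def tandem_dup_order():
    """Build a typical-vertebrate order with a tandem duplication of one gene."""

    def _build(gene: str, species_id: str | None = None) -> GeneOrder:
        tokens = list(TYPICAL_VERTEBRATE.labels())
        tokens.insert(tokens.index(gene) + 1, gene)
        return GeneOrder.from_tokens(species_id or f"dup_{gene}", tokens,
                                     taxon=("TestOrder", "TestFam"))

    return _build


# --- GenBank fixture builder -------------------------------------------------

_TRNA_PRODUCTS = {
    "A": "tRNA-Ala", "C": "tRNA-Cys", "D": "tRNA-Asp", "E": "tRNA-Glu",
    "F": "tRNA-Phe", "G": "tRNA-Gly", "H": "tRNA-His", "I": "tRNA-Ile",
    "K": "tRNA-Lys", "M": "tRNA-Met", "N": "tRNA-Asn", "P": "tRNA-Pro",
    "Q": "tRNA-Gln", "R": "tRNA-Arg", "T": "tRNA-Thr", "V": "tRNA-Val",
    "W": "tRNA-Trp", "Y": "tRNA-Tyr",
    "L1": ("tRNA-Leu", "UUR"), "L2": ("tRNA-Leu", "CUN"),
    "S1": ("tRNA-Ser", "UCN"), "S2": ("tRNA-Ser", "AGY"),
}
_PCG_NAMES = {
    "nad1": "ND1", "nad2": "ND2", "nad3": "ND3", "nad4": "ND4",
    "nad4L": "ND4L", "nad5": "ND5", "nad6": "ND6", "cox1": "COX1",
    "cox2": "COX2", "cox3": "COX3", "cob": "CYTB", "atp6": "ATP6",
    "atp8": "ATP8",
}


@pytest.fixture
def genbank_file(tmp_path):
    """Write a synthetic GenBank flat file annotating the given gene order.

    ``extras`` inserts extra features: ``("OL", after_label)`` adds a
    rep_origin, ``("pseudo", label, after_label)`` a pseudogene tRNA.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    def _feature(label: str, start: int) -> "SeqFeature":
        loc = SimpleLocation(start, start + 10, strand=1)
        if label == "CR":
            return SeqFeature(loc, type="D-loop")
        if label in _PCG_NAMES:
            return SeqFeature(loc, type="CDS", qualifiers={"gene": [_PCG_NAMES[label]]})
        if label in ("rrnS", "rrnL"):
            product = "12S ribosomal RNA" if label == "rrnS" else "16S ribosomal RNA"
            return SeqFeature(loc, type="rRNA", qualifiers={"product": [product]})
        prod = _TRNA_PRODUCTS[label]
        quals = {"product": [prod[0] if isinstance(prod, tuple) else prod]}
        if isinstance(prod, tuple):
            quals["codon_recognized"] = [prod[1]]
        return SeqFeature(loc, type="tRNA", qualifiers=quals)

    def _build(tokens, extras=(), name="fixture"):
        feats, pos = [], 0
        for label in tokens:
            feats.append(_feature(label, pos))
            pos += 10
        for extra in extras:
            if extra[0] == "OL":
                after = tokens.index(extra[1])
                feats.insert(after + 1, SeqFeature(
                    SimpleLocation(after * 10 + 4, after * 10 + 8, strand=1),
                    type="rep_origin"))
            elif extra[0] == "pseudo":
                _, label, after_label = extra
                after = tokens.index(after_label)
                feat = _feature(label, after * 10 + 4)
                feat.qualifiers["pseudo"] = [""]
                feats.insert(after + 1, feat)
        record = SeqRecord(Seq("A" * pos), id="SYN0001",
                           annotations={"organism": name, "molecule_type": "DNA"})
        record.features = feats
        path = tmp_path / f"{name}.gb"
        SeqIO.write(record, str(path), "genbank")
        return path

    return _build
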