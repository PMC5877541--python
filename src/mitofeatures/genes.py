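"""Gene nomenclature for the 37-gene insect mitogenome.

Canonical names, alias normalization, gene classes, and the ancestral
(*Drosophila*-type) gene arrangement with strands. The two Leu and two Ser
tRNAs are disambiguated by their anticodon class (UUR/CUN and AGN/UCN);
a bare "tRNA-Leu" or "tRNA-Ser" is deliberately rejected as ambiguous.
"""

from __future__ import annotations

# Strand symbols: J = majority/plus strand, N = minority/minus strand.
J = "J"
N = "N"

PCG_NAMES = (
    "ND2", "COI", "COII", "ATP8", "ATP6", "COIII", "ND3",
    "ND5", "ND4", "ND4L", "ND6", "CytB", "ND1",
)

TRNA_NAMES = (
    "tRNA-Ile", "tRNA-Gln", "tRNA-Met", "tRNA-Trp", "tRNA-Cys", "tRNA-Tyr",
    "tRNA-Leu(UUR)", "tRNA-Lys", "tRNA-Asp", "tRNA-Gly", "tRNA-Ala",
    "tRNA-Arg", "tRNA-Asn", "tRNA-Ser(AGN)", "tRNA-Glu", "tRNA-Phe",
    "tRNA-His", "tRNA-Thr", "tRNA-Pro", "tRNA-Ser(UCN)", "tRNA-Leu(CUN)",
    "tRNA-Val",
)

RRNA_NAMES = ("lrRNA", "srRNA")

CONTROL_REGION = "CR"

ALL_GENE_NAMES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES

#: Ancestral insect mitochondrial gene arrangement (the *D. melanogaster*
#: order), as (name, strand) in genomic order starting from tRNA-Ile.
#: The control region carries no strand (None).
ANCESTRAL_INSECT_ORDER: tuple[tuple[str, str | None], ...] = (
    ("tRNA-Ile", J), ("tRNA-Gln", N), ("tRNA-Met", J), ("ND2", J),
    ("tRNA-Trp", J), ("tRNA-Cys", N), ("tRNA-Tyr", N), ("COI", J),
    ("tRNA-Leu(UUR)", J), ("COII", J), ("tRNA-Lys", J), ("tRNA-Asp", J),
    ("ATP8", J), ("ATP6", J), ("COIII", J), ("tRNA-Gly", J), ("ND3", J),
    ("tRNA-Ala", J), ("tRNA-Arg", J), ("tRNA-Asn", J), ("tRNA-Ser(AGN)", J),
    ("tRNA-Glu", J), ("tRNA-Phe", N), ("ND5", N), ("tRNA-His", N),
    ("ND4", N), ("ND4L", N), ("tRNA-Thr", J), ("tRNA-Pro", N), ("ND6", J),
    ("CytB", J), ("tRNA-Ser(UCN)", J), ("ND1", N), ("tRNA-Leu(CUN)", N),
    ("lrRNA", N), ("tRNA-Val", N), ("srRNA", N), (CONTROL_REGION, None),
)

_AA3_TO_CANONICAL = {
    "ile": "tRNA-Ile", "gln": "tRNA-Gln", "met": "tRNA-Met",
    "trp": "tRNA-Trp", "cys": "tRNA-Cys", "tyr": "tRNA-Tyr",
    "lys": "tRNA-Lys", "asp": "tRNA-Asp", "gly": "tRNA-Gly",
    "ala": "tRNA-Ala", "arg": "tRNA-Arg", "asn": "tRNA-Asn",
    "glu": "tRNA-Glu", "phe": "tRNA-Phe", "his": "tRNA-His",
    "thr": "tRNA-Thr", "pro": "tRNA-Pro", "val": "tRNA-Val",
}

# Fig.-1 style numbering: L1 = Leu(UUR), L2 = Leu(CUN), S1 = Ser(AGN),
# S2 = Ser(UCN).
_ALIASES = {
    "coi": "COI", "co1": "COI", "cox1": "COI",
    "coii": "COII", "co2": "COII", "cox2": "COII",
    "coiii": "COIII", "co3": "COIII", "cox3": "COIII",
    "cytb": "CytB", "cob": "CytB",
    "nd1": "ND1", "nad1": "ND1", "nd2": "ND2", "nad2": "ND2",
    "nd3": "ND3", "nad3": "ND3", "nd4": "ND4", "nad4": "ND4",
    "nd4l": "ND4L", "nad4l": "ND4L", "nd5": "ND5", "nad5": "ND5",
    "nd6": "ND6", "nad6": "ND6",
    "atp6": "ATP6", "atp8": "ATP8",
    "lrrna": "lrRNA", "rrnl": "lrRNA", "16s": "lrRNA", "l-rrna": "lrRNA",
    "srrna": "srRNA", "rrns": "srRNA", "12s": "srRNA", "s-rrna": "srRNA",
    "cr": "CR", "control region": "CR", "a+t-rich region": "CR",
    "d-loop": "CR",
    "trnl1": "tRNA-Leu(UUR)", "l1": "tRNA-Leu(UUR)",
    "trnl2": "tRNA-Leu(CUN)", "l2": "tRNA-Leu(CUN)",
    "trns1": "tRNA-Ser(AGN)", "s1": "tRNA-Ser(AGN)",
    "trns2": "tRNA-Ser(UCN)", "s2": "tRNA-Ser(UCN)",
}

_LEU_TAGS = {"uur": "tRNA-Leu(UUR)", "cun": "tRNA-Leu(CUN)"}
_SER_TAGS = {"agn": "tRNA-Ser(AGN)", "ucn": "tRNA-Ser(UCN)"}


class GeneNameError(ValueError):
    """Raised for unrecognized or ambiguous gene names."""


def normalize_gene_name(name: str) -> str:
    """Map a gene name (case-insensitive, common aliases) to canonical form.

    Raises :class:`GeneNameError` for unknown names, and for a Leu/Ser tRNA
    lacking its UUR/CUN/AGN/UCN anticodon-class tag.
    """
    raw = name.strip()
    low = raw.lower()
    if low in _ALIASES:
        return _ALIASES[low]
    for canon in ALL_GENE_NAMES:
        if low == canon.lower():
            return canon
    if low.startswith("trna-") or low.startswith("trn"):
        body = low.removeprefix("trna-").removeprefix("trna").removeprefix("trn")
        tag = None
        if "(" in body and body.endswith(")"):
            body, tag = body[:-1].split("(", 1)
        body = body.strip("-_ ")
        if body in ("leu", "l"):
            if tag in _LEU_TAGS:
                return _LEU_TAGS[tag]
            raise GeneNameError(
                f"ambiguous leucine tRNA {name!r}: need a (UUR) or (CUN) tag"
            )
        if body in ("ser", "s"):
            if tag in _SER_TAGS:
                return _SER_TAGS[tag]
            raise GeneNameError(
                f"ambiguous serine tRNA {name!r}: need an (AGN) or (UCN) tag"
            )
        if body in _AA3_TO_CANONICAL:
            return _AA3_TO_CANONICAL[body]
    raise GeneNameError(f"unrecognized gene name: {name!r}")


def gene_class(canonical_name: str) -> str:
    """Classify a canonical gene name as 'PCG', 'tRNA', 'rRNA' or 'CR'."""
    if canonical_name in PCG_NAMES:
        return "PCG"
    if canonical_name in TRNA_NAMES:
        return "tRNA"
    if canonical_name in RRNA_NAMES:
        return "rRNA"
    if canonical_name == CONTROL_REGION:
        return "CR"
    raise GeneNameError(f"not a canonical gene name: {canonical_name!r}")
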