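"""Base composition and strand-skew statistics for genome partitions.

AT and GC skew measure strand asymmetry of base usage:

    AT skew = (A - T) / (A + T)
    GC skew = (G - C) / (G + C)

Both lie in [-1, 1]; a skew flips sign under reverse complementation.
Partitions (whole genome, protein-coding genes by strand, codon positions,
tRNAs by strand, rRNAs, control region) are built by concatenating the
selected features read in gene sense — the convention under which the
minority-strand partitions show their characteristic positive GC skew.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from Bio.Seq import Seq

from .annotation import FeatureTable, GeneFeature
from .genes import J, N

_IUPAC = set("ACGTUNRYSWKMBDHV")
_AMBIGUOUS = _IUPAC - set("ACGTU")

#: Report rounding that matches the published table layout.
AT_SKEW_DECIMALS = 2
GC_SKEW_DECIMALS = 3
PROPORTION_DECIMALS = 1


class SequenceError(ValueError):
    pass


@dataclass(frozen=True)
class CompositionProfile:
    """Base counts, proportions and skews for one sequence partition."""

    a: int
    t: int
    g: int
    c: int
    ambiguous: int = 0

    @property
    def n_unambiguous(self) -> int:
        return self.a + self.t + self.g + self.c

    @property
    def n_nucleotides(self) -> int:
        return self.n_unambiguous + self.ambiguous

    def _pct(self, count: int) -> float:
        return 100.0 * count / self.n_unambiguous

    @property
    def pct_a(self) -> float:
        return self._pct(self.a)

    @property
    def pct_t(self) -> float:
        return self._pct(self.t)

    @property
    def pct_g(self) -> float:
        return self._pct(self.g)

    @property
    def pct_c(self) -> float:
        return self._pct(self.c)

    @property
    def pct_at(self) -> float:
        return self._pct(self.a + self.t)

    @property
    def at_skew(self) -> float | None:
        """(A - T)/(A + T); None when A + T = 0."""
        if self.a + self.t == 0:
            return None
        return (self.a - self.t) / (self.a + self.t)

    @property
    def gc_skew(self) -> float | None:
        """(G - C)/(G + C); None when G + C = 0."""
        if self.g + self.c == 0:
            return None
        return (self.g - self.c) / (self.g + self.c)

    def merge(self, other: "CompositionProfile") -> "CompositionProfile":
        return CompositionProfile(
            a=self.a + other.a, t=self.t + other.t, g=self.g + other.g,
            c=self.c + other.c, ambiguous=self.ambiguous + other.ambiguous,
        )

    def as_row(self) -> dict:
        """Printed-table row: 1-dp proportions, 2/3-dp skews."""
        return {
            "pct_t": round(self.pct_t, PROPORTION_DECIMALS),
            "pct_c": round(self.pct_c, PROPORTION_DECIMALS),
            "pct_a": round(self.pct_a, PROPORTION_DECIMALS),
            "pct_g": round(self.pct_g, PROPORTION_DECIMALS),
            "pct_at": round(self.pct_at, PROPORTION_DECIMALS),
            "at_skew": None if self.at_skew is None else round(self.at_skew, AT_SKEW_DECIMALS),
            "gc_skew": None if self.gc_skew is None else round(self.gc_skew, GC_SKEW_DECIMALS),
            "n_nucleotides": self.n_nucleotides,
        }


def base_composition(seq: str) -> CompositionProfile:
    """Count bases of a nucleotide sequence (U folded into T).

    IUPAC ambiguity codes are tallied separately and excluded from
    proportions and skews. Empty input and non-IUPAC characters raise
    :class:`SequenceError` (the error names the offending position).
    """
    if not seq:
        raise SequenceError("empty sequence")
    s = str(seq).upper()
    counts = {"A": 0, "T": 0, "G": 0, "C": 0}
    ambiguous = 0
    for i, ch in enumerate(s):
        if ch == "U":
            ch = "T"
        if ch in counts:
            counts[ch] += 1
        elif ch in _AMBIGUOUS:
            ambiguous += 1
        else:
            raise SequenceError(f"non-IUPAC character {ch!r} at position {i + 1}")
    return CompositionProfile(
        a=counts["A"], t=counts["T"], g=counts["G"], c=counts["C"], ambiguous=ambiguous
    )


def skew_from_proportions(
    p_a: float, p_t: float, p_g: float, p_c: float
) -> tuple[float | None, float | None]:
    """Skews from (possibly rounded) percentage proportions.

    Returns (at_skew, gc_skew); an undefined denominator yields None for
    that skew rather than an exception.
    """
    if min(p_a, p_t, p_g, p_c) < 0:
        raise ValueError("proportions must be non-negative")
    at = None if p_a + p_t == 0 else (p_a - p_t) / (p_a + p_t)
    gc = None if p_g + p_c == 0 else (p_g - p_c) / (p_g + p_c)
    return at, gc


@dataclass(frozen=True)
class PartitionSpec:
    """A named selection of features with an orientation rule.

    ``selector`` picks features from the table (by predicate); orientation
    is 'gene-sense' (N-strand features reverse-complemented; the published
    convention) or 'genome-plus'. ``codon_position`` in {1, 2, 3} strides
    every third base of each protein-coding gene in gene sense, excluding
    the incomplete trailing stop fragment.
    """

    name: str
    selector: Callable[[GeneFeature], bool]
    orientation: str = "gene-sense"
    codon_position: int | None = None
    #: use the raw genome sequence (spacers included, overlaps counted
    #: once) instead of concatenating features — the whole-genome row
    raw: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in ("gene-sense", "genome-plus"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.codon_position not in (None, 1, 2, 3):
            raise ValueError("codon_position must be 1, 2 or 3")


def _feature_seq(genome: str, feature: GeneFeature, orientation: str) -> str:
    return feature.sequence(genome, gene_sense=(orientation == "gene-sense"))


def partition_composition(
    genome: str, table: FeatureTable, spec: PartitionSpec
) -> CompositionProfile:
    """Composition of the concatenated features selected by ``spec``."""
    if spec.raw:
        return base_composition(genome)
    selected = [f for f in table.features if spec.selector(f)]
    if not selected:
        raise SequenceError(f"partition {spec.name!r} selects no features")
    parts = []
    for f in selected:
        seq = _feature_seq(genome, f, spec.orientation)
        if spec.codon_position is not None:
            if f.gene_class != "PCG":
                raise SequenceError(
                    f"codon-position partition {spec.name!r} selects non-PCG {f.name}"
                )
            whole = 3 * (len(seq) // 3)  # drop the incomplete stop fragment
            seq = seq[spec.codon_position - 1 : whole : 3]
        parts.append(seq)
    return base_composition("".join(parts))


def _cls(cls_name: str, direction: str | None = None) -> Callable[[GeneFeature], bool]:
    def pred(f: GeneFeature) -> bool:
        if f.gene_class != cls_name:
            return False
        return direction is None or f.direction == direction

    return pred


def standard_partitions() -> list[PartitionSpec]:
    """The published composition-table rows, in layout order."""
    specs: list[PartitionSpec] = [
        PartitionSpec("Whole genome", lambda f: True, orientation="genome-plus",
                      raw=True)
    ]
    specs.append(PartitionSpec("PCGs", _cls("PCG")))
    specs.extend(
        PartitionSpec(f"PCGs codon{p}", _cls("PCG"), codon_position=p) for p in (1, 2, 3)
    )
    specs.append(PartitionSpec("PCG-J", _cls("PCG", J)))
    specs.extend(
        PartitionSpec(f"PCG-J codon{p}", _cls("PCG", J), codon_position=p)
        for p in (1, 2, 3)
    )
    specs.append(PartitionSpec("PCG-N", _cls("PCG", N)))
    specs.extend(
        PartitionSpec(f"PCG-N codon{p}", _cls("PCG", N), codon_position=p)
        for p in (1, 2, 3)
    )
    specs += [
        PartitionSpec("tRNAs", _cls("tRNA")),
        PartitionSpec("tRNA-J", _cls("tRNA", J)),
        PartitionSpec("tRNA-N", _cls("tRNA", N)),
        PartitionSpec("rRNAs", _cls("rRNA")),
        PartitionSpec("lrRNA", lambda f: f.name == "lrRNA"),
        PartitionSpec("srRNA", lambda f: f.name == "srRNA"),
        PartitionSpec("CR", lambda f: f.gene_class == "CR"),
    ]
    return specs


def composition_table(genome: str, table: FeatureTable) -> "pd.DataFrame":
    """Composition-table rows for all standard partitions, report-rounded."""
    import pandas as pd

    rows = []
    for spec in standard_partitions():
        try:
            profile = partition_composition(genome, table, spec)
        except SequenceError:
            continue  # partial genome: skip empty partitions
        rows.append({"partition": spec.name, **profile.as_row()})
    return pd.DataFrame(rows)


def sliding_gc(seq: str, window: int = 200, step: int = 50) -> list[tuple[int, float]]:
    """(window-start 1-based, GC fraction) pairs across the sequence."""
    s = str(seq).upper().replace("U", "T")
    out = []
    for i in range(0, max(len(s) - window + 1, 1), step):
        win = s[i : i + window]
        acgt = sum(win.count(b) for b in "ACGT")
        if acgt:
            out.append((i + 1, (win.count("G") + win.count("C")) / acgt))
    return out


def reverse_complement(seq: str) -> str:
    return str(Seq(str(seq)).reverse_complement())
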