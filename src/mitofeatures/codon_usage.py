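"""Codon extraction, start/stop classification and RSCU.

Relative synonymous codon usage (RSCU) of codon *c* in a synonymous family
of size *k* with counts N:

    RSCU(c) = N(c) * k / sum(N over the family)

Values are computed under the invertebrate mitochondrial code (translation
table 5: AGA/AGG = Ser, UGA = Trp, AUA = Met), which makes serine an
8-codon family (UCN + AGN) and leucine a 6-codon family (UUR + CUN); the
two complete stop codons UAA/UAG form their own 2-codon family. A config
switch splits the UCN and AGN serine families for cross-tool comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable

from .annotation import FeatureTable, GeneFeature
from .genes import J

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]

#: codon (DNA alphabet) -> single-letter amino acid, '*' for stops.
CODON_TO_AA: dict[str, str] = {
    **_TABLE5.forward_table,
    **{stop: "*" for stop in _TABLE5.stop_codons},
}

START_CLASSES = ("ATN-standard", "GTG-alternative", "TTG-alternative", "other")
STOP_CLASSES = ("TAA", "TAG", "incomplete-T", "incomplete-TA", "other")


class CodonError(ValueError):
    pass


def synonymous_families(split_serine: bool = False) -> dict[str, list[str]]:
    """Family label -> member codons (DNA alphabet).

    Default grouping is by translation-table-5 amino acid (8-fold Ser).
    ``split_serine=True`` separates the TCN and AGN serine boxes (labels
    'S-TCN' and 'S-AGN').
    """
    fams: dict[str, list[str]] = {}
    for codon, aa in sorted(CODON_TO_AA.items()):
        label = aa
        if split_serine and aa == "S":
            label = "S-AGN" if codon.startswith("AG") else "S-TCN"
        fams.setdefault(label, []).append(codon)
    return fams


def extract_codons(genome: str, feature: GeneFeature) -> tuple[list[str], str]:
    """Codons of a protein-coding gene in gene sense, plus the remainder.

    Returns (codons, remainder) where remainder is the trailing 0-2 nt
    incomplete stop fragment ('T' or 'TA' for truncated stops).
    """
    if feature.gene_class != "PCG":
        raise CodonError(f"{feature.name} is not a protein-coding gene")
    if feature.size < 6:
        raise CodonError(f"{feature.name}: {feature.size} nt is too short for a CDS")
    seq = feature.sequence(genome, gene_sense=True)
    whole = 3 * (len(seq) // 3)
    codons = [seq[i : i + 3] for i in range(0, whole, 3)]
    return codons, seq[whole:]


def classify_start(codon: str) -> str:
    """Start-codon class: ATN-standard, GTG/TTG alternative, or other."""
    c = _norm_fragment(codon)
    if len(c) == 3 and c.startswith("AT"):
        return "ATN-standard"
    if c == "GTG":
        return "GTG-alternative"
    if c == "TTG":
        return "TTG-alternative"
    return "other"


def classify_stop(codon_or_fragment: str) -> str:
    """Stop class: TAA, TAG, incomplete-T, incomplete-TA, or other."""
    c = _norm_fragment(codon_or_fragment)
    if c in ("TAA", "TAG"):
        return c
    if c == "T":
        return "incomplete-T"
    if c == "TA":
        return "incomplete-TA"
    return "other"


def _norm_fragment(codon: str) -> str:
    c = str(codon).strip().upper().replace("U", "T").rstrip("-")
    if not (1 <= len(c) <= 3):
        raise CodonError(f"codon/fragment must be 1-3 nt, got {codon!r}")
    return c


@dataclass(frozen=True)
class CodonRecord:
    codon: str  # DNA alphabet
    amino_acid: str
    n: int = 0
    n_j: int = 0
    n_n: int = 0
    rscu: float | None = None
    rscu_j: float | None = None
    rscu_n: float | None = None

    def __post_init__(self) -> None:
        if self.n != self.n_j + self.n_n:
            raise CodonError(
                f"{self.codon}: total {self.n} != J {self.n_j} + N {self.n_n}"
            )


@dataclass
class CodonUsageTable:
    """Per-codon counts (total / J-strand / N-strand) with RSCU columns."""

    records: dict[str, CodonRecord]
    skipped_ambiguous: int = 0
    split_serine: bool = False

    def to_dataframe(self, rna: bool = True) -> pd.DataFrame:
        fams = synonymous_families(self.split_serine)
        rows = []
        for label, codons in fams.items():
            for codon in codons:
                r = self.records[codon]
                rows.append(
                    {
                        "amino_acid": r.amino_acid,
                        "codon": codon.replace("T", "U") if rna else codon,
                        "n": r.n,
                        "rscu": r.rscu,
                        "n_j": r.n_j,
                        "rscu_j": r.rscu_j,
                        "n_n": r.n_n,
                        "rscu_n": r.rscu_n,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StartStopRecord:
    gene: str
    start_codon: str
    start_class: str
    stop_codon: str
    stop_class: str


def start_stop_report(genome: str, table: FeatureTable) -> list[StartStopRecord]:
    """Literal start/stop codons of every protein-coding gene, classified."""
    out = []
    for f in table.pcgs:
        codons, remainder = extract_codons(genome, f)
        start = codons[0]
        stop = remainder if remainder else codons[-1]
        out.append(
            StartStopRecord(
                gene=f.name,
                start_codon=start,
                start_class=classify_start(start),
                stop_codon=stop if len(stop) == 3 else stop + "-",
                stop_class=classify_stop(stop),
            )
        )
    return out


def count_codons(
    genome: str, table: FeatureTable, split_serine: bool = False
) -> CodonUsageTable:
    """Count every complete codon of every protein-coding gene.

    Complete stop codons are counted (they form the stop family); incomplete
    trailing fragments are not. Codons containing an ambiguous base are
    excluded and tallied in ``skipped_ambiguous``. J/N tallies follow the
    feature's strand.
    """
    if not table.pcgs:
        raise CodonError("no protein-coding genes in table")
    counts: dict[str, list[int]] = {c: [0, 0] for c in CODON_TO_AA}
    skipped = 0
    for f in table.pcgs:
        codons, _ = extract_codons(genome, f)
        strand_idx = 0 if f.direction == J else 1
        for codon in codons:
            if codon in counts:
                counts[codon][strand_idx] += 1
            else:
                skipped += 1
    records = {
        c: CodonRecord(
            codon=c, amino_acid=CODON_TO_AA[c], n=nj + nn, n_j=nj, n_n=nn
        )
        for c, (nj, nn) in counts.items()
    }
    usage = CodonUsageTable(
        records=records, skipped_ambiguous=skipped, split_serine=split_serine
    )
    return compute_rscu(usage)


def rscu_from_counts(
    counts: dict[str, int], split_serine: bool = False
) -> dict[str, float | None]:
    """RSCU per codon from a bare codon->count mapping (T or U alphabet).

    A family whose total count is zero yields None for all its members.
    """
    dna = {c.upper().replace("U", "T"): n for c, n in counts.items()}
    unknown = set(dna) - set(CODON_TO_AA)
    if unknown:
        raise CodonError(f"unknown codons: {sorted(unknown)}")
    out: dict[str, float | None] = {}
    for codons in synonymous_families(split_serine).values():
        total = sum(dna.get(c, 0) for c in codons)
        size = len(codons)
        for c in codons:
            if c in dna:
                out[c] = None if total == 0 else dna[c] * size / total
    return out


def compute_rscu(usage: CodonUsageTable) -> CodonUsageTable:
    """Fill the rscu / rscu_j / rscu_n columns of a usage table."""
    new = dict(usage.records)
    for codons in synonymous_families(usage.split_serine).values():
        size = len(codons)
        totals = {
            col: sum(getattr(usage.records[c], col) for c in codons)
            for col in ("n", "n_j", "n_n")
        }

        def _r(value: int, col: str) -> float | None:
            return None if totals[col] == 0 else value * size / totals[col]

        for c in codons:
            r = usage.records[c]
            new[c] = CodonRecord(
                codon=r.codon, amino_acid=r.amino_acid,
                n=r.n, n_j=r.n_j, n_n=r.n_n,
                rscu=_r(r.n, "n"), rscu_j=_r(r.n_j, "n_j"), rscu_n=_r(r.n_n, "n_n"),
            )
    return CodonUsageTable(
        records=new, skipped_ambiguous=usage.skipped_ambiguous,
        split_serine=usage.split_serine,
    )


def format_rscu(value: float | None) -> str:
    """Report formatting: 2 decimals with trailing zeros trimmed ('2.6', '1')."""
    if value is None:
        return ""
    text = f"{value:.2f}".rstrip("0").rstrip(".")
    return text if text else "0"
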