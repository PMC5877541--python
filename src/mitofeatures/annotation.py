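"""Feature-table model and coordinate arithmetic for annotated mitogenomes.

The central object is a :class:`FeatureTable`: an ordered list of named,
stranded, 1-based inclusive intervals (the layout of a published mitogenome
organization table), with optional anticodon spans and start/stop codons.
All downstream statistics (junction ledger, genome length, gene-order
comparison, bicistron motifs) are pure arithmetic on this table plus, where
needed, the genome sequence.

Coordinates are 1-based inclusive throughout; use :meth:`GeneFeature.slice`
for the 0-based half-open Python view at I/O boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .genes import (
    ANCESTRAL_INSECT_ORDER,
    CONTROL_REGION,
    GeneNameError,
    J,
    N,
    gene_class,
    normalize_gene_name,
)

TRNA_MIN_LEN = 60
TRNA_MAX_LEN = 80

#: 7-mer consensus shared by the ATP8/ATP6 and ND4L/ND4 overlap junctions.
BICISTRON_PATTERN = re.compile(r"ATG[ACGT]TAA")


class FeatureTableError(ValueError):
    """Validation failure in a feature table."""


class FeatureParseError(FeatureTableError):
    """Malformed feature-table file; message names the offending row."""


@dataclass(frozen=True)
class GeneFeature:
    """A named, stranded, 1-based inclusive genomic interval."""

    name: str
    direction: str | None  # J, N, or None (control region)
    start: int
    end: int
    anticodon: str | None = None
    anticodon_start: int | None = None
    anticodon_end: int | None = None
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise FeatureTableError(f"{self.name}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise FeatureTableError(
                f"{self.name}: end ({self.end}) < start ({self.start})"
            )
        if self.direction not in (J, N, None):
            raise FeatureTableError(
                f"{self.name}: direction must be J or N, got {self.direction!r}"
            )
        if self.anticodon_start is not None and self.anticodon_end is not None:
            if not (self.start <= self.anticodon_start <= self.anticodon_end <= self.end):
                raise FeatureTableError(
                    f"{self.name}: anticodon span outside feature interval"
                )
        if self.gene_class == "tRNA" and not (
            TRNA_MIN_LEN <= self.size <= TRNA_MAX_LEN
        ):
            raise FeatureTableError(
                f"{self.name}: tRNA length {self.size} outside "
                f"[{TRNA_MIN_LEN}, {TRNA_MAX_LEN}]"
            )

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def gene_class(self) -> str:
        return gene_class(self.name)

    @property
    def slice(self) -> slice:
        """0-based half-open slice of this feature on the plus strand."""
        return slice(self.start - 1, self.end)

    def sequence(self, genome: str, gene_sense: bool = True) -> str:
        """Subsequence of ``genome`` for this feature.

        With ``gene_sense=True`` (default), N-strand features are returned
        reverse-complemented, i.e. as read by the transcription machinery.
        """
        sub = str(genome)[self.slice].upper().replace("U", "T")
        if gene_sense and self.direction == N:
            sub = str(Seq(sub).reverse_complement())
        return sub


@dataclass
class FeatureTable:
    """Ordered feature list for one mitogenome annotation."""

    features: list[GeneFeature]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.features:
            raise FeatureTableError("feature table is empty")
        starts = [f.start for f in self.features]
        if starts != sorted(starts):
            raise FeatureTableError(
                "features are not sorted by start coordinate; sort the table first"
            )
        seen: dict[str, int] = {}
        for f in self.features:
            seen[f.name] = seen.get(f.name, 0) + 1
        dups = [n for n, c in seen.items() if c > 1]
        if dups:
            raise FeatureTableError(f"duplicate gene names: {dups}")
        if seen.get(CONTROL_REGION, 0) > 1:
            raise FeatureTableError("more than one control region feature")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, name: str) -> GeneFeature:
        canon = normalize_gene_name(name)
        for f in self.features:
            if f.name == canon:
                return f
        raise KeyError(canon)

    def of_class(self, cls: str) -> list[GeneFeature]:
        return [f for f in self.features if f.gene_class == cls]

    @property
    def pcgs(self) -> list[GeneFeature]:
        return self.of_class("PCG")

    @property
    def trnas(self) -> list[GeneFeature]:
        return self.of_class("tRNA")

    @property
    def rrnas(self) -> list[GeneFeature]:
        return self.of_class("rRNA")

    def validate_complete(self) -> None:
        """Require the full 37-gene + control-region complement."""
        names = {f.name for f in self.features}
        expected = {name for name, _ in ANCESTRAL_INSECT_ORDER}
        missing = sorted(expected - names)
        if missing:
            raise FeatureTableError(f"incomplete mitogenome, missing: {missing}")

    def gene_order(self) -> list[tuple[str, str | None]]:
        return [(f.name, f.direction) for f in self.features]


def _parse_coord(value, column: str, row_label: str) -> int | None:
    """Parse a 1-based coordinate, tolerating thousands separators."""
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    text = str(value).strip().replace(",", "")
    if not re.fullmatch(r"\d+", text):
        raise FeatureParseError(
            f"row {row_label!r}: malformed {column} coordinate {value!r}"
        )
    coord = int(text)
    if coord < 1:
        raise FeatureParseError(f"row {row_label!r}: {column} must be positive")
    return coord


_DIRECTION_MAP = {"f": J, "forward": J, "j": J, "+": J,
                  "r": N, "reverse": N, "n": N, "-": N}


def parse_feature_table(path: str | Path, complete: bool = False) -> FeatureTable:
    """Read a TSV feature table into a validated :class:`FeatureTable`.

    Expected columns: gene, direction (F/R), start, end, and optionally
    anticodon, anticodon_start, anticodon_end, start_codon, stop_codon.
    Extra columns are ignored. With ``complete=True`` the full 37-gene +
    CR complement is enforced.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene", "direction", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FeatureParseError(f"{path.name}: missing columns {sorted(missing)}")

    features: list[GeneFeature] = []
    for _, row in df.iterrows():
        label = row["gene"]
        try:
            name = normalize_gene_name(label)
        except GeneNameError as exc:
            raise FeatureParseError(f"row {label!r}: {exc}") from exc
        direction_raw = row["direction"].strip().lower()
        if direction_raw in _DIRECTION_MAP:
            direction = _DIRECTION_MAP[direction_raw]
        elif direction_raw == "" and name == CONTROL_REGION:
            direction = None
        else:
            raise FeatureParseError(
                f"row {label!r}: unrecognized direction {row['direction']!r}"
            )
        start = _parse_coord(row["start"], "start", label)
        end = _parse_coord(row["end"], "end", label)
        if start is None or end is None:
            raise FeatureParseError(f"row {label!r}: start/end required")

        def _opt(col: str) -> str | None:
            val = row.get(col, "")
            return val.strip() or None if isinstance(val, str) else None

        features.append(
            GeneFeature(
                name=name,
                direction=direction,
                start=start,
                end=end,
                anticodon=_opt("anticodon"),
                anticodon_start=_parse_coord(row.get("anticodon_start", ""), "anticodon_start", label),
                anticodon_end=_parse_coord(row.get("anticodon_end", ""), "anticodon_end", label),
                start_codon=_opt("start_codon"),
                stop_codon=_opt("stop_codon"),
            )
        )
    table = FeatureTable(features=features, source=path.name)
    if complete:
        table.validate_complete()
    return table


_GENBANK_KEYS = {"gene", "CDS", "tRNA", "rRNA", "misc_feature", "D-loop"}


def read_genbank_features(path: str | Path) -> FeatureTable:
    """Build a :class:`FeatureTable` from a GenBank flat file.

    Only gene/CDS/tRNA/rRNA/misc_feature/D-loop keys are considered; a CDS,
    tRNA or rRNA feature takes precedence over the bare ``gene`` record for
    the same locus.
    """
    record = SeqIO.read(str(path), "genbank")
    features: dict[str, GeneFeature] = {}
    for feat in record.features:
        if feat.type not in _GENBANK_KEYS:
            continue
        quals = feat.qualifiers
        label = (quals.get("gene") or quals.get("product") or quals.get("note") or [""])[0]
        if feat.type in ("misc_feature", "D-loop") and not label:
            label = "CR"
        try:
            name = normalize_gene_name(label)
        except GeneNameError:
            continue
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        direction = None if name == CONTROL_REGION else (J if feat.location.strand != -1 else N)
        prefer = feat.type != "gene"
        if name not in features or prefer:
            features[name] = GeneFeature(name=name, direction=direction, start=start, end=end)
    ordered = sorted(features.values(), key=lambda f: f.start)
    return FeatureTable(features=ordered, source=Path(path).name)


@dataclass(frozen=True)
class JunctionRecord:
    """Gap between two consecutive features.

    ``gap`` > 0 is an intergenic spacer, < 0 an overlap, 0 abutting.
    For the circular wrap-around junction (last feature back to the first)
    ``circular`` is True.
    """

    upstream: str
    downstream: str
    gap: int
    circular: bool = False


@dataclass(frozen=True)
class JunctionSummary:
    """Spacer/overlap totals over the non-circular junctions."""

    spacer_count: int
    spacer_total: int
    spacer_max: int
    overlap_count: int
    overlap_total: int
    overlap_max: int
    notes: tuple[str, ...] = ()


def junction_ledger(
    table: FeatureTable, include_circular: bool = True
) -> list[JunctionRecord]:
    """Per-junction gaps over consecutive table rows, in genomic order.

    gap = start(downstream) - end(upstream) - 1. The circular junction from
    the last feature back to the first (through the origin of the circle,
    at the genome length implied by the table) is appended last, flagged
    ``circular``, when ``include_circular`` is set.
    """
    feats = table.features
    records = [
        JunctionRecord(a.name, b.name, b.start - a.end - 1)
        for a, b in zip(feats, feats[1:])
    ]
    if include_circular and len(feats) > 1:
        length = genome_length(table)
        wrap = (length - feats[-1].end) + (feats[0].start - 1)
        records.append(
            JunctionRecord(feats[-1].name, feats[0].name, wrap, circular=True)
        )
    return records


def summarize_junctions(records: Sequence[JunctionRecord]) -> JunctionSummary:
    """Spacer/overlap census excluding the circular junction."""
    linear = [r for r in records if not r.circular]
    spacers = [r.gap for r in linear if r.gap > 0]
    overlaps = [-r.gap for r in linear if r.gap < 0]
    notes = []
    for r in linear:
        if r.gap > 0 and r.gap == max(spacers, default=0) and r.downstream == "ND1":
            notes.append(
                "longest spacer lies between tRNA-Ser(UCN) and ND1 by coordinates; "
                "descriptions sometimes attribute it to the ND1/tRNA-Leu(CUN) junction"
            )
    return JunctionSummary(
        spacer_count=len(spacers),
        spacer_total=sum(spacers),
        spacer_max=max(spacers, default=0),
        overlap_count=len(overlaps),
        overlap_total=sum(overlaps),
        overlap_max=max(overlaps, default=0),
        notes=tuple(notes),
    )


def genome_length(table: FeatureTable) -> int:
    """Genome length implied by the table: the maximum end coordinate."""
    return max(f.end for f in table.features)


@dataclass(frozen=True)
class OrderComparison:
    """Positional comparison of a gene order against a reference order."""

    identical: bool
    mismatches: tuple[int, ...]  # 0-based positions differing in name or strand
    shared_junctions: int
    missing_from_reference: tuple[str, ...]
    extra_in_reference: tuple[str, ...]


def compare_gene_order(
    table: FeatureTable,
    reference: Sequence[tuple[str, str | None]] = ANCESTRAL_INSECT_ORDER,
) -> OrderComparison:
    """Compare the table's (name, strand) order to a reference arrangement.

    Both order and strand must agree position-by-position for ``identical``.
    Genes absent from the reference (or vice versa) are listed, never
    silently dropped.
    """
    order = table.gene_order()
    ref = [(normalize_gene_name(n), s) for n, s in reference]
    ref_names = {n for n, _ in ref}
    obs_names = {n for n, _ in order}
    missing = tuple(sorted(obs_names - ref_names))
    extra = tuple(sorted(ref_names - obs_names))
    mismatches = tuple(
        i
        for i, (a, b) in enumerate(zip(order, ref))
        if a != b
    )
    length_differs = len(order) != len(ref)
    adjacency = {(a, b) for a, b in zip(order, order[1:])}
    ref_adjacency = {(a, b) for a, b in zip(ref, ref[1:])}
    return OrderComparison(
        identical=not mismatches and not length_differs,
        mismatches=mismatches,
        shared_junctions=len(adjacency & ref_adjacency),
        missing_from_reference=missing,
        extra_in_reference=extra,
    )


@dataclass(frozen=True)
class BicistronCheck:
    """Result of the 7-nt ATGNTAA overlap-junction motif check."""

    upstream: str
    downstream: str
    overlap: int
    motif: str | None
    matches: bool
    canonical_overlap: bool  # True iff overlap is exactly 7 nt, same strand


def check_bicistron_motif(
    genome: str, table: FeatureTable, pair: tuple[str, str]
) -> BicistronCheck:
    """Check an overlapping gene pair for the ATGNTAA bicistron motif.

    The two genes must overlap by exactly 7 nt on the same strand for the
    canonical check; the 7-mer is read in the genes' sense orientation.
    A non-7-nt overlap is reported (``canonical_overlap=False``), not raised.
    """
    a, b = (table[pair[0]], table[pair[1]])
    up, down = (a, b) if a.start <= b.start else (b, a)
    ov_start = max(up.start, down.start)
    ov_end = min(up.end, down.end)
    overlap = ov_end - ov_start + 1
    same_strand = a.direction == b.direction and a.direction is not None
    if overlap != 7 or not same_strand:
        return BicistronCheck(
            upstream=up.name, downstream=down.name,
            overlap=max(overlap, 0) if overlap > 0 else overlap,
            motif=None, matches=False, canonical_overlap=False,
        )
    motif = str(genome)[ov_start - 1 : ov_end].upper().replace("U", "T")
    if a.direction == N:
        motif = str(Seq(motif).reverse_complement())
    return BicistronCheck(
        upstream=up.name, downstream=down.name, overlap=overlap,
        motif=motif, matches=bool(BICISTRON_PATTERN.fullmatch(motif)),
        canonical_overlap=True,
    )
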