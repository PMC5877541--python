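"""Constrained cloverleaf folding of mitochondrial tRNA genes.

Metazoan mitochondrial tRNAs keep a rigid core geometry: a 7-bp acceptor
(AA) stem, a 5-bp anticodon (AC) stem around a 7-nt AC loop with the
anticodon at loop positions 3-5, and more variable dihydrouridine (DHU)
and TPsiC arms whose stems range from 3 to 5 bp; the DHU stem can be lost
entirely (the classic tRNA-Ser(AGN) case). Rather than free-energy
minimization, the fold here is a deterministic constrained search: the AC
arm is anchored by the annotated anticodon, the AA stem by the sequence
ends, and the DHU/TPsiC geometries are enumerated within bounds; the
structure maximizing (Watson-Crick pairs, then G-U wobble pairs, then
fewest mismatches) wins, with a documented deterministic tie-break.

Pairs are classified as Watson-Crick (A-U, U-A, G-C, C-G), G-U wobble, or
mismatch; T and U are interchangeable on input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

AA_STEM_LEN = 7
AC_STEM_LEN = 5
AC_LOOP_LEN = 7
MIN_TRNA_LEN = 60
MAX_TRNA_LEN = 80

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


def classify_pair(x: str, y: str) -> str:
    """'WC', 'GU' or 'mismatch' for a proposed base pair (U folded to T)."""
    p = (x.upper().replace("U", "T"), y.upper().replace("U", "T"))
    if p in _WC:
        return "WC"
    if p in _WOBBLE:
        return "GU"
    return "mismatch"


@dataclass(frozen=True)
class ArmGeometry:
    """Realized cloverleaf geometry (lengths, 5'->3')."""

    c1: int          # connector, acceptor stem -> DHU arm
    dhu_stem: int    # 0 = DHU stem absent (region folds as a bare loop)
    dhu_loop: int
    c2: int          # connector, DHU arm -> AC stem
    var_loop: int    # variable loop between AC and TPsiC arms
    t_stem: int
    t_loop: int
    c3: int          # connector, TPsiC arm -> acceptor 3' side
    tail: int        # unpaired 3' tail beyond the acceptor stem


@dataclass(frozen=True)
class CloverleafStructure:
    """Four-arm cloverleaf: per-arm position pairs plus loop spans (1-based)."""

    length: int
    anticodon_span: tuple[int, int]
    acceptor_pairs: tuple[tuple[int, int], ...]
    dhu_pairs: tuple[tuple[int, int], ...]
    ac_pairs: tuple[tuple[int, int], ...]
    t_pairs: tuple[tuple[int, int], ...]
    dhu_loop: tuple[int, int] | None
    ac_loop: tuple[int, int]
    t_loop: tuple[int, int] | None
    var_loop: tuple[int, int] | None
    geometry: ArmGeometry
    score: tuple[int, int, int] = (0, 0, 0)  # (WC, GU, mismatches)

    @property
    def dhu_present(self) -> bool:
        return len(self.dhu_pairs) > 0

    def arms(self) -> dict[str, tuple[tuple[int, int], ...]]:
        return {
            "AA": self.acceptor_pairs,
            "DHU": self.dhu_pairs,
            "AC": self.ac_pairs,
            "TPSIC": self.t_pairs,
        }

    def all_pairs(self) -> list[tuple[int, int]]:
        return [p for arm in self.arms().values() for p in arm]

    def dot_bracket(self) -> str:
        marks = ["."] * self.length
        for i, j in self.all_pairs():
            marks[i - 1] = "("
            marks[j - 1] = ")"
        return "".join(marks)


@dataclass(frozen=True)
class FoldFailure:
    """Returned when no feasible cloverleaf anchoring exists."""

    reason: str
    length: int
    anticodon_offset: int


@dataclass(frozen=True)
class FoldConfig:
    """Enumeration bounds for the constrained search."""

    c1_range: tuple[int, int] = (0, 4)
    dhu_stem_range: tuple[int, int] = (3, 5)
    dhu_loop_range: tuple[int, int] = (3, 12)
    c2_range: tuple[int, int] = (0, 3)
    var_loop_range: tuple[int, int] = (2, 12)
    t_stem_range: tuple[int, int] = (3, 5)
    t_loop_range: tuple[int, int] = (3, 12)
    c3_range: tuple[int, int] = (0, 1)
    tail_range: tuple[int, int] = (0, 4)
    #: a DHU/TPsiC stem candidate is admissible only if it has at most this
    #: many non-canonical (non-WC, non-GU) pairs.
    max_stem_mismatch: int = 1


DEFAULT_FOLD_CONFIG = FoldConfig()


def _pair_counts(seq: str, pairs: list[tuple[int, int]]) -> tuple[int, int, int]:
    wc = gu = mm = 0
    for i, j in pairs:
        kind = classify_pair(seq[i - 1], seq[j - 1])
        if kind == "WC":
            wc += 1
        elif kind == "GU":
            gu += 1
        else:
            mm += 1
    return wc, gu, mm


def _span(start: int, length: int) -> tuple[int, int] | None:
    return (start, start + length - 1) if length > 0 else None


def _dhu_candidates(seq: str, r1: int, cfg: FoldConfig) -> Iterator[tuple]:
    """Yield (pairs, geometry fragment, counts) for the DHU region.

    The region runs from position 8 to 7 + r1. Always yields the stem-less
    candidate (whole region as a loop).
    """
    yield ((), (0, 0, r1, 0), (0, 0, 0))
    for c1 in range(cfg.c1_range[0], cfg.c1_range[1] + 1):
        for d in range(cfg.dhu_stem_range[0], cfg.dhu_stem_range[1] + 1):
            for c2 in range(cfg.c2_range[0], cfg.c2_range[1] + 1):
                ld = r1 - c1 - 2 * d - c2
                if not (cfg.dhu_loop_range[0] <= ld <= cfg.dhu_loop_range[1]):
                    continue
                s = 8 + c1
                pairs = tuple((s + i, s + 2 * d + ld - 1 - i) for i in range(d))
                wc, gu, mm = _pair_counts(seq, list(pairs))
                if mm > cfg.max_stem_mismatch:
                    continue
                yield (pairs, (c1, d, ld, c2), (wc, gu, mm))


def _t_candidates(seq: str, start: int, r2: int, cfg: FoldConfig) -> Iterator[tuple]:
    """Yield (pairs, geometry fragment, counts) for the TPsiC region."""
    yield ((), (r2, 0, 0, 0), (0, 0, 0))
    for v in range(cfg.var_loop_range[0], cfg.var_loop_range[1] + 1):
        for t in range(cfg.t_stem_range[0], cfg.t_stem_range[1] + 1):
            for c3 in range(cfg.c3_range[0], cfg.c3_range[1] + 1):
                lt = r2 - v - 2 * t - c3
                if not (cfg.t_loop_range[0] <= lt <= cfg.t_loop_range[1]):
                    continue
                u = start + v
                pairs = tuple((u + i, u + 2 * t + lt - 1 - i) for i in range(t))
                wc, gu, mm = _pair_counts(seq, list(pairs))
                if mm > cfg.max_stem_mismatch:
                    continue
                yield (pairs, (v, t, lt, c3), (wc, gu, mm))


def fold_cloverleaf(
    trna_seq: str,
    anticodon_offset: int,
    config: FoldConfig = DEFAULT_FOLD_CONFIG,
) -> CloverleafStructure | FoldFailure:
    """Fold a tRNA gene sequence into its constrained cloverleaf.

    ``anticodon_offset`` is the 1-based position of the anticodon's first
    base within the (gene-sense) sequence. Returns a
    :class:`CloverleafStructure`, or a :class:`FoldFailure` when the
    anticodon cannot anchor a feasible cloverleaf. Sequences outside the
    60-80 nt tRNA length band violate the precondition and raise.
    """
    seq = str(trna_seq).upper().replace("U", "T")
    L = len(seq)
    if not (MIN_TRNA_LEN <= L <= MAX_TRNA_LEN):
        raise ValueError(f"tRNA length {L} outside [{MIN_TRNA_LEN}, {MAX_TRNA_LEN}]")
    a = anticodon_offset
    if not (1 <= a <= L - 2):
        raise ValueError(f"anticodon offset {a} outside sequence of length {L}")

    r1 = a - 15  # DHU region length, between AA stem and AC stem 5' side
    if r1 < 0:
        return FoldFailure(
            reason=f"anticodon at {a} leaves no room for acceptor + AC stems (5')",
            length=L, anticodon_offset=a,
        )
    ac_pairs = tuple((a - 7 + i, a + 9 - i) for i in range(AC_STEM_LEN))
    best = None
    best_key = None
    cfg = config
    for tail in range(cfg.tail_range[0], cfg.tail_range[1] + 1):
        aa3_end = L - tail
        r2 = aa3_end - AA_STEM_LEN - (a + 10) + 1  # TPsiC region length
        if r2 < 0:
            continue
        aa_pairs = tuple((k + 1, aa3_end - k) for k in range(AA_STEM_LEN))
        if aa_pairs[-1][1] <= a + 9:
            continue  # acceptor 3' side would collide with the AC stem
        base_counts = _pair_counts(seq, list(aa_pairs) + list(ac_pairs))
        for d_pairs, (c1, d, ld, c2), d_counts in _dhu_candidates(seq, r1, cfg):
            for t_pairs, (v, t, lt, c3), t_counts in _t_candidates(
                seq, a + 10, r2, cfg
            ):
                wc = base_counts[0] + d_counts[0] + t_counts[0]
                gu = base_counts[1] + d_counts[1] + t_counts[1]
                mm = base_counts[2] + d_counts[2] + t_counts[2]
                dhu_start = 8 + c1 if d else 0
                key = (-wc, -gu, mm, c1, dhu_start, c2, v, c3, tail)
                if best_key is None or key < best_key:
                    best_key = key
                    geometry = ArmGeometry(
                        c1=c1 if d else 0, dhu_stem=d, dhu_loop=ld,
                        c2=c2 if d else 0, var_loop=v, t_stem=t, t_loop=lt,
                        c3=c3 if t else 0, tail=tail,
                    )
                    u = a + 10 + v
                    best = CloverleafStructure(
                        length=L,
                        anticodon_span=(a, a + 2),
                        acceptor_pairs=aa_pairs,
                        dhu_pairs=d_pairs,
                        ac_pairs=ac_pairs,
                        t_pairs=t_pairs,
                        dhu_loop=_span(8 + c1 + d, ld) if r1 > 0 else None,
                        ac_loop=(a - 2, a + 4),
                        t_loop=_span(u + t, lt) if t else None,
                        var_loop=_span(a + 10, v) if t and v else (
                            _span(a + 10, r2) if not t else None
                        ),
                        geometry=geometry,
                        score=(wc, gu, mm),
                    )
    if best is None:
        return FoldFailure(
            reason=f"anticodon at {a} leaves no room for acceptor + TPsiC arms (3')",
            length=L, anticodon_offset=a,
        )
    return best


@dataclass(frozen=True)
class PairCensus:
    """Per-arm classification of the proposed pairs of a structure."""

    wc: dict[str, int]
    gu: dict[str, int]
    mismatches: dict[str, tuple[tuple[str, str], ...]]

    @property
    def total_wc(self) -> int:
        return sum(self.wc.values())

    @property
    def total_gu(self) -> int:
        return sum(self.gu.values())

    @property
    def total_mismatch(self) -> int:
        return sum(len(v) for v in self.mismatches.values())

    @property
    def total_pairs(self) -> int:
        return self.total_wc + self.total_gu + self.total_mismatch


def pair_census(structure: CloverleafStructure, seq: str) -> PairCensus:
    """Classify every proposed pair of ``structure`` against ``seq``."""
    s = str(seq).upper().replace("U", "T")
    if structure.length != len(s):
        raise ValueError("structure length does not match sequence")
    wc: dict[str, int] = {}
    gu: dict[str, int] = {}
    mm: dict[str, list[tuple[str, str]]] = {}
    for arm, pairs in structure.arms().items():
        wc[arm] = gu[arm] = 0
        mm[arm] = []
        for i, j in pairs:
            kind = classify_pair(s[i - 1], s[j - 1])
            if kind == "WC":
                wc[arm] += 1
            elif kind == "GU":
                gu[arm] += 1
            else:
                mm[arm].append((s[i - 1].replace("T", "U"), s[j - 1].replace("T", "U")))
    return PairCensus(
        wc=wc, gu=gu, mismatches={k: tuple(v) for k, v in mm.items()}
    )


def pairwise_identity(aligned_a: str, aligned_b: str) -> float:
    """Percent identity of two pre-aligned sequences.

    Columns with a gap in either sequence count as non-matches; columns
    gapped in both are dropped from the denominator. U and T match.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError(
            f"aligned lengths differ: {len(aligned_a)} vs {len(aligned_b)}"
        )
    a = str(aligned_a).upper().replace("U", "T")
    b = str(aligned_b).upper().replace("U", "T")
    matches = columns = 0
    for x, y in zip(a, b):
        if x == "-" and y == "-":
            continue
        columns += 1
        if x == y and x != "-":
            matches += 1
    if columns == 0:
        raise ValueError("alignment has no non-gap columns")
    return 100.0 * matches / columns
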