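"""Structural annotation of the mitochondrial control region (A+T-rich region).

The control region of an insect mitogenome carries the replication /
transcription initiation elements. This module detects, with deterministic
combinatorial scans over the raw sequence:

* maximal single-base runs ("poly-N tracts", default >= 7 nt);
* tandem repeat arrays (a simplified self-alignment re-implementation of
  the Tandem Repeats Finder idea: distance-p self-matches, identity
  thresholding, binomial significance, consensus building);
* stem-loop hairpins (inverted repeats with G-U wobble allowed) plus their
  5' TATA and 3' G(A)nT flanking motifs;
* conserved sequence blocks (CSBs) across an alignment of control regions,
  using 100 / 75 / 50 % per-column identity tiers;
* the leading / repeat-array / remainder segmentation of the region.

All coordinates are 1-based inclusive and local to the control region;
an optional genome offset converts to genome-global positions.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .trna import classify_pair


@dataclass(frozen=True)
class PolyRun:
    """Maximal single-base run."""

    base: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def find_poly_runs(seq: str, min_len: int = 7) -> list[PolyRun]:
    """All maximal runs of one base with length >= ``min_len``, by position."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    s = str(seq).upper().replace("U", "T")
    runs = []
    for m in re.finditer(r"(A+|C+|G+|T+)", s):
        if m.end() - m.start() >= min_len:
            runs.append(PolyRun(base=m.group()[0], start=m.start() + 1, end=m.end()))
    return runs


@dataclass(frozen=True)
class TandemRepeat:
    """A tandem repeat array call.

    ``copy_number`` is fractional (6.9 means six complete copies plus a
    partial one); ``identity`` is the fraction of array positions matching
    the consensus unit.
    """

    start: int
    end: int
    period: int
    copy_number: float
    consensus: str
    identity: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def score(self) -> float:
        return self.length * self.identity


def _consensus_unit(s: str, start0: int, end0: int, period: int) -> str:
    """Column-majority consensus of the unit stack over s[start0:end0+1]."""
    cols: list[Counter] = [Counter() for _ in range(period)]
    for idx in range(start0, end0 + 1):
        cols[(idx - start0) % period][s[idx]] += 1
    out = []
    for col in cols:
        if col:
            # deterministic majority: count desc, then alphabetical
            out.append(sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))[0][0])
    return "".join(out)


def _array_identity(s: str, start0: int, end0: int, consensus: str) -> float:
    period = len(consensus)
    hits = sum(
        1 for idx in range(start0, end0 + 1) if s[idx] == consensus[(idx - start0) % period]
    )
    return hits / (end0 - start0 + 1)


def find_tandem_repeats(
    seq: str,
    min_period: int = 2,
    max_period: int = 200,
    min_copies: float = 2.0,
    min_identity: float = 0.8,
    min_zscore: float = 5.0,
) -> list[TandemRepeat]:
    """Detect tandem repeat arrays by distance-p self-matching.

    For each candidate period p, positions where ``seq[i] == seq[i+p]`` are
    segmented into runs whose match fraction stays >= ``min_identity``; a
    segment must also exceed a binomial z-score of ``min_zscore`` over the
    0.25 random-match background (this keeps short chance matches in random
    sequence from being called). Surviving candidates are reduced to their
    smallest sufficient period, boundary-refined against the consensus
    unit, and overlap-resolved by highest (aligned length x identity).
    """
    s = str(seq).upper().replace("U", "T")
    L = len(s)
    if L < 2 * min_period:
        return []
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    candidates: list[TandemRepeat] = []
    for p in range(min_period, min(max_period, L // 2) + 1):
        matches = arr[p:] == arr[:-p]
        for seg_start, seg_end in _match_segments(matches, min_identity, p):
            # array spans the matched comparisons plus one trailing unit
            start0, end0 = seg_start, seg_end + p
            n = seg_end - seg_start + 1
            k = int(matches[seg_start : seg_end + 1].sum())
            z = (k - 0.25 * n) / math.sqrt(n * 0.25 * 0.75)
            if z < min_zscore:
                continue
            period = _smallest_period(s, start0, end0, p, min_identity)
            cand = _refine(s, start0, end0, period)
            if cand is None:
                continue
            if cand.copy_number < min_copies or cand.identity < min_identity:
                continue
            candidates.append(cand)
    return _resolve_overlaps(candidates)


def _match_segments(
    matches: np.ndarray, min_identity: float, period: int
) -> list[tuple[int, int]]:
    """Greedy maximal segments of the match array with identity >= threshold.

    Extension runs through mismatches while the running identity holds and
    the current mismatch gap is shorter than one period.
    """
    segs = []
    n = len(matches)
    i = 0
    while i < n:
        if not matches[i]:
            i += 1
            continue
        good = 1
        best_end = i
        j = i + 1
        while j < n:
            if matches[j]:
                good += 1
                if good / (j - i + 1) >= min_identity:
                    best_end = j
            elif j - best_end > max(period, 3):
                break
            j += 1
        segs.append((i, best_end))
        i = best_end + 1
    return segs


def _smallest_period(
    s: str, start0: int, end0: int, p: int, min_identity: float
) -> int:
    for d in range(2, p):
        if p % d == 0:
            cons = _consensus_unit(s, start0, end0, d)
            if _array_identity(s, start0, end0, cons) >= min_identity:
                return d
    return p


#: per-base mismatch penalty for the core boundary search; a random flank
#: (25% chance match) then scores -1.25 per base in expectation and is cut,
#: while a 10%-mutated true array (+0.7 per base) keeps extending.
_BOUNDARY_MISMATCH_PENALTY = 2


def _refine(s: str, start0: int, end0: int, period: int) -> TandemRepeat | None:
    """Boundary-refine an array against its consensus and package the call.

    The greedy self-match segment can overrun the true array through chance
    matches (or start late when edge copies are mutated), so boundaries are
    re-derived in two steps: (1) the maximal-scoring subarray of the
    match-to-consensus profile (match +1, mismatch -penalty) over the
    segment widened by three periods per side; (2) an edge walk that
    extends through single mismatched bases only when the two bases beyond
    them still match their consensus phase, so one substitution inside the
    array's edge copy does not truncate the call, while a random flank
    (whose next two bases rarely both match) does not extend it.
    """
    anchor = start0
    cons = _consensus_unit(s, start0, end0, period)
    if len(cons) != period:
        return None

    def phase(idx: int) -> str:
        return cons[(idx - anchor) % period]

    lo = max(0, start0 - 3 * period)
    hi = min(len(s) - 1, end0 + 3 * period)
    best_sum = cur = 0
    best: tuple[int, int] | None = None
    cur_start = 0
    for i in range(lo, hi + 1):
        val = 1 if s[i] == phase(i) else -_BOUNDARY_MISMATCH_PENALTY
        if cur <= 0:
            cur = val
            cur_start = i
        else:
            cur += val
        if cur > best_sum:
            best_sum = cur
            best = (cur_start, i)
    if best is None:
        return None
    start0, end0 = best
    # Edge walk with single-mismatch rescue: a mismatched base is crossed
    # when at least two of the three bases beyond it continue the phase
    # (the walk then lands on the furthest of those matches), so one
    # substitution inside an edge copy does not truncate the call while a
    # random flank almost never extends it.
    while True:
        nxt = end0 + 1
        if nxt >= len(s):
            break
        if s[nxt] == phase(nxt):
            end0 = nxt
            continue
        ahead = [
            i for i in range(nxt + 1, min(nxt + 4, len(s)))
            if s[i] == phase(i)
        ]
        if len(ahead) >= 2:
            end0 = max(ahead)
        elif ahead == [nxt + 1]:
            # terminal rescue: a single substitution in the array's last
            # copy, with exactly one phase-continuing base beyond it
            end0 = nxt + 1
        else:
            break
    while True:
        prv = start0 - 1
        if prv < 0:
            break
        if s[prv] == phase(prv):
            start0 = prv
            continue
        behind = [
            i for i in range(max(prv - 3, 0), prv)
            if s[i] == phase(i)
        ]
        if len(behind) >= 2:
            start0 = min(behind)
        elif behind == [prv - 1]:
            start0 = prv - 1
        else:
            break
    shift = (start0 - anchor) % period  # re-anchor phase 0 at the new start
    cons = cons[shift:] + cons[:shift]
    identity = _array_identity(s, start0, end0, cons)
    length = end0 - start0 + 1
    return TandemRepeat(
        start=start0 + 1,
        end=end0 + 1,
        period=period,
        copy_number=round(length / period, 1),
        consensus=cons,
        identity=identity,
    )


def _resolve_overlaps(candidates: list[TandemRepeat]) -> list[TandemRepeat]:
    """Keep highest-scoring calls; drop a call only when it substantially
    overlaps (> 25% of the shorter call) an already accepted one, so
    distinct arrays that merely touch are both reported."""
    chosen: list[TandemRepeat] = []
    for cand in sorted(
        candidates, key=lambda r: (-r.score, r.period, r.start)
    ):
        ok = True
        for c in chosen:
            overlap = min(cand.end, c.end) - max(cand.start, c.start) + 1
            if overlap > 0.25 * min(cand.length, c.length):
                ok = False
                break
        if ok:
            chosen.append(cand)
    return sorted(chosen, key=lambda r: r.start)


@dataclass(frozen=True)
class MotifHit:
    present: bool
    start: int | None = None
    end: int | None = None


@dataclass(frozen=True)
class StemLoop:
    """A hairpin: 5' stem, loop, 3' stem, with flanking-motif annotations."""

    stem5: tuple[int, int]
    loop: tuple[int, int]
    stem3: tuple[int, int]
    wc: int
    gu: int
    mismatch: int
    tata_5prime: MotifHit = MotifHit(False)
    gant_3prime: MotifHit = MotifHit(False)

    @property
    def stem_len(self) -> int:
        return self.stem5[1] - self.stem5[0] + 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.stem5[0], self.stem3[1])

    @property
    def pair_score(self) -> int:
        return self.wc + self.gu

    def shifted(self, offset: int) -> "StemLoop":
        """Genome-global copy: add ``offset`` (0-based CR start) to spans."""

        def mv(span):
            return (span[0] + offset, span[1] + offset)

        def mv_hit(hit: MotifHit) -> MotifHit:
            if not hit.present:
                return hit
            return MotifHit(True, hit.start + offset, hit.end + offset)

        return StemLoop(
            stem5=mv(self.stem5), loop=mv(self.loop), stem3=mv(self.stem3),
            wc=self.wc, gu=self.gu, mismatch=self.mismatch,
            tata_5prime=mv_hit(self.tata_5prime),
            gant_3prime=mv_hit(self.gant_3prime),
        )


def find_stem_loops(
    seq: str,
    min_stem: int = 10,
    loop_range: tuple[int, int] = (3, 20),
    max_mismatch: int = 2,
    allow_gu: bool = True,
) -> list[StemLoop]:
    """Scan for hairpins (inverted repeats around a short loop).

    For every loop placement the stem is extended outward pair by pair
    within the mismatch budget (G-U counts as pairing when ``allow_gu``),
    then trimmed so both stem ends close on a canonical pair. Maximal
    non-nested hits are returned, overlap-resolved by pair score.
    """
    if min_stem < 4:
        raise ValueError("min_stem must be >= 4")
    s = str(seq).upper().replace("U", "T")
    L = len(s)
    lo, hi = loop_range
    raw: list[StemLoop] = []
    for loop_len in range(lo, hi + 1):
        for loop_start in range(1, L - loop_len + 2):  # 1-based loop start
            left = loop_start - 1  # last 5' stem position candidate
            right = loop_start + loop_len  # first 3' stem position candidate
            kinds = []
            i, j = left, right
            while i >= 1 and j <= L:
                kind = classify_pair(s[i - 1], s[j - 1])
                if kind == "GU" and not allow_gu:
                    kind = "mismatch"
                kinds.append(kind)
                if sum(1 for k in kinds if k == "mismatch") > max_mismatch:
                    kinds.pop()
                    break
                i -= 1
                j += 1
            # trim outer mismatches: stem must end on a canonical pair
            while kinds and kinds[-1] == "mismatch":
                kinds.pop()
            # trim inner mismatches into the loop likewise
            inner_trim = 0
            while kinds and kinds[0] == "mismatch":
                kinds.pop(0)
                inner_trim += 1
            stem = len(kinds)
            if stem < min_stem:
                continue
            l5_end = left - inner_trim
            r3_start = right + inner_trim
            raw.append(
                StemLoop(
                    stem5=(l5_end - stem + 1, l5_end),
                    loop=(l5_end + 1, r3_start - 1),
                    stem3=(r3_start, r3_start + stem - 1),
                    wc=sum(1 for k in kinds if k == "WC"),
                    gu=sum(1 for k in kinds if k == "GU"),
                    mismatch=sum(1 for k in kinds if k == "mismatch"),
                )
            )
    # deduplicate identical spans (found from multiple loop placements)
    unique: dict[tuple, StemLoop] = {}
    for sl in raw:
        key = (sl.stem5, sl.loop, sl.stem3)
        unique.setdefault(key, sl)
    chosen: list[StemLoop] = []
    for sl in sorted(
        unique.values(), key=lambda x: (-(x.pair_score), x.mismatch, x.span)
    ):
        if all(sl.span[1] < c.span[0] or sl.span[0] > c.span[1] for c in chosen):
            chosen.append(sl)
    return sorted(chosen, key=lambda x: x.span)


_GANT = re.compile(r"GA+T")


def detect_flanking_motifs(seq: str, sl: StemLoop, window: int = 20) -> StemLoop:
    """Annotate a stem-loop with its 5' TATA and 3' G(A)nT flanking motifs.

    Searches up to ``window`` nt upstream of the 5' stem for the literal
    TATA box and up to ``window`` nt downstream of the 3' stem for G(A)nT
    with n >= 1; the hit nearest the stem is recorded.
    """
    s = str(seq).upper().replace("U", "T")
    up_start0 = max(0, sl.stem5[0] - 1 - window)
    upstream = s[up_start0 : sl.stem5[0] - 1]
    tata = MotifHit(False)
    idx = upstream.rfind("TATA")
    if idx != -1:
        start = up_start0 + idx + 1
        tata = MotifHit(True, start, start + 3)
    down0 = sl.stem3[1]
    downstream = s[down0 : down0 + window]
    gant = MotifHit(False)
    m = _GANT.search(downstream)
    if m:
        gant = MotifHit(True, down0 + m.start() + 1, down0 + m.end())
    return replace(sl, tata_5prime=tata, gant_3prime=gant)


@dataclass(frozen=True)
class ConservedBlock:
    """A maximal run of alignment columns above an identity tier."""

    label: str
    start: int  # alignment columns, 1-based inclusive
    end: int
    mean_identity: float  # mean per-column identity, percent
    min_class: int  # the tier (100/75/50) every column meets

    @property
    def length(self) -> int:
        return self.end - self.start + 1


IDENTITY_TIERS = (100, 75, 50)


def column_identity(column: Sequence[str]) -> float:
    """Percent identity of one alignment column.

    Identity = highest base frequency over all rows; gap characters count
    in the denominator but never as the majority residue.
    """
    counts = Counter(ch.upper().replace("U", "T") for ch in column)
    best = max((n for ch, n in counts.items() if ch not in "-."), default=0)
    return 100.0 * best / len(column)


def find_csbs(
    aligned_crs: Sequence[str],
    min_len: int = 15,
    min_identity_class: int = 50,
) -> list[ConservedBlock]:
    """Call conserved sequence blocks from aligned control regions.

    Per-column identities are classed at the 100/75/50 tiers; maximal runs
    of columns meeting ``min_identity_class`` with length >= ``min_len``
    are reported as CSB1..n in coordinate order.
    """
    if len(aligned_crs) < 3:
        raise ValueError("need >= 3 aligned sequences")
    lengths = {len(s) for s in aligned_crs}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    if min_identity_class not in IDENTITY_TIERS:
        raise ValueError(f"min_identity_class must be one of {IDENTITY_TIERS}")
    n_cols = lengths.pop()
    idents = [
        column_identity([s[i] for s in aligned_crs]) for i in range(n_cols)
    ]
    passing = [ident >= min_identity_class for ident in idents]
    blocks: list[ConservedBlock] = []
    i = 0
    while i < n_cols:
        if not passing[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_cols and passing[j + 1]:
            j += 1
        if j - i + 1 >= min_len:
            run = idents[i : j + 1]
            blocks.append(
                ConservedBlock(
                    label=f"CSB{len(blocks) + 1}",
                    start=i + 1,
                    end=j + 1,
                    mean_identity=sum(run) / len(run),
                    min_class=min_identity_class,
                )
            )
        i = j + 1
    return blocks


@dataclass(frozen=True)
class ControlRegionSegmentation:
    """Leading / tandem-repeat-array / remainder partition of the CR."""

    leading: tuple[int, int] | None
    repeat_block: tuple[int, int] | None
    remainder: tuple[int, int] | None
    repeat: TandemRepeat | None


def segment_control_region(
    cr_seq: str, **repeat_kwargs
) -> ControlRegionSegmentation:
    """Segment the CR around its top-ranked tandem repeat array.

    With no repeat found, the whole region is the leading segment.
    """
    if not cr_seq:
        raise ValueError("empty control region")
    L = len(cr_seq)
    repeats = find_tandem_repeats(cr_seq, **repeat_kwargs)
    if not repeats:
        return ControlRegionSegmentation((1, L), None, None, None)
    top = max(repeats, key=lambda r: r.score)
    leading = (1, top.start - 1) if top.start > 1 else None
    remainder = (top.end + 1, L) if top.end < L else None
    return ControlRegionSegmentation(
        leading=leading, repeat_block=(top.start, top.end),
        remainder=remainder, repeat=top,
    )
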