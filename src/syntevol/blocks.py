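"""Pairwise conserved-block detection and CSR/CFS statistics.

The detector is an explicit seed–chain–extend–merge algorithm with the
dot-plot criteria as defaults: windows of 40 bp at >= 60% identity. Seeds are
shared exact k-mers (k = word_size / 2) on the forward strand; seeds on the
same diagonal are chained, chains are extended to the maximal run of
word_size windows meeting the identity threshold and trimmed back to exact
seed boundaries, nearby chains are merged, and short blocks are dropped.

Conservation statistics follow the printed arithmetic: the conserved sequence
ratio CSR = 100 * conserved_total / overlap_length (one decimal), and the
average conserved fragment size CFS = floor(conserved_total / n_blocks).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .regions import GenomicRegion


@dataclass(frozen=True)
class BlockParams:
    word_size: int = 40
    min_identity: float = 0.60
    merge_distance: int = 200
    min_block_length: int = 200
    max_kmer_occurrences: int = 16

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        if self.word_size < 8:
            raise ValueError("word_size must be >= 8")


@dataclass(frozen=True)
class ConservedBlock:
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    identity: float

    @property
    def length(self) -> int:
        """Mean of the two spans."""
        return ((self.a_end - self.a_start) + (self.b_end - self.b_start)) // 2


@dataclass(frozen=True)
class ConservationStats:
    overlap_length: int
    conserved_total: int
    n_blocks: int
    csr: float  # percent, rounded to 1 decimal
    cfs: int  # bp, floor(total / n)
    empty: bool = False  # flagged when no blocks were found


@dataclass(frozen=True)
class GapEvent:
    side: str  # "a" or "b"
    interval: tuple[int, int]
    cause: str  # TE_insertion | deletion | unknown_indel | low_complexity
    evidence: tuple[str, ...] = ()


def _encode_masked(seq: str, sentinel: int) -> np.ndarray:
    """Encode ACGT to 0..3; N (and anything else) to a sentinel code that can
    never match the other sequence's sentinel."""
    table = np.full(256, sentinel, dtype=np.uint8)
    for i, c in enumerate("ACGT"):
        table[ord(c)] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer (k <= 24, codes < 6) into an int64."""
    if len(arr) < k:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(len(arr) - k + 1, dtype=np.int64)
    for i in range(k):
        codes = codes * 6 + arr[i : len(arr) - k + 1 + i]
    return codes


def _diagonal_runs(
    a: np.ndarray,
    b: np.ndarray,
    diag: int,
    j_lo: int,
    j_hi: int,
    params: BlockParams,
    seed_js: list[int],
    k: int,
) -> list[tuple[int, int, float]]:
    """Maximal runs of word_size windows >= min_identity on one diagonal.

    Runs are trimmed back to the outermost exact seed boundaries so block
    edges do not overshoot into unrelated sequence. Returns (b_start, b_end,
    identity) triples; a-coordinates follow from the diagonal offset.
    """
    w = params.word_size
    lo = max(0, j_lo - params.merge_distance, -diag)
    hi = min(len(b), j_hi + params.merge_distance, len(a) - diag)
    if hi - lo < w:
        lo = max(0, min(lo, j_lo))
        hi = min(len(b), len(a) - diag, max(hi, j_hi))
        if hi <= lo:
            return []
        m = a[diag + lo : diag + hi] == b[lo:hi]
        ident = float(m.mean())
        if ident >= params.min_identity:
            return [(lo, hi, ident)]
        return []
    m = (a[diag + lo : diag + hi] == b[lo:hi]).astype(np.int32)
    csum = np.concatenate([[0], np.cumsum(m)])
    wsums = csum[w:] - csum[:-w]  # window starting at lo + t
    need = math.ceil(params.min_identity * w)
    ok = wsums >= need
    runs: list[tuple[int, int, float]] = []
    t = 0
    n = len(ok)
    seed_arr = np.asarray(seed_js)
    while t < n:
        if not ok[t]:
            t += 1
            continue
        t2 = t
        while t2 < n and ok[t2]:
            t2 += 1
        run_s, run_e = lo + t, lo + t2 - 1 + w  # b-coordinates, half-open
        # trim to the outermost exact seeds inside the run
        inside = seed_arr[(seed_arr >= run_s) & (seed_arr + k <= run_e)]
        if inside.size:
            s = int(inside.min())
            e = int(inside.max()) + k
            # extend each end to its maximum-scoring position within the
            # window run (match +1, mismatch -1), so isolated mismatches near
            # a block edge are recouped by the matches beyond them while the
            # boundary still lands on an exact match
            score = best = 0
            best_s = s
            for j in range(s - 1, run_s - 1, -1):
                score += 1 if a[diag + j] == b[j] else -1
                if score > best:
                    best, best_s = score, j
            s = best_s
            score = best = 0
            best_e = e
            for j in range(e, run_e):
                score += 1 if a[diag + j] == b[j] else -1
                if score > best:
                    best, best_e = score, j + 1
            e = best_e
            ident = float(m[s - lo : e - lo].mean())
            runs.append((s, e, ident))
        t = t2
    return runs


def find_conserved_blocks(
    a: GenomicRegion | str,
    b: GenomicRegion | str,
    params: BlockParams = BlockParams(),
) -> list[ConservedBlock]:
    """Detect forward-strand conserved blocks between two regions."""
    sa = a.residues if isinstance(a, GenomicRegion) else a
    sb = b.residues if isinstance(b, GenomicRegion) else b
    if not sa or not sb:
        raise ValueError("both regions must be non-empty")
    arr_a = _encode_masked(sa, 4)
    arr_b = _encode_masked(sb, 5)
    k = max(8, params.word_size // 2)

    codes_a = _kmer_codes(arr_a, k)
    codes_b = _kmer_codes(arr_b, k)
    order = np.argsort(codes_a, kind="stable")
    sorted_codes = codes_a[order]
    left = np.searchsorted(sorted_codes, codes_b, side="left")
    right = np.searchsorted(sorted_codes, codes_b, side="right")

    seeds_by_diag: dict[int, list[int]] = defaultdict(list)
    for j in range(len(codes_b)):
        lo, hi = left[j], right[j]
        if hi - lo == 0 or hi - lo > params.max_kmer_occurrences:
            continue
        for i in order[lo:hi]:
            seeds_by_diag[int(i) - j].append(j)

    raw: list[ConservedBlock] = []
    for diag, js in seeds_by_diag.items():
        js.sort()
        # split seed lists where consecutive seeds are far apart
        start = 0
        for idx in range(1, len(js) + 1):
            if idx == len(js) or js[idx] - js[idx - 1] > params.merge_distance:
                cluster = js[start:idx]
                start = idx
                for s, e, ident in _diagonal_runs(
                    arr_a, arr_b, diag, cluster[0], cluster[-1] + k, params, cluster, k
                ):
                    raw.append(
                        ConservedBlock(diag + s, diag + e, s, e, round(ident, 4))
                    )

    if not raw:
        return []
    raw.sort(key=lambda blk: (blk.a_start, blk.b_start))

    # merge blocks separated by less than merge_distance on both sequences
    merged: list[ConservedBlock] = []
    for blk in raw:
        if merged:
            prev = merged[-1]
            gap_a = blk.a_start - prev.a_end
            gap_b = blk.b_start - prev.b_end
            if -params.word_size <= gap_a <= params.merge_distance and \
               -params.word_size <= gap_b <= params.merge_distance:
                la, lb = prev.length, blk.length
                ident = (prev.identity * la + blk.identity * lb) / (la + lb)
                merged[-1] = ConservedBlock(
                    prev.a_start,
                    max(prev.a_end, blk.a_end),
                    prev.b_start,
                    max(prev.b_end, blk.b_end),
                    round(ident, 4),
                )
                continue
        merged.append(blk)

    # drop short blocks; resolve residual overlaps greedily by length, trimming
    # the shorter block's overhang (blocks are diagonal runs, so equal trims
    # apply to both coordinates) and dropping it only when fully covered
    merged = [blk for blk in merged if blk.length >= params.min_block_length]
    merged.sort(key=lambda blk: -blk.length)
    kept: list[ConservedBlock] = []
    for blk in merged:
        s_a, e_a, s_b, e_b = blk.a_start, blk.a_end, blk.b_start, blk.b_end
        trim_l = trim_r = 0
        dead = False
        for other in kept:
            for s, e, os_, oe in (
                (s_a, e_a, other.a_start, other.a_end),
                (s_b, e_b, other.b_start, other.b_end),
            ):
                if not _overlap(s, e, os_, oe):
                    continue
                if os_ <= s and oe >= e:
                    dead = True
                elif os_ <= s:
                    trim_l = max(trim_l, oe - s)
                elif oe >= e:
                    trim_r = max(trim_r, e - os_)
                else:  # kept block strictly inside the candidate on this axis
                    trim_r = max(trim_r, e - os_)
        if dead:
            continue
        s_a, s_b = s_a + trim_l, s_b + trim_l
        e_a, e_b = e_a - trim_r, e_b - trim_r
        if min(e_a - s_a, e_b - s_b) < params.min_block_length:
            continue
        if any(
            _overlap(s_a, e_a, o.a_start, o.a_end)
            or _overlap(s_b, e_b, o.b_start, o.b_end)
            for o in kept
        ):
            continue
        kept.append(ConservedBlock(s_a, e_a, s_b, e_b, blk.identity))
    kept.sort(key=lambda blk: blk.a_start)
    return kept


def _overlap(s1: int, e1: int, s2: int, e2: int) -> bool:
    return s1 < e2 and s2 < e1


def conservation_stats(
    blocks: list[ConservedBlock],
    overlap_length: int | None = None,
) -> ConservationStats:
    """CSR/CFS summary of a block set.

    ``overlap_length`` defaults to the mutually alignable interval: the span
    from the first to the last block anchor on each sequence, averaged. Pass
    an explicit value to reproduce printed table inputs.
    """
    conserved_total = sum(blk.length for blk in blocks)
    if overlap_length is None:
        if not blocks:
            raise ValueError("cannot infer overlap_length without blocks")
        span_a = max(blk.a_end for blk in blocks) - min(blk.a_start for blk in blocks)
        span_b = max(blk.b_end for blk in blocks) - min(blk.b_start for blk in blocks)
        overlap_length = (span_a + span_b) // 2
    if overlap_length <= 0:
        raise ValueError("overlap_length must be positive")
    n = len(blocks)
    if n == 0:
        return ConservationStats(overlap_length, 0, 0, 0.0, 0, empty=True)
    csr = round(100.0 * conserved_total / overlap_length, 1)
    cfs = conserved_total // n
    return ConservationStats(overlap_length, conserved_total, n, csr, cfs)


def stats_from_totals(conserved_total: int, n_blocks: int, overlap_length: int) -> ConservationStats:
    """CSR/CFS from pre-tabulated totals (e.g. printed table rows)."""
    if overlap_length <= 0:
        raise ValueError("overlap_length must be positive")
    if n_blocks == 0:
        return ConservationStats(overlap_length, conserved_total, 0, 0.0, 0, empty=True)
    csr = round(100.0 * conserved_total / overlap_length, 1)
    return ConservationStats(
        overlap_length, conserved_total, n_blocks, csr, conserved_total // n_blocks
    )


def _dinucleotide_entropy(seq: str) -> float:
    if len(seq) < 2:
        return 0.0
    counts: dict[str, int] = defaultdict(int)
    for i in range(len(seq) - 1):
        counts[seq[i : i + 2]] += 1
    total = len(seq) - 1
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def classify_gaps(
    blocks: list[ConservedBlock],
    a: GenomicRegion,
    b: GenomicRegion,
    outgroup: GenomicRegion | None = None,
    min_gap: int = 50,
    te_cover_fraction: float = 0.5,
    params: BlockParams = BlockParams(),
) -> list[GapEvent]:
    """Classify inter-block intervals present on exactly one side.

    A one-sided gap covered >= 50% by an annotated TE is a TE insertion on
    that side; a low-complexity gap is flagged as such; otherwise, if the gap
    sequence aligns to a supplied outgroup the event is a deletion on the
    *other* side; anything else is an unknown indel.
    """
    events: list[GapEvent] = []
    for prev, nxt in zip(blocks, blocks[1:]):
        gaps = {
            "a": (prev.a_end, nxt.a_start),
            "b": (prev.b_end, nxt.b_start),
        }
        lens = {s: max(0, e - st) for s, (st, e) in gaps.items()}
        for side in ("a", "b"):
            other = "b" if side == "a" else "a"
            if lens[side] < min_gap or lens[other] >= min_gap:
                continue
            start, end = gaps[side]
            region = a if side == "a" else b
            tes = [
                f
                for f in region.features_of_kind("TE")
                if f.start < end and start < f.end
            ]
            covered = sum(min(end, f.end) - max(start, f.start) for f in tes)
            if covered >= te_cover_fraction * (end - start):
                events.append(
                    GapEvent(side, (start, end), "TE_insertion",
                             tuple(f.name for f in tes))
                )
                continue
            segment = region.residues[start:end]
            if _dinucleotide_entropy(segment) < 1.5:
                events.append(GapEvent(side, (start, end), "low_complexity"))
                continue
            if outgroup is not None and len(segment) >= params.min_block_length:
                hits = find_conserved_blocks(segment, outgroup, params)
                aligned = sum(h.a_end - h.a_start for h in hits)
                if aligned >= 0.5 * len(segment):
                    events.append(
                        GapEvent(other, (gaps[other][0], gaps[other][0]),
                                 "deletion", (outgroup.id,))
                    )
                    continue
            events.append(GapEvent(side, (start, end), "unknown_indel"))
    return events
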