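"""Conserved non-coding sequences, cis-regulatory motifs and SSRs.

CNS detection pairwise-aligns the intergenic stretches between shared anchor
genes, slides a fixed window over the alignment columns (gap columns count as
mismatches, as in VISTA-style percent-identity plots), keeps maximal runs at
or above the identity threshold, intersects the runs across all region pairs,
and maps the surviving segments back to each region. Segments overlapping any
genic feature are discarded. The reported identity is the pairwise minimum
across all region pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .molevol import global_align
from .regions import GenomicRegion

GENIC_KINDS = ("gene", "exon", "CDS", "five_prime_UTR", "three_prime_UTR")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: default promoter-element table (PlantCARE-style consensi)
DEFAULT_MOTIF_TABLE: dict[str, str] = {
    "TATA-box": "TATAAA",
    "CAAT-box": "CCAAT",
    "GC-box": "GGGCGG",
    "G-box": "CACGTG",
    "P-box": "CCTTTTG",
    "Py-rich": "TTTCTTCTCT",
    "SP1": "CCGCCC",
    "MBS": "CAACTG",
}

#: minimum perfect copies per unit length for SSR reporting
DEFAULT_MIN_COPIES: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class CNSParams:
    window: int = 100
    min_identity: float = 0.80
    min_length: int = 100
    genic_mask_padding: int = 0

    def __post_init__(self) -> None:
        if self.window < 20:
            raise ValueError("window must be >= 20")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class CNSRecord:
    label: str
    intervals: dict[str, tuple[int, int]]  # region id -> (start, end)
    mean_identity: float
    min_identity: float

    @property
    def length(self) -> int:
        """Mean span across regions."""
        spans = [e - s for s, e in self.intervals.values()]
        return sum(spans) // len(spans)


@dataclass(frozen=True)
class MotifHit:
    name: str
    consensus: str
    position: int  # 0-based start on the forward strand
    strand: str


@dataclass(frozen=True)
class SSRRecord:
    unit: str  # lexicographically smallest rotation
    copies: int
    start: int
    end: int


# --------------------------------------------------------------------------
# CNS detection


def _anchor_genes(regions: list[GenomicRegion]) -> list[str]:
    """Names of genes present in every region, ordered along the first."""
    common: set[str] | None = None
    for r in regions:
        names = {f.name for f in r.features_of_kind("gene")}
        common = names if common is None else common & names
    if not common:
        raise ValueError(
            "regions share no anchor gene; supply anchor features named "
            "identically in every region"
        )
    first = regions[0]
    ordered = sorted(
        (f for f in first.features_of_kind("gene") if f.name in common),
        key=lambda f: f.start,
    )
    return [f.name for f in ordered]


def _stretches(region: GenomicRegion, anchors: list[str]) -> list[tuple[int, int]]:
    """Intergenic stretches delimited by the anchor genes, including the two
    flanks."""
    genes = {f.name: f for f in region.features_of_kind("gene")}
    bounds = [genes[a] for a in anchors]
    bounds.sort(key=lambda f: f.start)
    out = []
    prev = 0
    for g in bounds:
        if g.start > prev:
            out.append((prev, g.start))
        prev = g.end
    if prev < region.length:
        out.append((prev, region.length))
    return out


def _conserved_column_runs(
    match: list[bool], window: int, min_identity: float, min_length: int
) -> list[tuple[int, int]]:
    """Maximal runs of alignment columns covered by a passing window."""
    n = len(match)
    if n < window:
        return []
    need = min_identity * window
    csum = [0]
    for v in match:
        csum.append(csum[-1] + v)
    # a column is covered when any passing window contains it (difference array)
    delta = [0] * (n + 1)
    for t in range(n - window + 1):
        if csum[t + window] - csum[t] >= need:
            delta[t] += 1
            delta[t + window] -= 1
    runs: list[tuple[int, int]] = []
    depth = 0
    start = -1
    for c in range(n + 1):
        depth += delta[c] if c <= n else 0
        inside = depth > 0 and c < n
        if inside and start < 0:
            start = c
        elif not inside and start >= 0:
            if c - start >= min_length:
                runs.append((start, c))
            start = -1
    return runs


def _column_maps(aln) -> tuple[list[int], list[int]]:
    """Per alignment column: ungapped offset in seq_a / seq_b (position of
    the residue at or before the column)."""
    pa, pb = [], []
    ia = ib = 0
    for x, y in zip(aln.seq_a, aln.seq_b):
        pa.append(ia)
        pb.append(ib)
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return pa, pb


def _project_runs_to_ref(aln, runs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Alignment-column runs -> ungapped intervals on seq_a."""
    pa, _ = _column_maps(aln)
    out = []
    for s, e in runs:
        a_lo = pa[s] + (0 if aln.seq_a[s] != "-" else 1)
        a_hi = pa[e - 1] + (1 if aln.seq_a[e - 1] != "-" else 0)
        if a_hi > a_lo:
            out.append((a_lo, a_hi))
    return out


def _intersect_intervals(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    a, b = sorted(a), sorted(b)
    while i < len(a) and j < len(b):
        lo, hi = max(a[i][0], b[j][0]), min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _ref_interval_to_other(aln, lo: int, hi: int) -> tuple[int, int]:
    """Map an ungapped seq_a interval to the corresponding seq_b interval."""
    pa, pb = _column_maps(aln)
    cols = [c for c in range(len(pa)) if aln.seq_a[c] != "-" and lo <= pa[c] < hi]
    b_positions = [pb[c] for c in cols if aln.seq_b[c] != "-"]
    if not b_positions:
        return (0, 0)
    return (min(b_positions), max(b_positions) + 1)


def _alignment_identity(aln, cols: tuple[int, int]) -> float:
    s, e = cols
    n = e - s
    if n <= 0:
        return 0.0
    matches = sum(
        1
        for x, y in zip(aln.seq_a[s:e], aln.seq_b[s:e])
        if x == y and x != "-"
    )
    return matches / n


def find_cns(
    regions: list[GenomicRegion],
    params: CNSParams = CNSParams(),
) -> list[CNSRecord]:
    """Detect conserved non-coding segments shared by all supplied regions."""
    if len(regions) < 2:
        raise ValueError("need at least two regions")
    anchors = _anchor_genes(regions)
    ref = regions[0]
    stretch_sets = [_stretches(r, anchors) for r in regions]
    if any(len(s) != len(stretch_sets[0]) for s in stretch_sets):
        raise ValueError("anchor genes delimit different stretch counts per region")

    candidates: list[CNSRecord] = []
    for si in range(len(stretch_sets[0])):
        ref_lo, ref_hi = stretch_sets[0][si]
        ref_seq = ref.subsequence(ref_lo, ref_hi)
        if len(ref_seq) < params.min_length:
            continue
        alignments = []
        per_pair_runs: list[list[tuple[int, int]]] = []
        usable = True
        for rj in range(1, len(regions)):
            lo_j, hi_j = stretch_sets[rj][si]
            other_seq = regions[rj].subsequence(lo_j, hi_j)
            if len(other_seq) < params.min_length:
                usable = False
                break
            aln = global_align(ref_seq, other_seq)
            match = [
                x == y and x != "-" for x, y in zip(aln.seq_a, aln.seq_b)
            ]
            runs = _conserved_column_runs(
                match, params.window, params.min_identity, params.min_length
            )
            per_pair_runs.append(_project_runs_to_ref(aln, runs))
            alignments.append((aln, lo_j))
        if not usable:
            continue
        shared = per_pair_runs[0]
        for runs in per_pair_runs[1:]:
            shared = _intersect_intervals(shared, runs)
        for lo, hi in shared:
            if hi - lo < params.min_length:
                continue
            intervals = {ref.id: (ref_lo + lo, ref_lo + hi)}
            identities = []
            ok = True
            for rj, (aln, off_j) in enumerate(alignments, start=1):
                b_lo, b_hi = _ref_interval_to_other(aln, lo, hi)
                if b_hi - b_lo < params.min_length // 2:
                    ok = False
                    break
                intervals[regions[rj].id] = (off_j + b_lo, off_j + b_hi)
            if not ok:
                continue
            # identity over every region pair on the candidate segment
            seqs = {
                rid: regions[[r.id for r in regions].index(rid)].subsequence(s, e)
                for rid, (s, e) in intervals.items()
            }
            ids = list(seqs)
            for x in range(len(ids)):
                for y in range(x + 1, len(ids)):
                    sub = global_align(seqs[ids[x]], seqs[ids[y]])
                    identities.append(
                        _alignment_identity(sub, (0, sub.length))
                    )
            min_id = min(identities)
            if min_id < params.min_identity:
                continue
            candidates.append(
                CNSRecord(
                    label="",
                    intervals=intervals,
                    mean_identity=round(sum(identities) / len(identities), 4),
                    min_identity=round(min_id, 4),
                )
            )

    # mask: drop candidates overlapping genic features in any region
    kept: list[CNSRecord] = []
    pad = params.genic_mask_padding
    for rec in candidates:
        clash = False
        for r in regions:
            s, e = rec.intervals[r.id]
            for f in r.features_of_kind(*GENIC_KINDS):
                if s < f.end + pad and f.start - pad < e:
                    clash = True
                    break
            if clash:
                break
        if not clash:
            kept.append(rec)
    kept.sort(key=lambda rec: rec.intervals[regions[0].id][0])
    return [
        CNSRecord(f"CNS{i + 1}", rec.intervals, rec.mean_identity, rec.min_identity)
        for i, rec in enumerate(kept)
    ]


# --------------------------------------------------------------------------
# cis-regulatory element scan


def _iupac_regex(consensus: str) -> str:
    parts = []
    for ch in consensus.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r}")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _is_palindromic(consensus: str) -> bool:
    return consensus.upper() == reverse_complement(consensus.upper())


def scan_cis_elements(
    seq: str,
    motif_table: dict[str, str] | None = None,
) -> list[MotifHit]:
    """All exact IUPAC matches on both strands, sorted by position.

    Palindromic consensi are reported once per site, on the forward strand.
    """
    table = DEFAULT_MOTIF_TABLE if motif_table is None else motif_table
    seq = seq.upper()
    hits: list[MotifHit] = []
    for name, consensus in table.items():
        fwd = re.compile(f"(?=({_iupac_regex(consensus)}))")
        for m in fwd.finditer(seq):
            hits.append(MotifHit(name, consensus, m.start(), "+"))
        if _is_palindromic(consensus):
            continue
        rev = re.compile(f"(?=({_iupac_regex(reverse_complement(consensus))}))")
        for m in rev.finditer(seq):
            hits.append(MotifHit(name, consensus, m.start(), "-"))
    hits.sort(key=lambda h: (h.position, h.name, h.strand))
    return hits


# --------------------------------------------------------------------------
# SSR detection


def smallest_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    """True when the unit is not itself a tandem repeat of a shorter unit."""
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def find_ssrs(
    seq: str,
    min_copies: dict[int, int] | None = None,
) -> list[SSRRecord]:
    """Maximal perfect tandem repeats of 1-6 bp units.

    Runs are reported under the lexicographically smallest rotation of their
    unit; non-primitive units (a (CTCT)n run is a (CT)2n run) are suppressed.
    """
    thresholds = DEFAULT_MIN_COPIES if min_copies is None else min_copies
    seq = seq.upper()
    n = len(seq)
    records: list[SSRRecord] = []
    for u, min_c in sorted(thresholds.items()):
        i = 0
        while i + u <= n:
            unit = seq[i : i + u]
            if "N" in unit or not _is_primitive(unit):
                i += 1
                continue
            j = i + u
            while j < n and seq[j] == seq[j - u]:
                j += 1
            copies = (j - i) // u
            if copies >= min_c:
                records.append(
                    SSRRecord(smallest_rotation(unit), copies, i, i + copies * u)
                )
                i = i + copies * u  # skip past the reported run
            else:
                i += 1
    # suppress runs fully contained in a reported run of smaller unit
    records.sort(key=lambda r: (r.start, len(r.unit)))
    kept: list[SSRRecord] = []
    for rec in records:
        if any(
            k.start <= rec.start and rec.end <= k.end and len(k.unit) < len(rec.unit)
            for k in kept
        ):
            continue
        kept.append(rec)
    return kept
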