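"""Pairwise alignment and substitution-rate estimators.

Implements the Kimura two-parameter (K2P) nucleotide distance

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

where P and Q are the transition and transversion proportions over usable
(ungapped, non-N) columns, and the Nei–Gojobori (1986) counting method for
per-site synonymous (Ks) and nonsynonymous (Ka) substitution rates with
Jukes–Cantor correction. Site counting follows the classic convention:
changes to stop codons count as nonsynonymous when tallying site fractions,
and multi-hit codons average synonymous/nonsynonymous differences over all
substitution pathways that avoid stop codons, with equal weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
from Bio import Align
from Bio.Data import CodonTable
from Bio.Seq import Seq

_NUC = "ACGT"
_PURINES = {"A", "G"}
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)

CODON_TO_AA: dict[str, str] = {
    "".join(c): _STANDARD.forward_table.get("".join(c), "*")
    for c in product(_NUC, repeat=3)
}


class SaturationError(ValueError):
    """Raised when observed divergence exceeds the model's invertible range."""


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped sequences of equal length."""

    seq_a: str
    seq_b: str
    id_a: str = "a"
    id_b: str = "b"

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("gapped sequences must have equal length")
        if not any(
            x != "-" and y != "-" for x, y in zip(self.seq_a, self.seq_b)
        ):
            raise ValueError("alignment has no ungapped column")

    @property
    def length(self) -> int:
        return len(self.seq_a)

    def identity(self) -> float:
        """Fraction of ungapped non-N columns that match."""
        usable = matches = 0
        for x, y in zip(self.seq_a, self.seq_b):
            if x in _NUC and y in _NUC:
                usable += 1
                matches += x == y
        return matches / usable if usable else 0.0


@dataclass(frozen=True)
class DistanceEstimate:
    """K2P distance with its transition/transversion components."""

    P: float
    Q: float
    K: float
    n_sites: int


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free paired codon columns."""

    codons_a: tuple[str, ...]
    codons_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon sequences differ in length")
        for i, (ca, cb) in enumerate(zip(self.codons_a, self.codons_b)):
            if len(ca) != 3 or len(cb) != 3:
                raise ValueError(f"codon column {i} is not a triplet")
            if ca in STOP_CODONS or cb in STOP_CODONS:
                raise ValueError(f"internal stop codon at codon index {i}")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass(frozen=True)
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float
    omega: float | None  # None when Ks == 0 (undefined)


def global_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
    id_a: str = "a",
    id_b: str = "b",
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment with deterministic tie-breaking."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if max(len(a), len(b)) > 100_000:
        raise ValueError("sequences exceed the 100 kb desk-scale guard")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return PairwiseAlignment(seq_a=ga, seq_b=gb, id_a=id_a, id_b=id_b)


_K2P_CLASS = np.full(256, -1, dtype=np.int8)  # -1 unusable, 0 purine, 1 pyrimidine
for _ch in b"AG":
    _K2P_CLASS[_ch] = 0
for _ch in b"CT":
    _K2P_CLASS[_ch] = 1


def k2p_distance(aln: PairwiseAlignment) -> DistanceEstimate:
    """Kimura two-parameter distance over ungapped non-N columns."""
    xa = np.frombuffer(aln.seq_a.encode(), dtype=np.uint8)
    xb = np.frombuffer(aln.seq_b.encode(), dtype=np.uint8)
    ca, cb = _K2P_CLASS[xa], _K2P_CLASS[xb]
    usable = (ca >= 0) & (cb >= 0)
    n = int(usable.sum())
    diff = usable & (xa != xb)
    ts = int((diff & (ca == cb)).sum())
    tv = int((diff & (ca != cb)).sum())
    if n == 0:
        raise ValueError("no usable (ungapped, non-N) alignment columns")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(
            f"K2P saturation: P={P:.4f}, Q={Q:.4f} leave the invertible range"
        )
    K = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DistanceEstimate(P=P, Q=Q, K=K, n_sites=n)


def build_codon_alignment(cds_a: str, cds_b: str) -> CodonAlignment:
    """Protein-guided codon alignment; gapped codon columns are dropped.

    Terminal stop codons are stripped; an internal stop is an error reporting
    the codon index.
    """
    seqs = []
    for label, cds in (("a", cds_a), ("b", cds_b)):
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError(f"CDS {label} length {len(cds)} not divisible by 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        for i, c in enumerate(codons):
            if c in STOP_CODONS:
                raise ValueError(f"internal stop codon in CDS {label} at codon index {i}")
        seqs.append(codons)
    ca, cb = seqs
    prot_a = str(Seq("".join(ca)).translate())
    prot_b = str(Seq("".join(cb)).translate())
    paln = global_align(prot_a, prot_b)
    cols_a: list[str] = []
    cols_b: list[str] = []
    ia = ib = 0
    for x, y in zip(paln.seq_a, paln.seq_b):
        if x != "-" and y != "-":
            cols_a.append(ca[ia])
            cols_b.append(cb[ib])
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return CodonAlignment(codons_a=tuple(cols_a), codons_b=tuple(cols_b))


def synonymous_site_fraction(codon: str) -> float:
    """NG86 count of synonymous sites in one codon (changes to stops count
    as nonsynonymous)."""
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for alt in _NUC:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if CODON_TO_AA[mutant] == aa and mutant not in STOP_CODONS:
                syn += 1
        s += syn / 3.0
    return s


def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two codons
    over all substitution orderings avoiding stop codons."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    if len(diff_pos) == 1:
        syn = CODON_TO_AA[ca] == CODON_TO_AA[cb]
        return (1.0, 0.0) if syn else (0.0, 1.0)

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = ca
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    results = [r for r in (walk(o) for o in permutations(diff_pos)) if r is not None]
    if not results:
        # every ordering crosses a stop; weight all orderings equally anyway
        results = []
        for order in permutations(diff_pos):
            cur = ca
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                    sd += 1.0
                else:
                    nd += 1.0
                cur = nxt
            results.append((sd, nd))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def _jc_rate(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4: Jukes–Cantor saturation")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(ca: CodonAlignment) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction."""
    if ca.n_codons < 10:
        warnings.warn(
            f"only {ca.n_codons} codon columns; Ka/Ks will be noisy", stacklevel=2
        )
    s_a = sum(synonymous_site_fraction(c) for c in ca.codons_a)
    s_b = sum(synonymous_site_fraction(c) for c in ca.codons_b)
    S = 0.5 * (s_a + s_b)
    N = 3.0 * ca.n_codons - S
    Sd = Nd = 0.0
    for x, y in zip(ca.codons_a, ca.codons_b):
        sd, nd = _pathway_counts(x, y)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = _jc_rate(ps)
    Ka = _jc_rate(pn)
    omega = Ka / Ks if Ks > 0 else None
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, Ks=Ks, Ka=Ka, omega=omega)


def noncoding_rate(aln: PairwiseAlignment) -> float:
    """K2P substitution rate for a UTR or intron alignment."""
    return k2p_distance(aln).K
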