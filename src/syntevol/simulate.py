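"""Synthetic homologous regions with known ground truth.

An ancestral region is diverged under a Kimura two-parameter (K2P)
substitution process into two or more lineages. On top of the substitution
background the generator places, with recorded coordinates:

* lineage-specific LTR-retrotransposon insertions whose twin LTRs start
  identical and then each accumulate substitutions at clock rate ``r`` so the
  expected LTR-pair divergence is ``2 r T`` for insertion age ``T``;
* ancestral ("colinear") LTR elements shared by all lineages, whose twin LTRs
  are identical at the split so both the within-lineage LTR pair and the
  between-lineage element pair date the lineage divergence;
* random insertions/deletions with geometric lengths;
* multi-exon genes evolving under purifying selection: synonymous positions
  track the neutral divergence while nonsynonymous substitutions are placed at
  a rate giving the configured Ka/Ks in expectation;
* SSR tracts and promoter motifs shared through the ancestor.

Substitutions are placed by per-site sampling from the K2P transition
probabilities integrated to the target branch length (exact marginal
distribution, no time stepping). Everything is driven by a single
``numpy.random.Generator``; a fixed seed gives byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .regions import FeatureInterval, GenomicRegion
from .molevol import CODON_TO_AA, STOP_CODONS

_NUC = "ACGT"
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(_NUC):
    _ENCODE[ord(_c)] = _i

SENSE_CODONS = tuple(
    c for c in ("".join(p) for p in product(_NUC, repeat=3)) if c not in STOP_CODONS
)

# single-nucleotide codon neighbourhoods (stops excluded)
SYN_NEIGHBORS: dict[str, tuple[str, ...]] = {}
NONSYN_NEIGHBORS: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    syn, non = [], []
    for _pos in range(3):
        for _alt in _NUC:
            if _alt == _codon[_pos]:
                continue
            _mut = _codon[:_pos] + _alt + _codon[_pos + 1 :]
            if _mut in STOP_CODONS:
                continue
            (syn if CODON_TO_AA[_mut] == CODON_TO_AA[_codon] else non).append(_mut)
    SYN_NEIGHBORS[_codon] = tuple(syn)
    NONSYN_NEIGHBORS[_codon] = tuple(non)


def encode(seq: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def decode(arr: np.ndarray) -> str:
    return bytes(_DECODE[arr]).decode()


def k2p_event_probs(distance: float, kappa: float) -> tuple[float, float]:
    """Per-site (transition, each-transversion) probabilities after evolving a
    branch of the given expected substitutions/site under K2P with ts/tv
    ratio kappa."""
    if distance < 0:
        raise ValueError("branch length must be >= 0")
    beta_t = distance / (2.0 * (kappa + 1.0))
    alpha_t = kappa * distance / (kappa + 1.0)
    p_ts = 0.25 + 0.25 * math.exp(-4.0 * beta_t) - 0.5 * math.exp(-2.0 * (alpha_t + beta_t))
    p_tv = 0.25 - 0.25 * math.exp(-4.0 * beta_t)
    return p_ts, p_tv


def mutate_k2p(arr: np.ndarray, distance: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded sequence along one branch of the K2P process.

    Encoding is A=0, C=1, G=2, T=3: the transition partner is always
    ``(x + 2) % 4``; the two transversions are ``(x + 1) % 4`` and
    ``(x + 3) % 4``.
    """
    p_ts, p_tv = k2p_event_probs(distance, kappa)
    u = rng.random(arr.shape[0])
    out = arr.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2.0 * p_tv)
    out[ts] = (arr[ts] + 2) % 4
    out[tv1] = (arr[tv1] + 1) % 4
    out[tv2] = (arr[tv2] + 3) % 4
    return out


def expected_identity(distance: float, kappa: float) -> float:
    p_ts, p_tv = k2p_event_probs(distance, kappa)
    return 1.0 - p_ts - 2.0 * p_tv


# --------------------------------------------------------------------------
# codon-level evolution under purifying selection


def evolve_codon(codon: str, t: float, omega: float, rng: np.random.Generator) -> str:
    """Gillespie simulation of one codon for branch length ``t`` measured in
    synonymous substitutions per synonymous site.

    Synonymous changes fire at total rate s_c (the NG86 synonymous-site count
    of the current codon) and nonsynonymous changes at rate ``omega * (3 -
    s_c)`` so that both Ks and Ka/Ks match their targets in expectation;
    changes to stop codons never occur.
    """
    time = 0.0
    while True:
        syn = SYN_NEIGHBORS[codon]
        non = NONSYN_NEIGHBORS[codon]
        s_c = len(syn) / 3.0
        rate_syn = s_c
        rate_non = omega * (3.0 - s_c)
        total = rate_syn + rate_non
        if total <= 0.0:
            return codon
        time += rng.exponential(1.0 / total)
        if time > t:
            return codon
        if rng.random() * total < rate_syn:
            codon = syn[rng.integers(len(syn))]
        else:
            codon = non[rng.integers(len(non))]


def evolve_codons(codons: list[str], t: float, omega: float, rng: np.random.Generator) -> list[str]:
    return [evolve_codon(c, t, omega, rng) for c in codons]


def random_sense_codons(n: int, rng: np.random.Generator) -> list[str]:
    idx = rng.integers(len(SENSE_CODONS), size=n)
    return [SENSE_CODONS[i] for i in idx]


def simulate_cds_pair(
    n_codons: int,
    ks_target: float,
    omega_target: float,
    seed: int | np.random.Generator = 0,
) -> tuple[str, str]:
    """A gap-free codon alignment pair with configured Ks and Ka/Ks.

    Substitutions are placed so that Nei-Gojobori counting recovers the
    targets in expectation: the targets are converted to per-site difference
    proportions by inverting the Jukes-Cantor correction
    (p = 3/4 (1 - e^(-4K/3))), and each codon receives at most one
    single-position change - synonymous with probability ps * s_c,
    nonsynonymous with probability pn * (3 - s_c), applied to one of the two
    copies at random. Single-position changes are attributed by NG86 exactly,
    so E[Sd] = ps * S and E[Nd] = pn * N. The output length is divisible by
    3 and contains no internal stop codons.
    """
    if n_codons < 50:
        raise ValueError("n_codons must be >= 50")
    if not (0.0 < omega_target <= 1.0):
        raise ValueError("omega_target must be in (0, 1]")
    if ks_target < 0.0:
        raise ValueError("ks_target must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ps_t = 0.75 * (1.0 - math.exp(-4.0 * ks_target / 3.0))
    pn_t = 0.75 * (1.0 - math.exp(-4.0 * omega_target * ks_target / 3.0))
    anc = random_sense_codons(n_codons, rng)
    a = list(anc)
    b = list(anc)
    for i, codon in enumerate(anc):
        syn = SYN_NEIGHBORS[codon]
        non = NONSYN_NEIGHBORS[codon]
        s_c = len(syn) / 3.0
        p_syn = ps_t * s_c
        p_non = pn_t * (3.0 - s_c)
        if p_syn + p_non > 1.0:
            raise ValueError(
                f"ks_target={ks_target} saturates the one-change-per-codon model"
            )
        u = rng.random()
        if u < p_syn:
            mutant = syn[rng.integers(len(syn))]
        elif u < p_syn + p_non and non:
            mutant = non[rng.integers(len(non))]
        else:
            continue
        if rng.random() < 0.5:
            a[i] = mutant
        else:
            b[i] = mutant
    return "".join(a), "".join(b)


# --------------------------------------------------------------------------
# LTR retrotransposons


@dataclass(frozen=True)
class LTRElement:
    """A full-length LTR retrotransposon with twin LTR sub-intervals
    (relative to the element start)."""

    sequence: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    true_divergence: float  # expected K between the two LTRs (= 2 r T)
    name: str = "LTR_element"


def simulate_ltr_element(
    ltr_length: int,
    age_years: float,
    r: float,
    seed: int | np.random.Generator = 0,
    internal_length: int = 3000,
    kappa: float = 2.0,
) -> LTRElement:
    """An LTR element whose twin LTRs were identical at insertion and have
    each accumulated substitutions at rate ``r`` for ``age_years`` years, so
    the expected pairwise LTR divergence is ``2 r T``."""
    if age_years < 0:
        raise ValueError("age must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ltr = rng.integers(0, 4, size=ltr_length).astype(np.uint8)
    internal = rng.integers(0, 4, size=internal_length).astype(np.uint8)
    branch = r * age_years
    ltr5 = mutate_k2p(ltr, branch, kappa, rng)
    ltr3 = mutate_k2p(ltr, branch, kappa, rng)
    seq = decode(np.concatenate([ltr5, internal, ltr3]))
    total = ltr_length * 2 + internal_length
    return LTRElement(
        sequence=seq,
        ltr5=(0, ltr_length),
        ltr3=(total - ltr_length, total),
        true_divergence=2.0 * r * age_years,
    )


# --------------------------------------------------------------------------
# whole-region simulation


@dataclass
class GeneModel:
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need one fewer intron than exons")
        if sum(self.exon_lengths) % 3:
            raise ValueError("total exon length must be divisible by 3")

    @property
    def span(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


DEFAULT_GENE_MODELS = (
    GeneModel((300, 201, 300), (150, 150)),
    GeneModel((240, 360), (180,)),
)

DEFAULT_SSRS = (("CT", 23), ("GAA", 8), ("CGGT", 5))
DEFAULT_MOTIFS = (("G-box", "CACGTG"), ("P-box", "CCTTTTG"))


@dataclass
class SimConfig:
    """Study conditions for the region generator.

    Defaults emulate a desk-scale slice of the homologous wheat regions:
    a 20 kb ancestral region diverged to K = 0.05 substitutions/site with
    ts/tv ratio 2, sparse indels, one colinear (ancestral) and two
    lineage-specific LTR retrotransposons per lineage (LTR clock
    1.3e-8 /site/year, insertions ~2 MY old, as dated for the wheat
    elements), two multi-exon genes under strong purifying selection
    (Ka/Ks = 0.05), and the printed SSR/motif inventory.
    """

    seed: int = 0
    ancestor_length: int = 20_000
    target_K: float = 0.05
    ts_tv_ratio: float = 2.0
    indel_rate: float = 1e-4
    indel_length_geometric_p: float = 0.1
    te_insertions_per_lineage: int = 2
    ancestral_te_count: int = 1
    ltr_length: int = 400
    ltr_internal_length: int = 800
    ltr_age_years: float = 2.0e6
    clock_rate_r: float = 1.3e-8
    gene_models: tuple[GeneModel, ...] = DEFAULT_GENE_MODELS
    omega_target: float = 0.05
    ssrs: tuple[tuple[str, int], ...] = DEFAULT_SSRS
    motifs: tuple[tuple[str, str], ...] = DEFAULT_MOTIFS

    def __post_init__(self) -> None:
        if self.target_K < 0:
            raise ValueError("target_K must be >= 0")
        if not (0.0 < self.indel_length_geometric_p <= 1.0):
            raise ValueError("indel_length_geometric_p must be in (0, 1]")
        if not (0.0 < self.omega_target <= 1.0):
            raise ValueError("omega_target must be in (0, 1]")


@dataclass
class SimTruth:
    """Recoverable ground truth for a simulated lineage set."""

    true_K: float
    ltr_divergence: float  # expected twin-LTR K of lineage-specific elements
    colinear_divergence: float  # expected K between colinear element copies
    te_insertions: dict[str, list[FeatureInterval]] = field(default_factory=dict)
    conserved: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    conserved_ancestral: list[tuple[int, int]] = field(default_factory=list)
    genes: dict[str, list[FeatureInterval]] = field(default_factory=dict)
    ssrs: dict[str, list[FeatureInterval]] = field(default_factory=dict)
    motifs: dict[str, list[FeatureInterval]] = field(default_factory=dict)


def _place_loci(length: int, spans: list[int], rng: np.random.Generator, margin: int = 500) -> list[int]:
    """Evenly spaced, jittered locus starts that never overlap each other or
    the region margins."""
    n = len(spans)
    if n == 0:
        return []
    slot = (length - 2 * margin) // n
    if slot <= max(spans) + 10:
        raise ValueError("ancestor too short for the requested loci")
    starts = []
    for i, span in enumerate(spans):
        lo = margin + i * slot
        hi = margin + (i + 1) * slot - span
        starts.append(int(rng.integers(lo, hi)))
    return starts


def _sample_interval(
    length: int,
    span: int,
    forbidden: list[tuple[int, int]],
    rng: np.random.Generator,
    max_tries: int = 200,
) -> tuple[int, int] | None:
    for _ in range(max_tries):
        s = int(rng.integers(0, length - span))
        e = s + span
        if all(e <= fs or s >= fe for fs, fe in forbidden):
            return s, e
    return None


@dataclass
class _Insertion:
    pos: int  # ancestral coordinate, insert before pos
    seq: np.ndarray
    kind: str  # "indel" or "TE"
    name: str = ""
    ltr5: tuple[int, int] | None = None
    ltr3: tuple[int, int] | None = None


def _assemble(
    mutated: np.ndarray,
    insertions: list[_Insertion],
    deletions: list[tuple[int, int]],
) -> tuple[np.ndarray, list[tuple[int, int, int]], list[FeatureInterval]]:
    """Apply structural events (ancestral coordinates, non-overlapping) to a
    mutated ancestor copy.

    Returns the lineage sequence, the ancestral->lineage piece map as
    (anc_start, anc_end, out_start) triples, and the TE/indel features created
    by insertions.
    """
    events: list[tuple[int, int, object]] = [(d[0], 1, d) for d in deletions]
    events += [(ins.pos, 0, ins) for ins in insertions]
    events.sort(key=lambda t: (t[0], t[1]))
    chunks: list[np.ndarray] = []
    pieces: list[tuple[int, int, int]] = []
    feats: list[FeatureInterval] = []
    cursor = 0
    out = 0
    for pos, tag, payload in events:
        if pos > cursor:
            chunks.append(mutated[cursor:pos])
            pieces.append((cursor, pos, out))
            out += pos - cursor
            cursor = pos
        if tag == 0:
            ins: _Insertion = payload  # type: ignore[assignment]
            chunks.append(ins.seq)
            if ins.kind == "TE":
                feats.append(
                    FeatureInterval(out, out + len(ins.seq), "+", "TE", ins.name)
                )
                if ins.ltr5 is not None:
                    feats.append(
                        FeatureInterval(out + ins.ltr5[0], out + ins.ltr5[1], "+",
                                        "LTR5", ins.name + "_LTR5")
                    )
                if ins.ltr3 is not None:
                    feats.append(
                        FeatureInterval(out + ins.ltr3[0], out + ins.ltr3[1], "+",
                                        "LTR3", ins.name + "_LTR3")
                    )
            out += len(ins.seq)
        else:
            s, e = payload  # type: ignore[misc]
            cursor = e
    if cursor < len(mutated):
        chunks.append(mutated[cursor:])
        pieces.append((cursor, len(mutated), out))
    seq = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint8)
    return seq, pieces, feats


def _map_interval(pieces: list[tuple[int, int, int]], s: int, e: int) -> list[tuple[int, int]]:
    """Map an ancestral interval through a piece map, splitting where the
    interval is interrupted by insertions or deletions."""
    out: list[tuple[int, int]] = []
    for anc_s, anc_e, out_s in pieces:
        lo, hi = max(s, anc_s), min(e, anc_e)
        if lo < hi:
            out.append((out_s + (lo - anc_s), out_s + (hi - anc_s)))
    return out


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def simulate_lineages(
    config: SimConfig,
    lineage_names: tuple[str, ...] = ("A", "B"),
) -> tuple[list[GenomicRegion], SimTruth]:
    """Descend ``len(lineage_names)`` lineages from one random ancestor.

    Each lineage evolves along an independent branch of ``target_K / 2``
    substitutions/site, so every pairwise distance is ``target_K`` in
    expectation.
    """
    cfg = config
    if expected_identity(cfg.target_K, cfg.ts_tv_ratio) < 0.25:
        raise ValueError(
            f"target_K={cfg.target_K} leaves expected identity below 25% (saturation)"
        )
    rng = np.random.default_rng(cfg.seed)
    L = cfg.ancestor_length
    ancestor = rng.integers(0, 4, size=L).astype(np.uint8)

    # --- embedded ancestral loci (shared by construction) -----------------
    locked: list[tuple[int, int]] = []  # no structural events allowed here

    gene_spans = [g.span for g in cfg.gene_models]
    ssr_tracts = [u * c for u, c in cfg.ssrs]
    ssr_spans = [len(t) for t in ssr_tracts]
    motif_spans = [len(m[1]) for m in cfg.motifs]
    anc_te_span = 2 * cfg.ltr_length + cfg.ltr_internal_length
    anc_te_spans = [anc_te_span] * cfg.ancestral_te_count

    all_spans = gene_spans + ssr_spans + motif_spans + anc_te_spans
    starts = _place_loci(L, all_spans, rng)
    k = 0
    gene_loci = []
    for g in cfg.gene_models:
        gene_loci.append((starts[k], g))
        locked.append((starts[k] - 10, starts[k] + g.span + 10))
        k += 1
    ssr_loci = []
    for (unit, copies), tract in zip(cfg.ssrs, ssr_tracts):
        s = starts[k]
        ancestor[s : s + len(tract)] = encode(tract)
        ssr_loci.append((s, s + len(tract), unit, copies))
        locked.append((s - 10, s + len(tract) + 10))
        k += 1
    motif_loci = []
    for name, consensus in cfg.motifs:
        s = starts[k]
        ancestor[s : s + len(consensus)] = encode(consensus)
        motif_loci.append((s, s + len(consensus), name))
        locked.append((s - 10, s + len(consensus) + 10))
        k += 1
    anc_te_loci = []
    for i in range(cfg.ancestral_te_count):
        s = starts[k]
        ltr = rng.integers(0, 4, size=cfg.ltr_length).astype(np.uint8)
        internal = rng.integers(0, 4, size=cfg.ltr_internal_length).astype(np.uint8)
        ancestor[s : s + anc_te_span] = np.concatenate([ltr, internal, ltr])
        anc_te_loci.append((s, s + anc_te_span, f"colinear_TE{i + 1}"))
        locked.append((s - 10, s + anc_te_span + 10))
        k += 1

    # ancestral gene coding sequences (random sense codons written into exons)
    gene_anc_codons = []
    for gs, g in gene_loci:
        n_codons = sum(g.exon_lengths) // 3
        codons = random_sense_codons(n_codons, rng)
        cds = encode("".join(codons))
        off = 0
        pos = gs
        for i, ex in enumerate(g.exon_lengths):
            ancestor[pos : pos + ex] = cds[off : off + ex]
            off += ex
            pos += ex
            if i < len(g.intron_lengths):
                pos += g.intron_lengths[i]
        gene_anc_codons.append(codons)

    branch = cfg.target_K / 2.0
    truth = SimTruth(
        true_K=cfg.target_K,
        ltr_divergence=2.0 * cfg.clock_rate_r * cfg.ltr_age_years,
        colinear_divergence=cfg.target_K,
    )

    regions: list[GenomicRegion] = []
    survived_per_lineage: dict[str, list[tuple[int, int]]] = {}
    pieces_per_lineage: dict[str, list[tuple[int, int, int]]] = {}

    for name in lineage_names:
        mutated = mutate_k2p(ancestor, branch, cfg.ts_tv_ratio, rng)
        # genes evolve by the codon process instead of the neutral background
        for (gs, g), anc_codons in zip(gene_loci, gene_anc_codons):
            codons = evolve_codons(anc_codons, branch, cfg.omega_target, rng)
            cds = encode("".join(codons))
            off = 0
            pos = gs
            for i, ex in enumerate(g.exon_lengths):
                mutated[pos : pos + ex] = cds[off : off + ex]
                off += ex
                pos += ex
                if i < len(g.intron_lengths):
                    pos += g.intron_lengths[i]

        # structural events, lineage specific
        forbidden = list(locked)
        deletions: list[tuple[int, int]] = []
        n_events = rng.poisson(cfg.indel_rate * L)
        insertions: list[_Insertion] = []
        for _ in range(n_events):
            size = int(rng.geometric(cfg.indel_length_geometric_p))
            if rng.random() < 0.5:
                iv = _sample_interval(L, size, forbidden, rng)
                if iv is None:
                    continue
                deletions.append(iv)
                forbidden.append(iv)
            else:
                iv = _sample_interval(L, 1, forbidden, rng)
                if iv is None:
                    continue
                insertions.append(
                    _Insertion(iv[0], rng.integers(0, 4, size=size).astype(np.uint8), "indel")
                )
                forbidden.append(iv)
        for i in range(cfg.te_insertions_per_lineage):
            iv = _sample_interval(L, 1, forbidden, rng)
            if iv is None:
                continue
            elem = simulate_ltr_element(
                cfg.ltr_length, cfg.ltr_age_years, cfg.clock_rate_r, rng,
                internal_length=cfg.ltr_internal_length, kappa=cfg.ts_tv_ratio,
            )
            insertions.append(
                _Insertion(iv[0], encode(elem.sequence), "TE",
                           name=f"{name}_TE{i + 1}", ltr5=elem.ltr5, ltr3=elem.ltr3)
            )
            forbidden.append(iv)

        seq, pieces, te_feats = _assemble(mutated, insertions, deletions)
        pieces_per_lineage[name] = pieces

        features = list(te_feats)
        truth.te_insertions[name] = [f for f in te_feats if f.kind == "TE"]
        # mapped ancestral annotations
        gene_feats = []
        for gi, (gs, g) in enumerate(gene_loci):
            maps = _map_interval(pieces, gs, gs + g.span)
            assert len(maps) == 1, "structural events are excluded from gene loci"
            out_s = maps[0][0]
            gname = f"gene{gi + 1}"
            gene_feats.append(FeatureInterval(out_s, out_s + g.span, "+", "gene", gname))
            pos = out_s
            for i, ex in enumerate(g.exon_lengths):
                gene_feats.append(FeatureInterval(pos, pos + ex, "+", "exon", f"{gname}.e{i + 1}"))
                gene_feats.append(FeatureInterval(pos, pos + ex, "+", "CDS", f"{gname}.c{i + 1}"))
                pos += ex
                if i < len(g.intron_lengths):
                    pos += g.intron_lengths[i]
        features += gene_feats
        truth.genes[name] = [f for f in gene_feats if f.kind == "gene"]

        ssr_feats = []
        for s, e, unit, copies in ssr_loci:
            (out_s, out_e), = _map_interval(pieces, s, e)
            ssr_feats.append(
                FeatureInterval(out_s, out_e, "+", "SSR", f"({unit}){copies}")
            )
        features += ssr_feats
        truth.ssrs[name] = ssr_feats

        motif_feats = []
        for s, e, mname in motif_loci:
            (out_s, out_e), = _map_interval(pieces, s, e)
            motif_feats.append(FeatureInterval(out_s, out_e, "+", "other", mname))
        truth.motifs[name] = motif_feats

        for s, e, tname in anc_te_loci:
            (out_s, out_e), = _map_interval(pieces, s, e)
            features.append(FeatureInterval(out_s, out_e, "+", "TE", tname))
            features.append(
                FeatureInterval(out_s, out_s + cfg.ltr_length, "+", "LTR5", tname + "_LTR5")
            )
            features.append(
                FeatureInterval(out_e - cfg.ltr_length, out_e, "+", "LTR3", tname + "_LTR3")
            )

        # ancestral material surviving this lineage
        deletions.sort()
        survived = []
        cur = 0
        for ds, de in deletions:
            if ds > cur:
                survived.append((cur, ds))
            cur = max(cur, de)
        if cur < L:
            survived.append((cur, L))
        survived_per_lineage[name] = survived

        features.sort(key=lambda f: (f.start, f.end))
        regions.append(GenomicRegion(id=name, residues=decode(seq), features=features))

    shared = survived_per_lineage[lineage_names[0]]
    for name in lineage_names[1:]:
        shared = _intersect(shared, survived_per_lineage[name])
    truth.conserved_ancestral = shared
    for name in lineage_names:
        mapped: list[tuple[int, int]] = []
        for s, e in shared:
            mapped += _map_interval(pieces_per_lineage[name], s, e)
        truth.conserved[name] = mapped
    return regions, truth


def simulate_pair(config: SimConfig) -> tuple[GenomicRegion, GenomicRegion, SimTruth]:
    """Two homologous regions descended from one random ancestor."""
    regions, truth = simulate_lineages(config, ("A", "B"))
    return regions[0], regions[1], truth


# --------------------------------------------------------------------------
# trios with implanted conserved non-coding sequences


@dataclass
class TrioTruth:
    cns: dict[str, list[tuple[int, int]]]
    genes: dict[str, list[FeatureInterval]]
    cns_identity: float


def _mutation_rate_for_identity(identity: float) -> float:
    """Per-copy substitution fraction e such that two independently mutated
    copies of a master sequence have expected pairwise identity
    (1-e)^2 + e^2/3 = identity."""
    if identity >= 1.0:
        return 0.0
    # (4/3) e^2 - 2 e + (1 - identity) = 0, smaller root
    disc = 4.0 - 16.0 / 3.0 * (1.0 - identity)
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


def _mutate_fraction(arr: np.ndarray, e: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute a near-deterministic fraction e of sites (stratified over
    the sequence so window identity stays close to target)."""
    out = arr.copy()
    n = len(arr)
    m = int(round(e * n))
    if m == 0:
        return out
    stratum = n / m
    for i in range(m):
        lo = int(i * stratum)
        hi = max(lo + 1, min(n, int((i + 1) * stratum)))
        pos = int(rng.integers(lo, hi))
        out[pos] = (out[pos] + 1 + rng.integers(3)) % 4
    return out


def simulate_trio_with_cns(
    config: SimConfig,
    n_cns: int,
    cns_identity: float,
    lineage_names: tuple[str, str, str] = ("A", "B", "D"),
    cns_length: int = 600,
    spacer_length: int = 400,
    flank_length: int = 300,
) -> tuple[list[GenomicRegion], TrioTruth]:
    """Three regions sharing two anchor genes and ``n_cns`` intergenic
    segments at the stated pairwise identity; the rest of the intergenic
    space is independent random sequence (diverged beyond detection)."""
    if cns_identity < 0.80:
        raise ValueError("cns_identity must be >= 0.80")
    rng = np.random.default_rng(config.seed)
    g1, g2 = DEFAULT_GENE_MODELS[0], DEFAULT_GENE_MODELS[1]
    gene_seqs = [
        encode("".join(random_sense_codons(sum(g.exon_lengths) // 3, rng)))
        for g in (g1, g2)
    ]
    masters = [rng.integers(0, 4, size=cns_length).astype(np.uint8) for _ in range(n_cns)]
    e = _mutation_rate_for_identity(cns_identity)

    truth = TrioTruth(cns={}, genes={}, cns_identity=cns_identity)
    regions = []
    for name in lineage_names:
        parts: list[np.ndarray] = []
        features: list[FeatureInterval] = []
        cns_coords: list[tuple[int, int]] = []
        pos = 0

        def _push(arr: np.ndarray) -> None:
            nonlocal pos
            parts.append(arr)
            pos += len(arr)

        def _push_gene(g: GeneModel, cds: np.ndarray, label: str) -> None:
            gs = pos
            off = 0
            for i, ex in enumerate(g.exon_lengths):
                features.append(FeatureInterval(pos, pos + ex, "+", "exon", f"{label}.e{i + 1}"))
                features.append(FeatureInterval(pos, pos + ex, "+", "CDS", f"{label}.c{i + 1}"))
                _push(cds[off : off + ex])
                off += ex
                if i < len(g.intron_lengths):
                    _push(rng.integers(0, 4, size=g.intron_lengths[i]).astype(np.uint8))
            features.append(FeatureInterval(gs, pos, "+", "gene", label))

        _push(rng.integers(0, 4, size=flank_length).astype(np.uint8))
        _push_gene(g1, gene_seqs[0], "gene1")
        for master in masters:
            _push(rng.integers(0, 4, size=spacer_length).astype(np.uint8))
            copy = _mutate_fraction(master, e, rng)
            cns_coords.append((pos, pos + len(copy)))
            _push(copy)
        _push(rng.integers(0, 4, size=spacer_length).astype(np.uint8))
        _push_gene(g2, gene_seqs[1], "gene2")
        _push(rng.integers(0, 4, size=flank_length).astype(np.uint8))

        seq = decode(np.concatenate(parts))
        features.sort(key=lambda f: (f.start, f.end))
        region = GenomicRegion(id=name, residues=seq, features=features)
        regions.append(region)
        truth.cns[name] = cns_coords
        truth.genes[name] = [f for f in features if f.kind == "gene"]
    return regions, truth
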