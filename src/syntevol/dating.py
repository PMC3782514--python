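"""Insertion-age and divergence-time estimation under a molecular clock.

The working formula throughout is T = K / (2 r): a pair of sequences (twin
LTRs of one element, colinear elements of two genomes, or orthologous gene
regions) that diverged T years ago at substitution rate r per site per year
accumulates an expected K = 2 r T substitutions per site between them.

Two clock-rate presets ship:

* ``GRASS_ADH_RATE`` = 6.5e-9 /site/year, the grass adh1/adh2 synonymous
  rate commonly used for gene-based dating;
* ``LTR_RATE`` = 1.3e-8 /site/year, the doubled rate conventionally applied
  to LTR regions (and the only rate consistent with the printed element
  ages this package reproduces).

A clock can instead be calibrated from a (K_cal, T_cal) pair, giving
r = K_cal / (2 T_cal) and calibrated_time(K) = K * T_cal / K_cal.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean

from .molevol import PairwiseAlignment, global_align, k2p_distance

GRASS_ADH_RATE = 6.5e-9
LTR_RATE = 1.3e-8

RATE_PRESETS = {"adh_6.5e-9": GRASS_ADH_RATE, "ltr_1.3e-8": LTR_RATE}


@dataclass(frozen=True)
class ClockRate:
    r: float  # substitutions / site / year
    source: str = "fixed"
    note: str = ""

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("clock rate must be positive")


@dataclass(frozen=True)
class Calibration:
    K_cal: float
    T_cal: float  # years

    def __post_init__(self) -> None:
        if self.K_cal <= 0 or self.T_cal <= 0:
            raise ValueError("calibration inputs must be positive")

    @property
    def rate(self) -> ClockRate:
        return ClockRate(self.K_cal / (2.0 * self.T_cal), source="calibrated")

    def calibrated_time(self, K: float) -> float:
        """Years corresponding to divergence K under this calibration."""
        return K * self.T_cal / self.K_cal


def calibrate(K_cal: float, T_cal: float) -> Calibration:
    return Calibration(K_cal=K_cal, T_cal=T_cal)


@dataclass(frozen=True)
class AgeEstimate:
    K: float
    r: float
    T: float  # years

    @property
    def mya(self) -> float:
        return self.T / 1e6


def age_from_divergence(K: float, rate: ClockRate | float) -> AgeEstimate:
    """T = K / (2 r)."""
    r = rate.r if isinstance(rate, ClockRate) else float(rate)
    if r <= 0:
        raise ValueError("rate must be positive")
    if K < 0:
        raise ValueError("divergence must be >= 0")
    return AgeEstimate(K=K, r=r, T=K / (2.0 * r))


def _pair_divergence(seq_a: str, seq_b: str) -> float:
    if len(seq_a) == len(seq_b):
        aln = PairwiseAlignment(seq_a.upper(), seq_b.upper())
    else:
        aln = global_align(seq_a.upper(), seq_b.upper())
    return k2p_distance(aln).K


def ltr_insertion_age(ltr5: str, ltr3: str, rate: ClockRate | float = LTR_RATE) -> AgeEstimate:
    """Date an LTR retrotransposon insertion from its twin LTRs.

    The LTRs were identical at insertion; their K2P divergence K dates the
    element at T = K / (2 r).
    """
    return age_from_divergence(_pair_divergence(ltr5, ltr3), rate)


def colinear_element_age(
    elem_a: str, elem_b: str, rate: ClockRate | float = LTR_RATE
) -> AgeEstimate:
    """Date the divergence of two genomes from a colinear element pair."""
    return age_from_divergence(_pair_divergence(elem_a, elem_b), rate)


@dataclass(frozen=True)
class LocusDatingRow:
    """One locus-dating row: two genes, two calibrations, averaged times.

    The slower gene contributes the mean of its coding and intron rates (at
    full precision, averaged before any rounding); the faster gene
    contributes its synonymous rate. Each is converted to years through its
    own calibration and the two times are averaged.
    """

    pair_label: str
    slow_coding_K: float | None
    slow_intron_K: float | None
    slow_avg_K: float | None
    slow_time_years: float | None
    fast_Ks: float | None
    fast_time_years: float | None
    avg_time_years: float | None

    def display_mya(self, decimals: int = 4) -> dict[str, float | None]:
        def _r(v: float | None) -> float | None:
            return None if v is None else round(v / 1e6, decimals)

        return {
            "slow_time_mya": _r(self.slow_time_years),
            "fast_time_mya": _r(self.fast_time_years),
            "avg_time_mya": _r(self.avg_time_years),
        }


def locus_dating_row(
    pair_label: str,
    slow_gene_rates: tuple[float | None, float | None],
    fast_gene_Ks: float | None,
    cal_slow: Calibration,
    cal_fast: Calibration,
) -> LocusDatingRow:
    """Combine per-gene substitution rates into averaged divergence times.

    ``slow_gene_rates`` is the (coding K, intron K) pair of the slower gene;
    ``fast_gene_Ks`` the synonymous rate of the faster gene. Missing rates
    yield a row with blanks.
    """
    coding, intron = slow_gene_rates
    slow_avg = None if coding is None or intron is None else (coding + intron) / 2.0
    slow_time = None if slow_avg is None else cal_slow.calibrated_time(slow_avg)
    fast_time = None if fast_gene_Ks is None else cal_fast.calibrated_time(fast_gene_Ks)
    times = [t for t in (slow_time, fast_time) if t is not None]
    avg_time = mean(times) if times else None
    return LocusDatingRow(
        pair_label=pair_label,
        slow_coding_K=coding,
        slow_intron_K=intron,
        slow_avg_K=slow_avg,
        slow_time_years=slow_time,
        fast_Ks=fast_gene_Ks,
        fast_time_years=fast_time,
        avg_time_years=avg_time,
    )
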