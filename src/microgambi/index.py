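"""Per-station microgAMBI computations.

For every sampling station (one column of the count table) the assessment
reports the six quantities of the calculation template: total reads, taxon
richness, Shannon-Wiener diversity H' (log2), the read partition over
ecological groups, the group percentages, and the microgAMBI index with its
five-class ecological status.

The index follows the AMBI family form: a weighted mean of the ecological-
group relative abundances,

    microgAMBI = (w_EGI * %EGI + w_EGIII * %EGIII) / 100

with default weights 0 (EGI, sensitive) and 6 (EGIII, tolerant), so the
index runs from 0 (all sensitive reads) to 6 (all tolerant reads).  Status
classes are right-closed intervals over the default boundaries
1.2 / 3.3 / 4.3 / 5.5: high, good, moderate, poor, bad.  Both weights and
boundaries are configuration, echoed into every report for provenance.

Richness and H' are computed over ALL taxa with reads > 0, including those
not in the reference list, because the template computes them on the raw
data column before any matching.
"""

from __future__ import annotations

import bisect
import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .community import AbundanceMatrix
from .taxa import MatchCategory, MatchOptions, TaxaReference, lookup

__all__ = [
    "IndexConfig",
    "DenominatorPolicy",
    "Status",
    "EGPartition",
    "StationAssessment",
    "StationTotals",
    "UndefinedFractionsError",
    "station_totals",
    "shannon_diversity",
    "partition_reads",
    "eg_fractions",
    "microgambi_index",
    "classify_status",
    "assess_station",
    "assess_all",
]

_TOL = 1e-9


class DenominatorPolicy(str, enum.Enum):
    """Denominator for the group fractions entering the index.

    ``ASSIGNED_ONLY`` renormalizes over EGI+EGIII reads (the AMBI lineage:
    the index is the relative-abundance ratio of the two groups);
    ``ALL_READS`` divides by the station total, letting unmatched reads
    dilute both fractions.
    """

    ASSIGNED_ONLY = "assigned_only"
    ALL_READS = "all_reads"


class Status(str, enum.Enum):
    HIGH = "high"
    GOOD = "good"
    MODERATE = "moderate"
    POOR = "poor"
    BAD = "bad"
    UNCLASSIFIABLE = "unclassifiable"


#: Class order from best to worst, for monotonicity checks and reporting.
STATUS_ORDER = (Status.HIGH, Status.GOOD, Status.MODERATE, Status.POOR, Status.BAD)


@dataclass(frozen=True)
class IndexConfig:
    """Weights, class boundaries, and policy knobs of the index.

    ``weight_egi`` / ``weight_egiii``: coefficients of the two group
    fractions (defaults 0 and 6, the canonical equation).
    ``class_boundaries``: strictly increasing (b1..b4) splitting
    [weight_egi, weight_egiii] into high/good/moderate/poor/bad.
    ``unmatched_warn_threshold``: percentage of not-assigned + not-in-list
    reads above which a coverage flag is raised (users with many unassigned
    taxa are advised to seek updated assignments).
    """

    weight_egi: float = 0.0
    weight_egiii: float = 6.0
    class_boundaries: tuple[float, float, float, float] = (1.2, 3.3, 4.3, 5.5)
    denominator_policy: DenominatorPolicy = DenominatorPolicy.ASSIGNED_ONLY
    unmatched_warn_threshold: float = 20.0

    def __post_init__(self) -> None:
        if self.weight_egi < 0 or self.weight_egiii < 0:
            raise ValueError("weights must be non-negative")
        if not self.weight_egi < self.weight_egiii:
            raise ValueError("weight_egi must be < weight_egiii")
        b = tuple(float(x) for x in self.class_boundaries)
        if len(b) != 4 or not all(b[i] < b[i + 1] for i in range(3)):
            raise ValueError("class_boundaries must be a strictly increasing 4-vector")
        if b[0] <= self.weight_egi or b[-1] >= self.weight_egiii:
            raise ValueError(
                "class boundaries must lie strictly inside "
                "(weight_egi, weight_egiii)"
            )
        object.__setattr__(self, "class_boundaries", b)
        object.__setattr__(
            self, "denominator_policy", DenominatorPolicy(self.denominator_policy)
        )

    def as_dict(self) -> dict:
        return {
            "weight_egi": self.weight_egi,
            "weight_egiii": self.weight_egiii,
            "class_boundaries": list(self.class_boundaries),
            "denominator_policy": self.denominator_policy.value,
            "unmatched_warn_threshold": self.unmatched_warn_threshold,
        }


@dataclass
class StationTotals:
    total_reads: int
    n_taxa: int


@dataclass
class EGPartition:
    """A station's reads and taxa split over the four match categories.

    Only taxa with reads > 0 appear; the four read counts sum to the
    station's total.
    """

    reads_egi: int = 0
    reads_egiii: int = 0
    reads_not_assigned: int = 0
    reads_not_in_list: int = 0
    taxa_egi: list[str] = field(default_factory=list)
    taxa_egiii: list[str] = field(default_factory=list)
    taxa_not_assigned: list[str] = field(default_factory=list)
    taxa_not_in_list: list[str] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return (self.reads_egi + self.reads_egiii
                + self.reads_not_assigned + self.reads_not_in_list)


@dataclass
class StationAssessment:
    """The template's output row for one station."""

    station_id: str
    total_reads: int
    n_taxa: int
    shannon_h_bits: Optional[float]
    reads_egi: int
    reads_egiii: int
    reads_not_assigned: int
    reads_not_in_list: int
    pct_egi: float
    pct_egiii: float
    pct_not_assigned: float
    pct_not_in_list: float
    f_egi: Optional[float]
    f_egiii: Optional[float]
    index_value: Optional[float]
    status: Status
    flags: list[str] = field(default_factory=list)


class UndefinedFractionsError(ZeroDivisionError):
    """Group fractions are undefined (zero denominator); carries a reason."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


# -- the six template computations ----------------------------------------

def station_totals(matrix: AbundanceMatrix, station: str) -> StationTotals:
    """Total reads (column sum) and richness (cells with reads > 0)."""
    col = matrix.station_counts(station)
    return StationTotals(int(col.sum()), int((col > 0).sum()))


def shannon_diversity(counts: Sequence[int]) -> float:
    """Shannon-Wiener diversity H' in bits: -sum p_i log2 p_i over taxa
    with count > 0, p_i the read fraction.

    Bounded by [0, log2(richness)].  Undefined for an all-zero vector
    (raises ValueError rather than silently returning 0, since an empty
    station has no community to be diverse).
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("Shannon diversity is undefined for an all-zero vector")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum()) if p.size > 1 else 0.0


def partition_reads(
    matrix: AbundanceMatrix,
    ref: TaxaReference,
    station: str,
    options: MatchOptions | None = None,
) -> EGPartition:
    """Route every taxon with reads > 0 into exactly one category.

    Zero-count taxa contribute nothing and are listed nowhere; read sums
    conserve the column total by construction.
    """
    col = matrix.station_counts(station)
    part = EGPartition()
    for name, n in zip(matrix.taxa_names, col):
        if n <= 0:
            continue
        n = int(n)
        cat = lookup(ref, name, options).category
        if cat is MatchCategory.EGI:
            part.reads_egi += n
            part.taxa_egi.append(name)
        elif cat is MatchCategory.EGIII:
            part.reads_egiii += n
            part.taxa_egiii.append(name)
        elif cat is MatchCategory.NOT_ASSIGNED:
            part.reads_not_assigned += n
            part.taxa_not_assigned.append(name)
        else:
            part.reads_not_in_list += n
            part.taxa_not_in_list.append(name)
    return part


def eg_fractions(
    p: EGPartition,
    policy: DenominatorPolicy = DenominatorPolicy.ASSIGNED_ONLY,
) -> tuple[float, float]:
    """Percentages (f_egi, f_egiii) under the chosen denominator policy.

    Under ``ASSIGNED_ONLY`` the two fractions sum to exactly 100; a zero
    denominator raises :class:`UndefinedFractionsError` with a reason code.
    """
    policy = DenominatorPolicy(policy)
    if policy is DenominatorPolicy.ASSIGNED_ONLY:
        denom = p.reads_egi + p.reads_egiii
        if denom == 0:
            raise UndefinedFractionsError("NO_ASSIGNED_READS")
    else:
        denom = p.total_reads
        if denom == 0:
            raise UndefinedFractionsError("NO_READS")
    return 100.0 * p.reads_egi / denom, 100.0 * p.reads_egiii / denom


def microgambi_index(f_egi: float, f_egiii: float, cfg: IndexConfig | None = None) -> float:
    """The weighted-percentage index; linear in f_egiii.

    With the default weights this is (0*%EGI + 6*%EGIII)/100, spanning
    [weight_egi, weight_egiii] as f_egiii runs 0..100.
    """
    cfg = cfg or IndexConfig()
    if f_egi < 0 or f_egiii < 0:
        raise ValueError("group fractions must be non-negative")
    if f_egi > 100 + _TOL or f_egiii > 100 + _TOL:
        raise ValueError("group fractions are percentages in [0, 100]")
    return (cfg.weight_egi * f_egi + cfg.weight_egiii * f_egiii) / 100.0


def classify_status(index: float, cfg: IndexConfig | None = None) -> Status:
    """Map an index value to its quality class.

    Intervals are right-closed — [w_egi, b1] high, (b1, b2] good, (b2, b3]
    moderate, (b3, b4] poor, (b4, w_egiii] bad — so a value sitting exactly
    on a boundary takes the better class.  Total and monotone over the valid
    range; values outside it are an error.
    """
    cfg = cfg or IndexConfig()
    if index < cfg.weight_egi - _TOL or index > cfg.weight_egiii + _TOL:
        raise ValueError(
            f"index {index} outside [{cfg.weight_egi}, {cfg.weight_egiii}]"
        )
    return STATUS_ORDER[bisect.bisect_left(cfg.class_boundaries, index)]


def assess_station(
    matrix: AbundanceMatrix,
    ref: TaxaReference,
    station: str,
    cfg: IndexConfig | None = None,
    options: MatchOptions | None = None,
) -> StationAssessment:
    """Compose the full per-station assessment.

    A station with zero EGI+EGIII reads (under the assigned-only policy) or
    zero reads overall is typed ``unclassifiable`` with an explanatory flag
    rather than producing NaN arithmetic.  A coverage flag is appended when
    the combined not-assigned + not-in-list percentage exceeds
    ``cfg.unmatched_warn_threshold``.
    """
    cfg = cfg or IndexConfig()
    totals = station_totals(matrix, station)
    part = partition_reads(matrix, ref, station, options)
    flags: list[str] = []

    if totals.total_reads > 0:
        h = shannon_diversity(matrix.station_counts(station))
        pct = tuple(
            100.0 * r / totals.total_reads
            for r in (part.reads_egi, part.reads_egiii,
                      part.reads_not_assigned, part.reads_not_in_list)
        )
    else:
        h = None
        pct = (0.0, 0.0, 0.0, 0.0)
        flags.append("EMPTY_STATION")

    f_egi: Optional[float]
    f_egiii: Optional[float]
    try:
        f_egi, f_egiii = eg_fractions(part, cfg.denominator_policy)
        index_value: Optional[float] = microgambi_index(f_egi, f_egiii, cfg)
        status = classify_status(index_value, cfg)
    except UndefinedFractionsError as e:
        f_egi = f_egiii = index_value = None
        status = Status.UNCLASSIFIABLE
        if e.reason not in flags and totals.total_reads > 0:
            flags.append(e.reason)

    unmatched = pct[2] + pct[3]
    if totals.total_reads > 0 and unmatched > cfg.unmatched_warn_threshold:
        flags.append(
            f"LOW_REFERENCE_COVERAGE:{unmatched:.1f}%_unmatched"
        )

    return StationAssessment(
        station_id=station,
        total_reads=totals.total_reads,
        n_taxa=totals.n_taxa,
        shannon_h_bits=h,
        reads_egi=part.reads_egi,
        reads_egiii=part.reads_egiii,
        reads_not_assigned=part.reads_not_assigned,
        reads_not_in_list=part.reads_not_in_list,
        pct_egi=pct[0],
        pct_egiii=pct[1],
        pct_not_assigned=pct[2],
        pct_not_in_list=pct[3],
        f_egi=f_egi,
        f_egiii=f_egiii,
        index_value=index_value,
        status=status,
        flags=flags,
    )


def assess_all(
    matrix: AbundanceMatrix,
    ref: TaxaReference,
    cfg: IndexConfig | None = None,
    options: MatchOptions | None = None,
) -> list[StationAssessment]:
    """Assess every station in input column order.

    Never aborts on a single unclassifiable station; an empty station set
    is an error.
    """
    if not matrix.station_ids:
        raise ValueError("matrix has no stations")
    return [assess_station(matrix, ref, s, cfg, options) for s in matrix.station_ids]
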