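"""Domain record types shared across the analysis modules.

Coordinates are 0-based half-open internally (BED convention); the printed
locus strings of the source tables are 1-based inclusive and are converted on
parse (see :func:`cislnc.cis.parse_locus`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import DataError

BIOTYPES = ("lncRNA", "mRNA")
STRANDS = ("+", "-")


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript isoform; the carrier of TSS logic.

    The transcription start site (TSS) is the 5'-most base of the transcript:
    ``start`` on the plus strand and ``end - 1`` on the minus strand.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise DataError(
                f"transcript {self.transcript_id!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise DataError(
                f"transcript {self.transcript_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if self.biotype not in BIOTYPES:
            raise DataError(
                f"transcript {self.transcript_id!r}: biotype must be one of "
                f"{BIOTYPES}, got {self.biotype!r}"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DEResult:
    """Per-transcript differential-expression record for one comparison."""

    transcript_id: str
    comparison: str  # "B_vs_A"
    log2fc: float
    fold_change: float
    p: float
    q: float
    status: str  # OK | LOWDATA | FAIL


@dataclass(frozen=True)
class CisPair:
    """A screened lncRNA-mRNA pair within the genomic-distance cutoff.

    ``signed_distance`` is measured from the lncRNA anchor to the mRNA TSS in
    mRNA orientation: negative when the lncRNA lies upstream of the TSS,
    positive downstream, 0 when the anchor overlaps the TSS.
    """

    lnc_id: str
    mrna_id: str
    chrom: str
    signed_distance: int
    lnc_log2fc: float
    mrna_log2fc: float
    pattern: str  # co_down | co_up | opposite
    antisense_flag: bool


@dataclass(frozen=True)
class CisSummary:
    """Counts and fold-change correlation over the screened pairs."""

    comparison: str
    n_pairs: int
    n_co_down: int
    n_co_up: int
    n_opposite: int
    pearson_r: Optional[float]
    p_two_tailed: Optional[float]

    def __post_init__(self) -> None:
        if self.n_co_down + self.n_co_up + self.n_opposite != self.n_pairs:
            raise DataError("pattern counts do not partition n_pairs")

    @property
    def correlation_defined(self) -> bool:
        return self.pearson_r is not None


@dataclass(frozen=True)
class SpecificityCall:
    """Tissue-specificity decision for one transcript against a panel."""

    transcript_id: str
    focal_expr: float
    max_other_expr: float
    max_other_tissue: str
    ratio: float  # inf when max_other_expr == 0 and focal > 0
    is_specific: bool
    factor: float


@dataclass(frozen=True)
class PatternCall:
    """Graft expression-pattern class over (islet, PBS graft, ALT graft)."""

    transcript_id: str
    values: tuple
    pattern: str  # monotone_down | monotone_up | other


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR well: a cycle-threshold value or an absent (undetected) call."""

    target: str
    sample: str
    group: str
    replicate: int
    ct: Optional[float]

    def __post_init__(self) -> None:
        if self.ct is not None and not (0 < self.ct <= 45):
            raise DataError(
                f"well ({self.target}, {self.sample}, rep {self.replicate}): "
                f"Ct {self.ct} outside (0, 45]"
            )


@dataclass(frozen=True)
class RelativeExpression:
    """ddCt result: fold change with replicate values and a t-test p-value."""

    target: str
    comparison: str
    replicate_2neg_ddct: tuple
    calibrator_2neg_ddct: tuple
    mean: float
    se: float
    fold_change: float
    fold_regulation: float
    p: float
    paired: bool


@dataclass(frozen=True)
class TunelCount:
    """TUNEL / insulin co-staining counts for one islet or graft section."""

    unit_id: str
    n_beta: int
    n_tunel_beta: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_tunel_beta <= self.n_beta):
            raise DataError(
                f"unit {self.unit_id!r}: need 0 <= TUNEL+ ({self.n_tunel_beta}) "
                f"<= beta cells ({self.n_beta})"
            )


@dataclass(frozen=True)
class QuadrantSummary:
    """Annexin-V / PI quadrant percentages and the apoptotic rate.

    ``apoptotic_rate`` = early + late apoptotic percentage. ``labeling``
    records which quadrant-naming convention produced the late/necrotic split.
    """

    n_events: int
    pct_viable: float
    pct_early: float
    pct_late: float
    pct_necrotic: float
    apoptotic_rate: float
    labeling: str

    def __post_init__(self) -> None:
        total = self.pct_viable + self.pct_early + self.pct_late + self.pct_necrotic
        if abs(total - 100.0) > 1e-9:
            raise DataError(f"quadrant percentages sum to {total}, not 100")
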