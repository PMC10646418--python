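"""Apoptosis quantification: TUNEL co-staining counts and Annexin-V/PI flow
cytometry quadrants.

Quadrant labelings
------------------
``methods`` (default): early apoptotic = AnnexinV+/PI-, late apoptotic =
AnnexinV+/PI+, necrotic = AnnexinV-/PI+.
``legend``: the alternative naming in which AnnexinV-/PI+ is called late
apoptotic and AnnexinV+/PI+ necrotic.

In both labelings viable = AnnexinV-/PI- and the apoptotic rate is the sum
of the early and late percentages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .types import QuadrantSummary, TunelCount

__all__ = [
    "tunel_fraction",
    "tunel_compare",
    "TunelSummary",
    "flow_quadrant_summary",
    "QUADRANT_LABELINGS",
]

QUADRANT_LABELINGS = ("methods", "legend")
QUADRANT_KEYS = ("viable", "early", "late", "necrotic")


@dataclass(frozen=True)
class TunelSummary:
    """Per-unit TUNEL+ beta-cell percentages with group mean and SE."""

    percentages: Dict[str, float]
    mean: float
    se: float
    n_units: int
    excluded: tuple


def tunel_fraction(counts: Sequence[TunelCount]) -> TunelSummary:
    """100 * TUNEL+ beta cells / beta cells per unit, with mean +/- SE.

    Units with zero beta cells are excluded with a warning rather than
    failing the whole group.
    """
    excluded = tuple(c.unit_id for c in counts if c.n_beta == 0)
    if excluded:
        warnings.warn(
            f"units with no beta cells excluded: {', '.join(excluded)}",
            stacklevel=2,
        )
    usable = [c for c in counts if c.n_beta > 0]
    if not usable:
        raise DataError("no units with beta cells")
    pct = {c.unit_id: 100.0 * c.n_tunel_beta / c.n_beta for c in usable}
    vals = np.array(list(pct.values()))
    se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else math.nan
    return TunelSummary(
        percentages=pct,
        mean=float(vals.mean()),
        se=se,
        n_units=len(usable),
        excluded=excluded,
    )


def tunel_compare(
    group_a: Sequence[TunelCount],
    group_b: Sequence[TunelCount],
    paired: bool = False,
) -> Tuple[TunelSummary, TunelSummary, float]:
    """Two-group comparison of TUNEL percentages by t-test (paired option
    for donor-matched designs)."""
    sa, sb = tunel_fraction(group_a), tunel_fraction(group_b)
    va = np.array(list(sa.percentages.values()))
    vb = np.array(list(sb.percentages.values()))
    if paired:
        if va.size != vb.size:
            raise DataError("paired comparison requires equal unit counts")
        p = float(stats.ttest_rel(va, vb).pvalue)
    else:
        p = float(stats.ttest_ind(va, vb).pvalue)
    return sa, sb, p


def _quadrant_of(
    annexin_pos: bool, pi_pos: bool, labeling: str
) -> str:
    if not annexin_pos and not pi_pos:
        return "viable"
    if annexin_pos and not pi_pos:
        return "early"
    if labeling == "methods":
        return "late" if (annexin_pos and pi_pos) else "necrotic"
    return "necrotic" if (annexin_pos and pi_pos) else "late"


def flow_quadrant_summary(
    events: Optional[pd.DataFrame] = None,
    counts: Optional[Mapping[str, int]] = None,
    annexin_threshold: float = 1000.0,
    pi_threshold: float = 1000.0,
    labeling: str = "methods",
) -> QuadrantSummary:
    """Partition flow events (or precomputed quadrant counts) and report the
    apoptotic rate.

    ``events`` needs columns ``annexin`` and ``pi``; an intensity at or above
    its threshold is a positive stain. Alternatively pass ``counts`` with
    keys viable/early/late/necrotic directly.
    """
    if labeling not in QUADRANT_LABELINGS:
        raise DataError(f"unknown labeling {labeling!r}; choose from {QUADRANT_LABELINGS}")
    if (events is None) == (counts is None):
        raise DataError("pass exactly one of events or counts")
    if counts is not None:
        missing = [k for k in QUADRANT_KEYS if k not in counts]
        if missing:
            raise DataError(f"quadrant counts missing key(s): {', '.join(missing)}")
        tallies = {k: int(counts[k]) for k in QUADRANT_KEYS}
    else:
        for col in ("annexin", "pi"):
            if col not in events.columns:
                raise DataError(f"event table missing column {col!r}")
        if len(events) == 0:
            raise DataError("empty event table")
        if annexin_threshold <= 0 or pi_threshold <= 0:
            raise DataError("thresholds must be positive")
        a_pos = events["annexin"].to_numpy() >= annexin_threshold
        p_pos = events["pi"].to_numpy() >= pi_threshold
        tallies = dict.fromkeys(QUADRANT_KEYS, 0)
        for ap, pp in zip(a_pos, p_pos):
            tallies[_quadrant_of(bool(ap), bool(pp), labeling)] += 1
    n = sum(tallies.values())
    if n == 0:
        raise DataError("no events to summarize")
    pct = {k: 100.0 * tallies[k] / n for k in QUADRANT_KEYS}
    return QuadrantSummary(
        n_events=n,
        pct_viable=pct["viable"],
        pct_early=pct["early"],
        pct_late=pct["late"],
        pct_necrotic=pct["necrotic"],
        apoptotic_rate=pct["early"] + pct["late"],
        labeling=labeling,
    )
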