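"""Tissue specificity, graft expression patterns, detection and localization.

The islet-specificity rule is the strict more-than-double criterion: a
transcript is islet-specific when its expression in the focal tissue is
strictly greater than ``factor`` (default 2) times the highest expression in
any other tissue of the panel. Expression units cancel in the ratio, so FPKM
and 2^-dCt panels are interchangeable here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DataError
from .matrix import TissuePanel
from .types import PatternCall, SpecificityCall

__all__ = [
    "rank_by_focal_expression",
    "islet_specificity_call",
    "specificity_call_from_values",
    "specificity_calls",
    "specificity_ratio_report",
    "RatioReport",
    "classify_graft_pattern",
    "detection_call",
    "localization_call",
]


def rank_by_focal_expression(panel: TissuePanel, top_n: Optional[int] = None) -> List[str]:
    """Transcripts in descending focal-tissue expression; ties broken
    lexicographically by transcript id."""
    if top_n is not None and top_n > panel.values.shape[0]:
        raise DataError(
            f"top_n={top_n} exceeds panel size {panel.values.shape[0]}"
        )
    focal = panel.values[panel.focal_tissue]
    order = sorted(focal.index, key=lambda tid: (-focal[tid], tid))
    return order[:top_n] if top_n is not None else order


def specificity_call_from_values(
    transcript_id: str,
    focal_expr: float,
    other_expr: Mapping[str, float],
    factor: float = 2.0,
) -> SpecificityCall:
    """Strict rule: specific iff focal > factor x max(other tissues).

    If every other tissue is 0 and the focal value is positive the call is
    specific with an infinite ratio; a focal value of 0 is never specific.
    """
    if not other_expr:
        raise DataError(f"transcript {transcript_id!r}: no non-focal tissues")
    max_tissue = max(other_expr, key=lambda t: (other_expr[t], t))
    max_other = float(other_expr[max_tissue])
    if max_other > 0:
        ratio = focal_expr / max_other
    else:
        ratio = math.inf if focal_expr > 0 else math.nan
    return SpecificityCall(
        transcript_id=transcript_id,
        focal_expr=float(focal_expr),
        max_other_expr=max_other,
        max_other_tissue=max_tissue,
        ratio=ratio,
        is_specific=bool(focal_expr > 0 and focal_expr > factor * max_other),
        factor=factor,
    )


def islet_specificity_call(
    panel: TissuePanel, transcript_id: str, factor: float = 2.0
) -> SpecificityCall:
    """Apply the more-than-double rule to one panel row."""
    if transcript_id not in panel.values.index:
        raise DataError(f"transcript {transcript_id!r} not in panel")
    row = panel.values.loc[transcript_id]
    others = {t: float(row[t]) for t in panel.other_tissues}
    return specificity_call_from_values(
        transcript_id, float(row[panel.focal_tissue]), others, factor=factor
    )


def specificity_calls(panel: TissuePanel, factor: float = 2.0) -> List[SpecificityCall]:
    return [islet_specificity_call(panel, tid, factor) for tid in panel.values.index]


@dataclass(frozen=True)
class RatioReport:
    """Per-transcript focal/max-other ratios with min and max over the
    non-excluded rows."""

    ratios: pd.Series
    min_ratio: float
    max_ratio: float
    excluded: tuple
    undefined: tuple


def specificity_ratio_report(
    panel: TissuePanel, exclude: Iterable[str] = ()
) -> RatioReport:
    """Exact focal/top-other quotients; min and max skip excluded rows and
    rows with an undefined ratio (max other tissue = 0), the latter with a
    warning."""
    exclude = tuple(exclude)
    calls = specificity_calls(panel)
    ratios = pd.Series(
        {c.transcript_id: c.ratio for c in calls}, name="ratio", dtype=float
    )
    undefined = tuple(
        c.transcript_id
        for c in calls
        if not math.isfinite(c.ratio) and c.transcript_id not in exclude
    )
    if undefined:
        warnings.warn(
            f"ratio undefined (max other tissue = 0) for: {', '.join(undefined)}; "
            "excluded from min/max",
            stacklevel=2,
        )
    usable = ratios.drop(index=list(exclude) + list(undefined), errors="ignore")
    usable = usable[np.isfinite(usable)]
    if usable.empty:
        raise DataError("no rows with a defined ratio after exclusions")
    return RatioReport(
        ratios=ratios,
        min_ratio=float(usable.min()),
        max_ratio=float(usable.max()),
        excluded=exclude,
        undefined=undefined,
    )


def classify_graft_pattern(
    transcript_id: str, islet: float, pbs: float, alt: float
) -> PatternCall:
    """Strict-chain classification of (islet, PBS graft, ALT graft) values.

    monotone_down: islet > pbs > alt; monotone_up: islet < pbs < alt; every
    other arrangement (including any tie) is ``other``.
    """
    if min(islet, pbs, alt) < 0:
        raise DataError(f"transcript {transcript_id!r}: negative expression value")
    if islet > pbs > alt:
        pattern = "monotone_down"
    elif islet < pbs < alt:
        pattern = "monotone_up"
    else:
        pattern = "other"
    return PatternCall(
        transcript_id=transcript_id, values=(islet, pbs, alt), pattern=pattern
    )


def detection_call(
    ct_values: Sequence[Optional[float]],
    max_cycles: float = 40.0,
    dissociation_ok: bool = True,
) -> str:
    """'detected' iff the dissociation curve is clean and any replicate Ct is
    below ``max_cycles`` (the threshold cycle count is inclusive for
    undetected)."""
    if not dissociation_ok:
        return "undetected"
    for ct in ct_values:
        if ct is not None and not (isinstance(ct, float) and math.isnan(ct)):
            if ct < max_cycles:
                return "detected"
    return "undetected"


def localization_call(cyto_signal: float, nuc_signal: float, fold: float = 2.0) -> str:
    """Subcellular enrichment from cytoplasmic vs nuclear fraction signals."""
    if cyto_signal < 0 or nuc_signal < 0:
        raise DataError("fraction signals must be nonnegative")
    if cyto_signal == 0 and nuc_signal == 0:
        raise DataError("both fraction signals are zero; localization undefined")
    if nuc_signal > fold * cyto_signal:
        return "nuclear"
    if cyto_signal > fold * nuc_signal:
        return "cytoplasmic"
    return "both"
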