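"""Genomic-distance screening of lncRNA-mRNA pairs and co-regulation summary.

A differentially expressed lncRNA is paired with a differentially expressed
mRNA when the lncRNA lies within ``max_distance`` (default 50 kb) of the mRNA
transcription start site. Distances are computed per transcript isoform, not
per gene, and a transcript may participate in several pairs.

Anchor modes
------------
``nearest_edge`` (default)
    distance from the closest point of the lncRNA interval to the mRNA TSS
    (0 when the TSS falls inside the lncRNA).
``tss5p``
    distance from the lncRNA's own 5' end to the mRNA TSS.

Sign convention: measured in mRNA orientation; negative means the lncRNA
anchor is upstream of the mRNA TSS, positive downstream. The magnitude, not
the sign, is what the 50-kb screen uses.
"""

from __future__ import annotations

import re
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .errors import DataError
from .types import CisPair, CisSummary, DEResult, TranscriptRecord

__all__ = [
    "parse_locus",
    "format_locus",
    "pair_distance",
    "screen_cis_pairs",
    "classify_pair",
    "summarize_pairs",
]

ANCHOR_MODES = ("nearest_edge", "tss5p")
DEFAULT_MAX_DISTANCE = 50_000

_LOCUS_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_locus(locus: str) -> Tuple[str, int, int]:
    """Parse a 1-based inclusive ``chr:start-end`` locus string.

    Returns (chrom, start, end) in the internal 0-based half-open convention;
    ``format_locus`` round-trips back to the printed string.
    """
    m = _LOCUS_RE.match(locus.strip())
    if m is None:
        raise DataError(f"malformed locus string {locus!r}; expected chr:start-end")
    start1, end1 = int(m.group("start")), int(m.group("end"))
    if start1 < 1 or end1 < start1:
        raise DataError(f"malformed locus string {locus!r}: start must be >= 1 and <= end")
    return m.group("chrom"), start1 - 1, end1


def format_locus(chrom: str, start: int, end: int) -> str:
    """Inverse of :func:`parse_locus` (back to 1-based inclusive)."""
    return f"{chrom}:{start + 1}-{end}"


def pair_distance(
    lnc: TranscriptRecord,
    mrna: TranscriptRecord,
    anchor: str = "nearest_edge",
) -> Optional[int]:
    """Signed bp distance from the lncRNA anchor to the mRNA TSS.

    Returns None for records on different chromosomes. For the nearest-edge
    anchor the lncRNA interval is treated as the closed segment
    [start, end] on the genomic line, so a lncRNA ending at 2000 is 500 bp
    from a TSS at 2500 and 0 bp from any TSS it covers.
    """
    if anchor not in ANCHOR_MODES:
        raise DataError(f"unknown anchor mode {anchor!r}; choose from {ANCHOR_MODES}")
    if lnc.chrom != mrna.chrom:
        return None
    t = mrna.tss
    if anchor == "nearest_edge":
        if lnc.start <= t <= lnc.end:
            unsigned = 0
            lnc_right_of_tss = False  # sign irrelevant at 0
        elif t > lnc.end:
            unsigned = t - lnc.end
            lnc_right_of_tss = False
        else:
            unsigned = lnc.start - t
            lnc_right_of_tss = True
    else:  # tss5p
        a = lnc.start if lnc.strand == "+" else lnc.end - 1
        unsigned = abs(a - t)
        lnc_right_of_tss = a > t
    raw = unsigned if lnc_right_of_tss else -unsigned
    signed = raw if mrna.strand == "+" else -raw
    return int(signed)


def classify_pair(lnc_log2fc: float, mrna_log2fc: float) -> str:
    """co_down (both negative), co_up (both positive), opposite otherwise."""
    if lnc_log2fc == 0 or mrna_log2fc == 0:
        raise DataError(
            "pair classification requires nonzero fold changes on both sides"
        )
    if lnc_log2fc < 0 and mrna_log2fc < 0:
        return "co_down"
    if lnc_log2fc > 0 and mrna_log2fc > 0:
        return "co_up"
    return "opposite"


def _annotation_map(
    annotation: Union[Mapping[str, TranscriptRecord], Iterable[TranscriptRecord]],
) -> Dict[str, TranscriptRecord]:
    if isinstance(annotation, Mapping):
        return dict(annotation)
    return {rec.transcript_id: rec for rec in annotation}


def screen_cis_pairs(
    de_lnc: Sequence[DEResult],
    de_mrna: Sequence[DEResult],
    annotation: Union[Mapping[str, TranscriptRecord], Iterable[TranscriptRecord]],
    max_distance: int = DEFAULT_MAX_DISTANCE,
    anchor: str = "nearest_edge",
) -> List[CisPair]:
    """All (lncRNA, mRNA) combinations with |distance| <= ``max_distance``.

    Inputs are expected to be pre-filtered DE lists (the cis_screen preset in
    the full pipeline). Every retained pair carries both log2 fold changes, a
    co-regulation pattern, and an antisense flag (opposite strands with
    overlapping intervals).
    """
    ann = _annotation_map(annotation)
    for r in list(de_lnc) + list(de_mrna):
        if r.transcript_id not in ann:
            raise DataError(f"transcript {r.transcript_id!r} missing from annotation")
    pairs: List[CisPair] = []
    for rl in de_lnc:
        lnc = ann[rl.transcript_id]
        for rm in de_mrna:
            mrna = ann[rm.transcript_id]
            d = pair_distance(lnc, mrna, anchor=anchor)
            if d is None or abs(d) > max_distance:
                continue
            antisense = (
                lnc.strand != mrna.strand
                and lnc.start < mrna.end
                and mrna.start < lnc.end
            )
            pairs.append(
                CisPair(
                    lnc_id=lnc.transcript_id,
                    mrna_id=mrna.transcript_id,
                    chrom=lnc.chrom,
                    signed_distance=d,
                    lnc_log2fc=rl.log2fc,
                    mrna_log2fc=rm.log2fc,
                    pattern=classify_pair(rl.log2fc, rm.log2fc),
                    antisense_flag=antisense,
                )
            )
    return pairs


def summarize_pairs(pairs: Sequence[CisPair], comparison: str = "") -> CisSummary:
    """Pattern counts plus Pearson correlation of the paired fold changes.

    With fewer than two pairs (or a constant fold-change vector) the counts
    are still returned and the correlation is flagged undefined (None).
    """
    n_co_down = sum(1 for p in pairs if p.pattern == "co_down")
    n_co_up = sum(1 for p in pairs if p.pattern == "co_up")
    n_opposite = sum(1 for p in pairs if p.pattern == "opposite")
    r: Optional[float] = None
    p_two: Optional[float] = None
    if len(pairs) >= 2:
        x = np.array([p.lnc_log2fc for p in pairs])
        y = np.array([p.mrna_log2fc for p in pairs])
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            res = stats.pearsonr(x, y)
            r, p_two = float(res.statistic), float(res.pvalue)
    return CisSummary(
        comparison=comparison,
        n_pairs=len(pairs),
        n_co_down=n_co_down,
        n_co_up=n_co_up,
        n_opposite=n_opposite,
        pearson_r=r,
        p_two_tailed=p_two,
    )
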