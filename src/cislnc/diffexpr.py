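"""Differential expression: fold changes, a replicate t-test, threshold
presets, and right-tailed Fisher gene-set enrichment.

The significance test is a two-sample Student t-test on
log2(abundance + pseudocount) replicates with Benjamini-Hochberg correction
across transcripts. It is a
deliberately simple, documented stand-in for a full RNA-seq dispersion model:
all planted-truth recovery in this package is asserted against it, never
against a re-analysis of the original sequencing data.

Threshold presets encode the inclusion rules used at different stages of the
study verbatim, including whether each comparison is strict or inclusive:

``rnaseq_de``
    |fold change| >= 2 and BH q <= 0.05 and test status OK.
``cis_screen``
    |log2 fold change| > 1.5 and p < 0.05 (the cis-pairing pre-filter).
``ipa_upload``
    |fold change| > 1.5 and p < 0.05.
``plot_inclusion``
    |fold change| > 1.5 OR p < 0.05.

Note ``cis_screen`` thresholds log2(FC) at 1.5 (FC ~ 2.83) while
``ipa_upload`` thresholds FC itself at 1.5; the two rules are intentionally
not reconciled because both appear as stated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .matrix import ExpressionMatrix
from .types import DEResult

__all__ = [
    "ThresholdPreset",
    "PRESETS",
    "compute_log2fc",
    "test_de",
    "filter_de",
    "DEFilterResult",
    "enrichment_fisher",
    "results_to_frame",
    "frame_to_results",
]

DE_TABLE_COLUMNS = [
    "transcript_id",
    "comparison",
    "log2fc",
    "fold_change",
    "p",
    "q",
    "status",
]


@dataclass(frozen=True)
class ThresholdPreset:
    """One named inclusion rule over (log2fc, p or q, status).

    Exactly one of ``max_p`` / ``max_q`` is set. ``strict_fc`` / ``strict_p``
    select ``>`` vs ``>=`` (``<`` vs ``<=``) to match the printed operator.
    """

    name: str
    min_abs_log2fc: float
    max_p: Optional[float] = None
    max_q: Optional[float] = None
    combine: str = "AND"
    strict_fc: bool = False
    strict_p: bool = False
    require_status_ok: bool = False

    def __post_init__(self) -> None:
        if (self.max_p is None) == (self.max_q is None):
            raise DataError(
                f"preset {self.name!r}: exactly one of max_p/max_q must be set"
            )
        if self.combine not in ("AND", "OR"):
            raise DataError(f"preset {self.name!r}: combine must be AND or OR")

    def passes_fc(self, log2fc: float) -> bool:
        a = abs(log2fc)
        return a > self.min_abs_log2fc if self.strict_fc else a >= self.min_abs_log2fc

    def passes_sig(self, p: float, q: float) -> bool:
        if self.max_p is not None:
            val, cut = p, self.max_p
        else:
            val, cut = q, self.max_q
        if math.isnan(val):
            return False
        return val < cut if self.strict_p else val <= cut

    def passes(self, r: DEResult) -> bool:
        if self.require_status_ok and r.status != "OK":
            return False
        fc_ok = self.passes_fc(r.log2fc)
        sig_ok = self.passes_sig(r.p, r.q)
        return (fc_ok and sig_ok) if self.combine == "AND" else (fc_ok or sig_ok)


PRESETS: Dict[str, ThresholdPreset] = {
    "rnaseq_de": ThresholdPreset(
        name="rnaseq_de",
        min_abs_log2fc=1.0,  # fold change >= 2
        max_q=0.05,
        strict_fc=False,
        strict_p=False,
        require_status_ok=True,
    ),
    "cis_screen": ThresholdPreset(
        name="cis_screen",
        min_abs_log2fc=1.5,  # log2(FC) > 1.5, strict
        max_p=0.05,
        strict_fc=True,
        strict_p=True,
    ),
    "ipa_upload": ThresholdPreset(
        name="ipa_upload",
        min_abs_log2fc=math.log2(1.5),  # FC > 1.5, strict
        max_p=0.05,
        strict_fc=True,
        strict_p=True,
    ),
    "plot_inclusion": ThresholdPreset(
        name="plot_inclusion",
        min_abs_log2fc=math.log2(1.5),
        max_p=0.05,
        combine="OR",
        strict_fc=True,
        strict_p=True,
    ),
}


def _group_arrays(
    matrix: ExpressionMatrix, group_a: str, group_b: str
) -> Tuple[np.ndarray, np.ndarray]:
    va = matrix.group_values(group_a).to_numpy(dtype=float)
    vb = matrix.group_values(group_b).to_numpy(dtype=float)
    return va, vb


def compute_log2fc(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2((mean_b + pseudocount) / (mean_a + pseudocount)) per transcript.

    With ``pseudocount = 0`` a zero group mean yields +/-inf (one side zero)
    or NaN (both zero); these are passed through rather than masked so the
    caller sees the undefined ratio explicitly.
    """
    if pseudocount < 0:
        raise DataError("pseudocount must be nonnegative")
    va, vb = _group_arrays(matrix, group_a, group_b)
    mean_a = va.mean(axis=1) + pseudocount
    mean_b = vb.mean(axis=1) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        l2fc = np.log2(mean_b) - np.log2(mean_a)
    return pd.Series(l2fc, index=matrix.values.index, name="log2fc")


def test_de(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
) -> List[DEResult]:
    """Student t-test of B vs A on log2(value + pseudocount) replicates.

    The pooled-variance (equal-variance) form is used deliberately: the
    generator's noise model is homoscedastic on the log2 scale and at
    triplicate group sizes the pooled test holds its nominal 5% size, which
    the small-sample Welch approximation does not. One ``DEResult`` per
    transcript. Transcripts in groups with < 2 replicates get status LOWDATA
    and no p/q. Zero-variance rows follow the degenerate conventions:
    identical groups -> p = 1; distinct constant groups -> p = 0. BH
    q-values are computed over the OK tests only.
    """
    va, vb = _group_arrays(matrix, group_a, group_b)
    comparison = f"{group_b}_vs_{group_a}"
    l2fc = compute_log2fc(matrix, group_a, group_b, pseudocount).to_numpy()

    n_a, n_b = va.shape[1], vb.shape[1]
    status = "OK" if (n_a >= 2 and n_b >= 2) else "LOWDATA"

    if status == "OK":
        la = np.log2(va + pseudocount)
        lb = np.log2(vb + pseudocount)
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # near-constant rows are handled below by the degenerate conventions
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = stats.ttest_ind(lb, la, axis=1, equal_var=True)
        p = np.asarray(p, dtype=float)
        var_a = la.var(axis=1, ddof=1)
        var_b = lb.var(axis=1, ddof=1)
        degenerate = (var_a == 0) & (var_b == 0)
        same_mean = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p[degenerate & same_mean] = 1.0
        p[degenerate & ~same_mean] = 0.0
        q = np.full_like(p, np.nan)
        finite = ~np.isnan(p)
        if finite.any():
            q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    else:
        p = np.full(matrix.values.shape[0], np.nan)
        q = np.full_like(p, np.nan)

    return [
        DEResult(
            transcript_id=tid,
            comparison=comparison,
            log2fc=float(l2fc[i]),
            fold_change=float(2.0 ** l2fc[i]),
            p=float(p[i]),
            q=float(q[i]),
            status=status,
        )
        for i, tid in enumerate(matrix.values.index)
    ]


@dataclass(frozen=True)
class DEFilterResult:
    """Survivors of a threshold preset, partitioned by fold-change sign."""

    preset: str
    comparison: str
    retained: tuple
    up: tuple  # log2fc > 0
    down: tuple  # log2fc < 0

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)

    @property
    def n_total(self) -> int:
        return len(self.retained)


def filter_de(results: Sequence[DEResult], preset: ThresholdPreset | str) -> DEFilterResult:
    """Apply a threshold preset; survivors split into up/down by log2fc sign."""
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise DataError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    comparisons = {r.comparison for r in results}
    if len(comparisons) > 1:
        raise DataError(f"mixed comparisons in DE results: {sorted(comparisons)}")
    comparison = comparisons.pop() if comparisons else ""
    retained = tuple(r for r in results if preset.passes(r))
    up = tuple(r for r in retained if r.log2fc > 0)
    down = tuple(r for r in retained if r.log2fc < 0)
    return DEFilterResult(
        preset=preset.name, comparison=comparison, retained=retained, up=up, down=down
    )


def enrichment_fisher(
    de_set: Set[str],
    universe: Set[str],
    gene_sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Right-tailed Fisher (hypergeometric tail) enrichment per gene set.

    p = P(X >= observed overlap) under sampling |de_set| transcripts from the
    universe; each gene set is intersected with the universe first. Returns a
    DataFrame indexed by set name with columns (n_set, n_overlap, p,
    neg_log10_p).
    """
    universe = set(universe)
    if not universe:
        raise DataError("enrichment universe is empty")
    de_set = set(de_set)
    stray = de_set - universe
    if stray:
        raise DataError(
            f"DE set contains ids outside the universe, e.g. {sorted(stray)[:3]}"
        )
    m = len(universe)
    n_draw = len(de_set)
    rows = {}
    for name, members in gene_sets.items():
        members_in = set(members) & universe
        k = len(members_in & de_set)
        p = float(stats.hypergeom.sf(k - 1, m, len(members_in), n_draw))
        p = min(p, 1.0)
        rows[name] = {
            "n_set": len(members_in),
            "n_overlap": k,
            "p": p,
            "neg_log10_p": -math.log10(p) if p > 0 else math.inf,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "comparison": r.comparison,
                "log2fc": r.log2fc,
                "fold_change": r.fold_change,
                "p": r.p,
                "q": r.q,
                "status": r.status,
            }
            for r in results
        ],
        columns=DE_TABLE_COLUMNS,
    )


def frame_to_results(frame: pd.DataFrame) -> List[DEResult]:
    missing = [c for c in DE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"DE table missing column(s): {', '.join(missing)}")
    return [
        DEResult(
            transcript_id=str(row.transcript_id),
            comparison=str(row.comparison),
            log2fc=float(row.log2fc),
            fold_change=float(row.fold_change),
            p=float(row.p),
            q=float(row.q),
            status=str(row.status),
        )
        for row in frame.itertuples()
    ]
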