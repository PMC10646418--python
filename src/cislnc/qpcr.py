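"""dCt / ddCt relative quantification for SYBR-green qPCR plates.

Normalization follows the classical comparative-Ct method: the target Ct in
each sample is referenced to the geometric mean of the reference-gene
quantities, which on the Ct (log2) scale is the arithmetic mean of the
reference Cts. ddCt is taken against the mean calibrator dCt, replicate
2^-ddCt values are kept, and significance is a Student t-test (paired or
unpaired) of the replicate 2^-ddCt values between arms, as in the source
protocol. Fold regulation maps fold changes below 1 to their negative
inverse so up- and downregulation are symmetric around +/-1.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .types import QpcrMeasurement, RelativeExpression

__all__ = [
    "normalize_ct",
    "relative_expression",
    "relative_expression_from_plate",
    "fold_regulation",
    "expression_2negdct",
]

DEFAULT_REFERENCES = ("GAPDH", "ACTB")


def normalize_ct(
    plate: Sequence[QpcrMeasurement],
    reference_targets: Sequence[str] = DEFAULT_REFERENCES,
) -> pd.DataFrame:
    """Per-well dCt = Ct_target - mean(reference Cts of the same sample).

    Reference wells are averaged within each sample (all replicates); a
    sample lacking a detected Ct for any reference target is an error naming
    both. Reference targets themselves are omitted from the output. Wells
    with an absent Ct propagate as NaN dCt (undetected).
    """
    reference_targets = tuple(reference_targets)
    if not reference_targets:
        raise DataError("at least one reference target is required")
    by_sample: Dict[str, Dict[str, List[float]]] = defaultdict(lambda: defaultdict(list))
    for w in plate:
        if w.target in reference_targets and w.ct is not None:
            by_sample[w.sample][w.target].append(w.ct)
    ref_mean: Dict[str, float] = {}
    samples = {w.sample for w in plate}
    for sample in samples:
        cts = []
        for ref in reference_targets:
            vals = by_sample[sample].get(ref, [])
            if not vals:
                raise DataError(
                    f"sample {sample!r}: missing reference Ct for {ref!r}"
                )
            cts.append(float(np.mean(vals)))
        ref_mean[sample] = float(np.mean(cts))
    rows = []
    for w in plate:
        if w.target in reference_targets:
            continue
        dct = (w.ct - ref_mean[w.sample]) if w.ct is not None else math.nan
        rows.append(
            {
                "target": w.target,
                "sample": w.sample,
                "group": w.group,
                "replicate": w.replicate,
                "ct": w.ct if w.ct is not None else math.nan,
                "dct": dct,
            }
        )
    return pd.DataFrame(rows, columns=["target", "sample", "group", "replicate", "ct", "dct"])


def _ttest_2negddct(
    treat: np.ndarray, calib: np.ndarray, paired: bool
) -> float:
    """t-test with degenerate-variance conventions: identical constant arms
    give p = 1, distinct constant arms p = 0."""
    if paired:
        diffs = treat - calib
        if np.allclose(diffs.var(ddof=0), 0.0):
            return 1.0 if np.allclose(diffs.mean(), 0.0) else 0.0
        return float(stats.ttest_rel(treat, calib).pvalue)
    if np.allclose(treat.var(ddof=0), 0.0) and np.allclose(calib.var(ddof=0), 0.0):
        return 1.0 if np.allclose(treat.mean(), calib.mean()) else 0.0
    return float(stats.ttest_ind(treat, calib).pvalue)


def relative_expression(
    dct_treatment: Sequence[float],
    dct_calibrator: Sequence[float],
    paired: bool = False,
    target: str = "",
    comparison: str = "treatment_vs_calibrator",
) -> RelativeExpression:
    """ddCt relative quantification of a treatment arm against a calibrator.

    ddCt_i = dCt_treatment_i - mean(dCt_calibrator); the calibrator
    replicates are transformed against their own mean (expected value 1) so
    both arms live on the 2^-ddCt scale for the t-test. The reported fold
    change is the mean treatment 2^-ddCt.
    """
    treat = np.asarray(dct_treatment, dtype=float)
    calib = np.asarray(dct_calibrator, dtype=float)
    if treat.size < 2 or calib.size < 2:
        raise DataError("need >= 2 replicates in both arms")
    if np.isnan(treat).any() or np.isnan(calib).any():
        raise DataError("undetected (NaN) dCt replicate in relative expression input")
    if paired and treat.size != calib.size:
        raise DataError("paired test requires equal replicate counts")
    cal_mean = calib.mean()
    treat_vals = 2.0 ** -(treat - cal_mean)
    calib_vals = 2.0 ** -(calib - cal_mean)
    fold = float(treat_vals.mean())
    se = float(treat_vals.std(ddof=1) / math.sqrt(treat_vals.size))
    p = _ttest_2negddct(treat_vals, calib_vals, paired)
    return RelativeExpression(
        target=target,
        comparison=comparison,
        replicate_2neg_ddct=tuple(float(v) for v in treat_vals),
        calibrator_2neg_ddct=tuple(float(v) for v in calib_vals),
        mean=fold,
        se=se,
        fold_change=fold,
        fold_regulation=fold_regulation(fold),
        p=p,
        paired=paired,
    )


def relative_expression_from_plate(
    plate: Sequence[QpcrMeasurement],
    target: str,
    treatment_group: str,
    calibrator_group: str,
    reference_targets: Sequence[str] = DEFAULT_REFERENCES,
    paired: bool = False,
) -> RelativeExpression:
    """Convenience chain: normalize a plate, then ddCt for one target."""
    dct = normalize_ct(plate, reference_targets)
    sub = dct[dct["target"] == target]
    if sub.empty:
        raise DataError(f"target {target!r} not on plate")
    treat = sub.loc[sub["group"] == treatment_group, "dct"].to_numpy()
    calib = sub.loc[sub["group"] == calibrator_group, "dct"].to_numpy()
    if treat.size == 0 or calib.size == 0:
        raise DataError(
            f"target {target!r}: group {treatment_group!r} or "
            f"{calibrator_group!r} absent from plate"
        )
    return relative_expression(
        treat,
        calib,
        paired=paired,
        target=target,
        comparison=f"{treatment_group}_vs_{calibrator_group}",
    )


def fold_regulation(fold_change: float) -> float:
    """Identity above 1, negative inverse below 1 (0.25 -> -4); |result| >= 1."""
    if not fold_change > 0:
        raise DataError(f"fold change must be positive, got {fold_change}")
    return fold_change if fold_change >= 1 else -1.0 / fold_change


def expression_2negdct(dct: float) -> float:
    """Normalized expression on the 2^-dCt scale."""
    return float(2.0 ** -dct)
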