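"""Synthetic fixtures with planted ground truth.

Everything downstream of read alignment is exercised against data generated
here: a single synthetic chromosome with lncRNA/mRNA isoforms, a three-group
(Islet / PBS graft / ALT graft) FPKM matrix with planted differential
expression, a multi-tissue panel with planted islet-specific transcripts, a
qPCR plate following Ct = intercept - log2(abundance) + noise, and
Annexin-V/PI flow events drawn from a four-population multinomial mixture.

The layout places each transcript in its own widely spaced slot so that the
only lncRNA-mRNA proximities are the planted ones: pair lncRNAs sit at a
controlled distance (<= 50 kb) from their partner mRNA TSS, decoys sit
60-120 kb away (past the screen but nearest to that mRNA), and all other
transcripts are hundreds of kb from everything. Expression noise is
log-normal: Gaussian on the log2 scale around group means, so zero noise
reproduces every planted quantity exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cis import pair_distance
from .errors import ConfigError, DataError
from .matrix import ExpressionMatrix, TissuePanel
from .types import QpcrMeasurement, TranscriptRecord

__all__ = [
    "TruthConfig",
    "Annotation",
    "SimExpression",
    "FlowEvents",
    "generate_annotation",
    "generate_expression",
    "generate_qpcr_plate",
    "generate_flow_events",
    "generate_correlated_fold_changes",
]

DECOY_DISTANCE_RANGE = (60_000, 120_000)
_DEFAULT_TISSUES = (
    "islet",
    "heart",
    "liver",
    "lung",
    "kidney",
    "spleen",
    "thymus",
    "muscle",
    "brain",
)


@dataclass(frozen=True)
class TruthConfig:
    """All knobs of the generator; the defaults are the study conditions.

    Planted |log2FC| is 2.5 with log2 noise sd 0.3 and triplicate groups;
    the PBS graft group sits at half the planted effect so monotone
    Islet > PBS > ALT (and the reverse) patterns arise by construction.
    """

    seed: int = 0
    n_mrna: int = 40
    n_lncrna: int = 30
    n_pairs_planted: int = 5
    pair_distance_range: Tuple[int, int] = (1_000, 40_000)
    n_decoy_pairs: int = 3
    n_antisense_pairs: int = 0
    n_up_mrna: int = 8
    n_down_mrna: int = 8
    n_up_lncrna: int = 6
    n_down_lncrna: int = 6
    effect_log2fc: float = 2.5
    noise_sd_log2: float = 0.3
    n_replicates: int = 3
    tissue_panel: Tuple[str, ...] = _DEFAULT_TISSUES
    n_islet_specific: int = 10
    specificity_factor_planted: float = 4.0
    groups: Tuple[str, str, str] = ("Islet", "PBS", "ALT")
    chrom: str = "chrS"
    chrom_length: Optional[int] = None
    slot_bp: int = 400_000
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 1.5
    ct_intercept: float = 35.0
    ct_detection_limit: float = 40.0

    def validate(self) -> None:
        c = self
        if c.n_mrna < 1 or c.n_lncrna < 1:
            raise ConfigError("need at least one mRNA and one lncRNA")
        if c.n_pairs_planted + c.n_decoy_pairs > c.n_lncrna:
            raise ConfigError("n_pairs_planted + n_decoy_pairs exceeds n_lncrna")
        lo, hi = c.pair_distance_range
        if not (0 <= lo <= hi <= 50_000):
            raise ConfigError("pair_distance_range must lie within [0, 50000]")
        if c.n_antisense_pairs > c.n_pairs_planted:
            raise ConfigError("n_antisense_pairs exceeds n_pairs_planted")
        if c.n_up_mrna + c.n_down_mrna > c.n_mrna:
            raise ConfigError("planted DE mRNAs exceed n_mrna")
        if c.n_up_lncrna + c.n_down_lncrna > c.n_lncrna:
            raise ConfigError("planted DE lncRNAs exceed n_lncrna")
        if c.n_pairs_planted + c.n_decoy_pairs > c.n_up_lncrna + c.n_down_lncrna:
            raise ConfigError("pair and decoy lncRNAs must all be planted DE")
        if c.n_pairs_planted > c.n_up_mrna + c.n_down_mrna:
            raise ConfigError("pair partner mRNAs must all be planted DE")
        if c.n_pairs_planted + c.n_decoy_pairs > c.n_mrna:
            raise ConfigError("not enough mRNA slots for distinct pair/decoy partners")
        if c.effect_log2fc <= 0:
            raise ConfigError("effect_log2fc must be positive")
        if c.noise_sd_log2 < 0:
            raise ConfigError("noise_sd_log2 must be nonnegative")
        if c.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if "islet" not in c.tissue_panel or len(c.tissue_panel) < 2:
            raise ConfigError("tissue_panel must contain 'islet' plus other tissues")
        if c.n_islet_specific > c.n_lncrna:
            raise ConfigError("n_islet_specific exceeds n_lncrna")
        if not c.specificity_factor_planted > 2:
            raise ConfigError("specificity_factor_planted must exceed 2")
        if c.slot_bp < 2 * (DECOY_DISTANCE_RANGE[1] + 5_000):
            raise ConfigError("slot_bp too small to isolate decoys from neighbors")
        if c.chrom_length is not None and c.chrom_length < self.required_length():
            raise ConfigError(
                f"infeasible placement: chrom_length {c.chrom_length} < required "
                f"{self.required_length()} for this many transcripts"
            )

    def required_length(self) -> int:
        n_extra_lnc = self.n_lncrna - self.n_pairs_planted - self.n_decoy_pairs
        return self.slot_bp * (self.n_mrna + n_extra_lnc + 2)


@dataclass
class Annotation:
    """Generated transcript records plus the planted truth tables."""

    records: List[TranscriptRecord]
    transcripts: pd.DataFrame  # transcript_id, biotype, direction, islet_specific
    pairs: pd.DataFrame  # lnc_id, mrna_id, signed_distance, is_decoy, antisense
    config: TruthConfig

    def by_id(self) -> Dict[str, TranscriptRecord]:
        return {r.transcript_id: r for r in self.records}

    def planted_pair_ids(self) -> set:
        true_pairs = self.pairs[~self.pairs["is_decoy"]]
        return set(zip(true_pairs["lnc_id"], true_pairs["mrna_id"]))


def _directions(n: int, n_up: int, n_down: int) -> List[int]:
    return [1] * n_up + [-1] * n_down + [0] * (n - n_up - n_down)


def generate_annotation(cfg: TruthConfig) -> Annotation:
    """Place transcripts on the synthetic chromosome and record pair truth."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 11])
    slot = cfg.slot_bp

    mrna_dirs = _directions(cfg.n_mrna, cfg.n_up_mrna, cfg.n_down_mrna)
    lnc_dirs = _directions(cfg.n_lncrna, cfg.n_up_lncrna, cfg.n_down_lncrna)

    records: List[TranscriptRecord] = []
    mrna_recs: List[TranscriptRecord] = []
    for i in range(cfg.n_mrna):
        tss = (i + 1) * slot
        length = int(rng.integers(800, 2001))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = tss, tss + length
        else:
            start, end = tss + 1 - length, tss + 1
        rec = TranscriptRecord(
            transcript_id=f"mRNA_{i:04d}",
            gene_id=f"gene_m{i:04d}",
            biotype="mRNA",
            chrom=cfg.chrom,
            start=start,
            end=end,
            strand=strand,
        )
        records.append(rec)
        mrna_recs.append(rec)

    pair_rows = []
    lnc_recs: List[TranscriptRecord] = []

    def _make_lnc(idx: int, start: int, end: int, strand: str) -> TranscriptRecord:
        rec = TranscriptRecord(
            transcript_id=f"lnc_{idx:04d}",
            gene_id=f"gene_l{idx:04d}",
            biotype="lncRNA",
            chrom=cfg.chrom,
            start=start,
            end=end,
            strand=strand,
        )
        lnc_recs.append(rec)
        records.append(rec)
        return rec

    lo, hi = cfg.pair_distance_range
    for j in range(cfg.n_pairs_planted):
        partner = mrna_recs[j]
        t = partner.tss
        length = int(rng.integers(500, 1501))
        antisense = j < cfg.n_antisense_pairs
        d = int(rng.integers(lo, hi + 1))
        if antisense or d == 0:
            # overlap the partner TSS on the opposite strand
            start = t - length // 2
            end = start + length
            strand = "-" if partner.strand == "+" else "+"
            antisense = True
        else:
            # upstream side of the mRNA (away from the gene body) whenever the
            # planted gap could collide with the body; otherwise either side
            body_side_free = d > partner.length + 1
            go_right = body_side_free and rng.random() < 0.5
            if partner.strand == "-":
                go_right = not go_right
            if go_right:
                start, end = t + d, t + d + length
            else:
                start, end = t - d - length, t - d
            strand = "+" if rng.random() < 0.5 else "-"
        rec = _make_lnc(j, start, end, strand)
        signed = pair_distance(rec, partner)
        pair_rows.append(
            {
                "lnc_id": rec.transcript_id,
                "mrna_id": partner.transcript_id,
                "signed_distance": signed,
                "is_decoy": False,
                "antisense": antisense,
            }
        )

    for k in range(cfg.n_decoy_pairs):
        idx = cfg.n_pairs_planted + k
        partner = mrna_recs[idx]
        t = partner.tss
        length = int(rng.integers(500, 1501))
        d = int(rng.integers(*DECOY_DISTANCE_RANGE))
        if rng.random() < 0.5:
            start, end = t + d, t + d + length
        else:
            start, end = t - d - length, t - d
        strand = "+" if rng.random() < 0.5 else "-"
        rec = _make_lnc(idx, start, end, strand)
        pair_rows.append(
            {
                "lnc_id": rec.transcript_id,
                "mrna_id": partner.transcript_id,
                "signed_distance": pair_distance(rec, partner),
                "is_decoy": True,
                "antisense": False,
            }
        )

    n_placed = cfg.n_pairs_planted + cfg.n_decoy_pairs
    for m in range(n_placed, cfg.n_lncrna):
        anchor = (cfg.n_mrna + (m - n_placed) + 1) * slot
        length = int(rng.integers(500, 1501))
        strand = "+" if rng.random() < 0.5 else "-"
        _make_lnc(m, anchor, anchor + length, strand)

    specific_ids = {r.transcript_id for r in lnc_recs[-cfg.n_islet_specific:]} if cfg.n_islet_specific else set()
    transcripts = pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "biotype": [r.biotype for r in records],
            "direction": (
                [{1: "up", -1: "down", 0: "none"}[d] for d in mrna_dirs]
                + [{1: "up", -1: "down", 0: "none"}[d] for d in lnc_dirs]
            ),
            "islet_specific": [r.transcript_id in specific_ids for r in records],
        }
    )
    pairs = pd.DataFrame(
        pair_rows,
        columns=["lnc_id", "mrna_id", "signed_distance", "is_decoy", "antisense"],
    )
    return Annotation(records=records, transcripts=transcripts, pairs=pairs, config=cfg)


@dataclass
class SimExpression:
    """Expression matrix, tissue panel, and the matching truth tables."""

    matrix: ExpressionMatrix
    de_truth: pd.DataFrame  # transcript_id, direction, planted log2fc per comparison
    tissue_panel: TissuePanel
    specificity_truth: pd.DataFrame  # transcript_id, planted_specific


def generate_expression(annotation: Annotation, cfg: Optional[TruthConfig] = None) -> SimExpression:
    """Log-normal FPKM replicates around planted group means.

    Group means on the log2 scale are baseline (Islet), baseline +/- half the
    planted effect (PBS graft) and baseline +/- the full effect (ALT graft)
    for up/down transcripts; null transcripts share one mean across groups.
    Baseline log2 abundance is clipped to [2.5, 9] — the expressed-transcript
    range in which a pseudocount of 1 does not erode the planted fold change.
    """
    cfg = cfg or annotation.config
    rng = np.random.default_rng([cfg.seed, 23])
    tx = annotation.transcripts
    n_tx = len(tx)
    base = np.clip(
        rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n_tx), 2.5, 9.0
    )
    dir_num = tx["direction"].map({"up": 1.0, "down": -1.0, "none": 0.0}).to_numpy()
    group_shift = {
        cfg.groups[0]: 0.0,
        cfg.groups[1]: 0.5 * cfg.effect_log2fc,
        cfg.groups[2]: cfg.effect_log2fc,
    }
    columns, data, sheet_rows = [], [], []
    for group in cfg.groups:
        mean_log2 = base + dir_num * group_shift[group]
        for r in range(cfg.n_replicates):
            noise = (
                rng.normal(0.0, cfg.noise_sd_log2, size=n_tx)
                if cfg.noise_sd_log2 > 0
                else np.zeros(n_tx)
            )
            sample = f"{group}_{r + 1}"
            columns.append(sample)
            data.append(2.0 ** (mean_log2 + noise))
            sheet_rows.append({"sample": sample, "group": group, "replicate": r + 1})
    values = pd.DataFrame(
        np.column_stack(data), index=tx["transcript_id"], columns=columns
    )
    matrix = ExpressionMatrix(values, pd.DataFrame(sheet_rows))

    g0, g1, g2 = cfg.groups
    e = cfg.effect_log2fc
    de_truth = pd.DataFrame(
        {
            "transcript_id": tx["transcript_id"],
            "biotype": tx["biotype"],
            "direction": tx["direction"],
            f"log2fc_{g1}_vs_{g0}": dir_num * (e / 2),
            f"log2fc_{g2}_vs_{g0}": dir_num * e,
            f"log2fc_{g2}_vs_{g1}": dir_num * (e / 2),
        }
    )

    # tissue panel over lncRNA isoforms with planted islet-specific rows
    lnc_mask = (tx["biotype"] == "lncRNA").to_numpy()
    lnc_ids = tx.loc[lnc_mask, "transcript_id"].to_numpy()
    islet_vals = 2.0 ** base[lnc_mask]
    specific = tx.loc[lnc_mask, "islet_specific"].to_numpy()
    others = [t for t in cfg.tissue_panel if t != "islet"]
    panel = {"islet": islet_vals}
    factor = cfg.specificity_factor_planted
    # planted-specific rows: every other tissue is below islet/factor by a
    # further margin; non-specific rows get one tissue within 2x of islet
    dominant = rng.integers(0, len(others), size=islet_vals.size)
    for ti, tissue in enumerate(others):
        u = rng.uniform(1.2, 4.0, size=islet_vals.size)
        vals = islet_vals / (factor * u)
        near = rng.uniform(0.6, 1.5, size=islet_vals.size)
        low = rng.uniform(0.01, 0.55, size=islet_vals.size)
        nonspec = np.where(dominant == ti, near, low) * islet_vals
        panel[tissue] = np.where(specific, vals, nonspec)
    panel_df = pd.DataFrame(panel, index=pd.Index(lnc_ids, name="transcript_id"))
    tissue_panel = TissuePanel(panel_df, focal_tissue="islet")
    specificity_truth = pd.DataFrame(
        {"transcript_id": lnc_ids, "planted_specific": specific}
    )
    return SimExpression(
        matrix=matrix,
        de_truth=de_truth,
        tissue_panel=tissue_panel,
        specificity_truth=specificity_truth,
    )


def generate_qpcr_plate(
    abundance: Mapping[str, Mapping[str, float]],
    n_replicates: int = 3,
    ct_noise_sd: float = 0.15,
    intercept: float = 35.0,
    detection_limit: float = 40.0,
    seed: int = 0,
) -> List[QpcrMeasurement]:
    """Triplicate-style plate with Ct = intercept - log2(abundance) + noise.

    ``abundance[target][group]`` gives the relative quantity of each target
    in each group; reference genes are modelled by giving them equal
    abundance across groups. Nonpositive abundance, or a noisy Ct at or past
    the detection limit, is emitted as an absent Ct.
    """
    rng = np.random.default_rng([seed, 37])
    plate: List[QpcrMeasurement] = []
    for target, per_group in abundance.items():
        for group, a in per_group.items():
            for r in range(1, n_replicates + 1):
                if a <= 0:
                    ct = None
                else:
                    noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                    raw = intercept - math.log2(a) + noise
                    ct = None if raw >= detection_limit else float(raw)
                plate.append(
                    QpcrMeasurement(
                        target=target,
                        sample=f"{group}_{r}",
                        group=group,
                        replicate=r,
                        ct=ct,
                    )
                )
    return plate


@dataclass
class FlowEvents:
    """Simulated Annexin-V/PI events plus the drawn quadrant truth counts."""

    events: pd.DataFrame  # event_id, annexin, pi
    truth_counts: Dict[str, int]
    labeling: str


_NEG_MU, _POS_MU, _INTENSITY_SD = math.log(100.0), math.log(10_000.0), 0.3


def generate_flow_events(
    proportions: Mapping[str, float] | Sequence[float],
    n_events: int,
    seed: int = 0,
    labeling: str = "methods",
) -> FlowEvents:
    """Multinomial draw over {viable, early, late, necrotic} with
    well-separated log-normal stain intensities per quadrant."""
    if not isinstance(proportions, Mapping):
        proportions = dict(zip(("viable", "early", "late", "necrotic"), proportions))
    keys = ("viable", "early", "late", "necrotic")
    missing = [k for k in keys if k not in proportions]
    if missing:
        raise DataError(f"proportions missing population(s): {', '.join(missing)}")
    probs = np.array([float(proportions[k]) for k in keys])
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise DataError("proportions must be nonnegative and sum to 1 (tol 1e-9)")
    if labeling == "methods":
        signatures = {"viable": (0, 0), "early": (1, 0), "late": (1, 1), "necrotic": (0, 1)}
    elif labeling == "legend":
        signatures = {"viable": (0, 0), "early": (1, 0), "late": (0, 1), "necrotic": (1, 1)}
    else:
        raise DataError(f"unknown labeling {labeling!r}")
    rng = np.random.default_rng([seed, 53])
    counts = rng.multinomial(n_events, probs)
    truth = dict(zip(keys, (int(c) for c in counts)))
    rows_a, rows_p = [], []
    for key, c in truth.items():
        a_pos, p_pos = signatures[key]
        mu_a = _POS_MU if a_pos else _NEG_MU
        mu_p = _POS_MU if p_pos else _NEG_MU
        rows_a.append(np.exp(rng.normal(mu_a, _INTENSITY_SD, size=c)))
        rows_p.append(np.exp(rng.normal(mu_p, _INTENSITY_SD, size=c)))
    annexin = np.concatenate(rows_a) if rows_a else np.array([])
    pi = np.concatenate(rows_p) if rows_p else np.array([])
    order = rng.permutation(n_events)
    events = pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "annexin": annexin[order],
            "pi": pi[order],
        }
    )
    return FlowEvents(events=events, truth_counts=truth, labeling=labeling)


def generate_correlated_fold_changes(
    rho: float, n: int, seed: int = 0, scale: float = 1.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Bivariate-normal (lncRNA, mRNA) log2 fold changes with correlation
    ``rho`` — the oracle input for correlation-recovery checks."""
    if not -1.0 <= rho <= 1.0:
        raise ConfigError("rho must be in [-1, 1]")
    rng = np.random.default_rng([seed, 71])
    cov = scale**2 * np.array([[1.0, rho], [rho, 1.0]])
    xy = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    return xy[:, 0], xy[:, 1]
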