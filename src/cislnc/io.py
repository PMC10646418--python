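"""Readers and writers for the standard interchange formats.

Annotation moves as GTF (attributes transcript_id, gene_id, biotype) and
BED6; expression as a TSV matrix plus a sample sheet; DE results, cis pairs,
qPCR plates and specificity calls as TSV; pair intervals as BEDPE; gene sets
as GMT; summaries as JSON. ``load_table`` gives schema-checked TSV loading
with errors that name the offending column.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .cis import parse_locus
from .errors import DataError
from .matrix import TissuePanel
from .types import CisPair, QpcrMeasurement, TranscriptRecord

__all__ = [
    "load_table",
    "write_gtf",
    "read_gtf",
    "write_bed6",
    "write_bedpe",
    "pairs_to_frame",
    "write_gmt",
    "read_gmt",
    "plate_to_frame",
    "frame_to_plate",
    "write_json",
    "load_table1",
    "table1_records",
    "table1_panel",
]

TABLE1_RESOURCE = "table1_islet_lncrnas.tsv"


def load_table(path, required: Sequence[str], sep: str = "\t") -> pd.DataFrame:
    """Read a delimited table and validate that the required columns exist."""
    frame = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DataError(
            f"{path}: missing required column(s): {', '.join(missing)} "
            f"(found: {', '.join(frame.columns)})"
        )
    return frame


# ---------------------------------------------------------------- annotation

def write_gtf(records: Iterable[TranscriptRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            attrs = (
                f'transcript_id "{r.transcript_id}"; gene_id "{r.gene_id}"; '
                f'biotype "{r.biotype}";'
            )
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        "cislnc",
                        "transcript",
                        str(r.start + 1),  # GTF is 1-based inclusive
                        str(r.end),
                        ".",
                        r.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gtf(path) -> List[TranscriptRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    records = []
    for feat in db.all_features():
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
            biotype = feat.attributes["biotype"][0]
        except KeyError as exc:
            raise DataError(f"{path}: GTF feature missing attribute {exc}")
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=gid,
                biotype=biotype,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return records


def write_bed6(records: Iterable[TranscriptRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.transcript_id}\t0\t{r.strand}\n"
            )


# --------------------------------------------------------------------- pairs

PAIR_COLUMNS = [
    "lnc_id",
    "mrna_id",
    "chrom",
    "signed_distance",
    "lnc_log2fc",
    "mrna_log2fc",
    "pattern",
    "antisense_flag",
]


def pairs_to_frame(pairs: Sequence[CisPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_id": p.lnc_id,
                "mrna_id": p.mrna_id,
                "chrom": p.chrom,
                "signed_distance": p.signed_distance,
                "lnc_log2fc": p.lnc_log2fc,
                "mrna_log2fc": p.mrna_log2fc,
                "pattern": p.pattern,
                "antisense_flag": p.antisense_flag,
            }
            for p in pairs
        ],
        columns=PAIR_COLUMNS,
    )


def write_bedpe(
    pairs: Sequence[CisPair], annotation: Mapping[str, TranscriptRecord], path
) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            ln, mr = annotation[p.lnc_id], annotation[p.mrna_id]
            fh.write(
                "\t".join(
                    [
                        ln.chrom,
                        str(ln.start),
                        str(ln.end),
                        mr.chrom,
                        str(mr.start),
                        str(mr.end),
                        f"{p.lnc_id}|{p.mrna_id}",
                        str(p.signed_distance),
                        ln.strand,
                        mr.strand,
                    ]
                )
                + "\n"
            )


# ----------------------------------------------------------------- gene sets

def write_gmt(gene_sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_gmt(path) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{n}: GMT line needs name, description, members")
            sets[fields[0]] = [m for m in fields[2:] if m]
    return sets


# --------------------------------------------------------------------- qPCR

PLATE_COLUMNS = ["target", "sample", "group", "replicate", "ct"]


def plate_to_frame(plate: Sequence[QpcrMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "target": w.target,
                "sample": w.sample,
                "group": w.group,
                "replicate": w.replicate,
                "ct": w.ct if w.ct is not None else "",
            }
            for w in plate
        ],
        columns=PLATE_COLUMNS,
    )


def frame_to_plate(frame: pd.DataFrame) -> List[QpcrMeasurement]:
    missing = [c for c in PLATE_COLUMNS if c not in frame.columns]
    if missing:
        raise DataError(f"plate table missing column(s): {', '.join(missing)}")
    plate = []
    for row in frame.itertuples():
        ct = row.ct
        if ct is None or ct == "" or (isinstance(ct, float) and pd.isna(ct)):
            ct_val: Optional[float] = None
        else:
            ct_val = float(ct)
        plate.append(
            QpcrMeasurement(
                target=str(row.target),
                sample=str(row.sample),
                group=str(row.group),
                replicate=int(row.replicate),
                ct=ct_val,
            )
        )
    return plate


# --------------------------------------------------------------------- JSON

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ------------------------------------------------------- packaged fixture

TABLE1_COLUMNS = [
    "transcript_id",
    "gene_id",
    "n_isoforms",
    "locus_hg19",
    "strand",
    "locus_class",
    "fpkm_islet",
    "fpkm_pbs_graft",
    "fpkm_alt_graft",
    "noncode_top_tissue",
    "noncode_top_fpkm",
    "nearest_genes",
]


def load_table1() -> pd.DataFrame:
    """The packaged islet-lncRNA reference table (10 isoforms): locus,
    strand, per-group FPKM, and the top-expressing other tissue with its
    FPKM from the public body-map compilation."""
    ref = resources.files("cislnc.data").joinpath(TABLE1_RESOURCE)
    with resources.as_file(ref) as path:
        return load_table(path, TABLE1_COLUMNS)


def table1_records(frame: Optional[pd.DataFrame] = None) -> List[TranscriptRecord]:
    frame = load_table1() if frame is None else frame
    records = []
    for row in frame.itertuples():
        chrom, start, end = parse_locus(row.locus_hg19)
        records.append(
            TranscriptRecord(
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                biotype="lncRNA",
                chrom=chrom,
                start=start,
                end=end,
                strand=row.strand,
            )
        )
    return records


def table1_panel(frame: Optional[pd.DataFrame] = None) -> TissuePanel:
    """Two-tissue panel per isoform: islet FPKM against the top-expressing
    other tissue's FPKM (the strongest competitor, which is all the strict
    more-than-double rule needs)."""
    frame = load_table1() if frame is None else frame
    values = pd.DataFrame(
        {
            "islet": frame["fpkm_islet"].to_numpy(),
            "top_other_tissue": frame["noncode_top_fpkm"].to_numpy(),
        },
        index=pd.Index(frame["transcript_id"], name="transcript_id"),
    )
    return TissuePanel(values, focal_tissue="islet")
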