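"""File formats: multi-page TIFF stacks, integer-label TIFF masks, tidy CSV
for traces and wells, VCF/CSV for variant tables, JSON drop reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .core import InputError, ShapeError, Trace, WellTrace
from .extraction import RoiMaskSet
from .variants import ANNOTATION_COLUMNS, FilterResult

__all__ = [
    "write_stack_tiff",
    "read_stack_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
    "traces_to_frame",
    "frame_to_traces",
    "write_traces_csv",
    "read_traces_csv",
    "wells_to_frame",
    "frame_to_wells",
    "write_wells_csv",
    "read_wells_csv",
    "read_variant_table",
    "read_variant_vcf",
    "read_variant_csv",
    "write_variant_csv",
    "write_variant_vcf",
    "write_filter_report",
]


# ---------------------------------------------------------------------------
# TIFF
# ---------------------------------------------------------------------------

def write_stack_tiff(path: str | Path, stack: np.ndarray) -> None:
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ShapeError("stack must be (frames, height, width)")
    tifffile.imwrite(path, stack.astype(np.float32))


def read_stack_tiff(path: str | Path) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return np.asarray(stack, dtype=float)


def write_mask_tiff(path: str | Path, masks: RoiMaskSet) -> None:
    tifffile.imwrite(path, masks.label_image.astype(np.int32))


def read_mask_tiff(path: str | Path) -> RoiMaskSet:
    return RoiMaskSet(label_image=np.asarray(tifffile.imread(path)))


# ---------------------------------------------------------------------------
# Trace / well CSV (tidy long format)
# ---------------------------------------------------------------------------

def traces_to_frame(traces: Sequence[Trace]) -> pd.DataFrame:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "id": tr.id,
                    "group": tr.group if tr.group is not None else "",
                    "time_s": tr.time_s,
                    "value": tr.values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_traces(frame: pd.DataFrame) -> list[Trace]:
    required = {"id", "time_s", "value"}
    if not required <= set(frame.columns):
        raise InputError(f"trace table needs columns {sorted(required)}")
    traces = []
    for tid, sub in frame.groupby("id", sort=True):
        sub = sub.sort_values("time_s")
        group = None
        if "group" in sub.columns:
            g = sub["group"].iloc[0]
            group = None if pd.isna(g) or g == "" else str(g)
        traces.append(
            Trace(
                id=str(tid),
                time_s=sub["time_s"].to_numpy(float),
                values=sub["value"].to_numpy(float),
                group=group,
            )
        )
    return traces


def write_traces_csv(path: str | Path, traces: Sequence[Trace]) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[Trace]:
    return frame_to_traces(pd.read_csv(path))


def wells_to_frame(wells: Sequence[WellTrace]) -> pd.DataFrame:
    frames = []
    for w in wells:
        frames.append(
            pd.DataFrame(
                {
                    "well_id": w.well_id,
                    "group": w.group if w.group is not None else "",
                    "stimulus": w.stimulus,
                    "time_s": w.time_s,
                    "f340": w.f340,
                    "f380": w.f380,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_wells(frame: pd.DataFrame) -> list[WellTrace]:
    required = {"well_id", "time_s", "f340", "f380"}
    if not required <= set(frame.columns):
        raise InputError(f"well table needs columns {sorted(required)}")
    wells = []
    for wid, sub in frame.groupby("well_id", sort=True):
        sub = sub.sort_values("time_s")
        group = None
        if "group" in sub.columns and not pd.isna(sub["group"].iloc[0]):
            group = str(sub["group"].iloc[0]) or None
        stim = "other"
        if "stimulus" in sub.columns and not pd.isna(sub["stimulus"].iloc[0]):
            stim = str(sub["stimulus"].iloc[0])
        wells.append(
            WellTrace(
                well_id=str(wid),
                time_s=sub["time_s"].to_numpy(float),
                f340=sub["f340"].to_numpy(float),
                f380=sub["f380"].to_numpy(float),
                group=group,
                stimulus=stim,
            )
        )
    return wells


def write_wells_csv(path: str | Path, wells: Sequence[WellTrace]) -> None:
    wells_to_frame(wells).to_csv(path, index=False)


def read_wells_csv(path: str | Path) -> list[WellTrace]:
    return frame_to_wells(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def _samples_of(table: pd.DataFrame) -> list[str]:
    return [c[3:] for c in table.columns if c.startswith("gt_")]


def write_variant_csv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_variant_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"variant CSV missing columns: {missing}")
    table["in_dbsnp"] = table["in_dbsnp"].astype(bool)
    return table


def write_variant_vcf(path: str | Path, table: pd.DataFrame) -> None:
    """Write the table as a minimal VCF 4.2 file.

    Annotations go to INFO (CSQ = consequence class, FREQ = subpopulation
    frequency, CADD = scaled score, DB flag = dbSNP membership); genotypes
    to per-sample GT fields.
    """
    samples = _samples_of(table)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">',
        '##INFO=<ID=FREQ,Number=1,Type=Float,Description="Subpopulation allele frequency">',
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="Scaled CADD score">',
        '##INFO=<ID=DB,Number=0,Type=Flag,Description="In dbSNP">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for _, row in table.iterrows():
        info = [f"CSQ={row['consequence']}"]
        if pd.notna(row["pop_freq"]):
            info.append(f"FREQ={float(row['pop_freq']):g}")
        if pd.notna(row["cadd"]):
            info.append(f"CADD={float(row['cadd']):g}")
        if bool(row["in_dbsnp"]):
            info.append("DB")
        gts = [str(row.get(f"gt_{s}", "./.")) for s in samples]
        lines.append(
            "\t".join(
                [
                    str(row["chrom"]),
                    str(int(row["pos"])),
                    "rs0" if bool(row["in_dbsnp"]) else ".",
                    str(row["ref"]),
                    str(row["alt"]),
                    ".",
                    "PASS",
                    ";".join(info),
                    "GT",
                    *gts,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_variant_vcf(
    path: str | Path,
    csq_key: str = "CSQ",
    freq_key: str = "FREQ",
    cadd_key: str = "CADD",
) -> pd.DataFrame:
    """Read an annotated VCF into the flat variant-table layout.

    Multi-allelic records are refused: split them (e.g. ``bcftools norm -m-``)
    before filtering. dbSNP membership is taken from the DB INFO flag or a
    non-missing ID.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise InputError(
                f"{rec.CHROM}:{rec.POS} has {len(rec.ALT)} ALT alleles; "
                "split multi-allelic records before filtering"
            )
        freq = rec.INFO.get(freq_key)
        cadd = rec.INFO.get(cadd_key)
        row = {
            "chrom": rec.CHROM,
            "pos": rec.POS,
            "ref": rec.REF,
            "alt": rec.ALT[0],
            "consequence": rec.INFO.get(csq_key, ""),
            "in_dbsnp": bool(rec.INFO.get("DB"))
            or (rec.ID not in (None, ".")),
            "pop_freq": np.nan if freq is None else float(freq),
            "cadd": np.nan if cadd is None else float(cadd),
        }
        for sample, gt in zip(samples, rec.gt_types):
            # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
            row[f"gt_{sample}"] = {0: "0/0", 1: "0/1", 2: "./.", 3: "1/1"}[
                int(gt)
            ]
        rows.append(row)
    cols = list(ANNOTATION_COLUMNS) + [f"gt_{s}" for s in samples]
    return pd.DataFrame(rows, columns=cols)


def read_variant_table(path: str | Path, **vcf_kwargs) -> pd.DataFrame:
    """Dispatch on extension: ``.vcf`` via cyvcf2, anything else as CSV."""
    p = Path(path)
    if p.suffix.lower() in {".vcf", ".gz", ".bcf"}:
        return read_variant_vcf(p, **vcf_kwargs)
    return read_variant_csv(p)


def write_filter_report(path: str | Path, result: FilterResult) -> None:
    report = {
        "n_retained": result.n_retained,
        "n_dropped": result.n_dropped,
        "drop_reason_counts": result.reason_counts,
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
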