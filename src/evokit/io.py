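"""Readers and writers for the plain-text formats shared by the stages.

Genome layouts are a directory of three files: ``genome.txt`` (length +
circular flag), ``scars.bed`` (0-based half-open width-1 intervals for the
junction points) and ``genes.tsv``. OD curves travel as wide CSV with a
``time_min`` first column; everything else is TSV.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .growth import GrowthCurve, TransferLog
from .mutbias import MutationRecord
from .periodicity import ExpressionProfile
from .simulate import Gene, GenomeLayout

GENOME_FILE = "genome.txt"
SCAR_FILE = "scars.bed"
GENE_FILE = "genes.tsv"


# -- genome layout -----------------------------------------------------------

def write_layout(layout: GenomeLayout, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / GENOME_FILE).write_text(
        f"length\t{layout.length}\ncircular\t{str(layout.circular).lower()}\n"
    )
    with open(outdir / SCAR_FILE, "w") as fh:
        for i, s in enumerate(layout.scars, start=1):
            # 1-based junction point -> 0-based half-open interval of width 1
            fh.write(f"genome\t{s - 1}\t{s}\tscar{i}\n")
    rows = [
        {
            "gene_id": g.gene_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "essential": int(g.essential),
            "category": g.category,
            "regulons": ",".join(g.regulons),
        }
        for g in layout.genes
    ]
    pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand",
                                "essential", "category", "regulons"]).to_csv(
        outdir / GENE_FILE, sep="\t", index=False
    )


def read_layout(indir) -> GenomeLayout:
    indir = Path(indir)
    meta = dict(
        line.split("\t")
        for line in (indir / GENOME_FILE).read_text().strip().splitlines()
    )
    length = int(meta["length"])
    circular = meta.get("circular", "true").lower() == "true"
    scars = []
    scar_path = indir / SCAR_FILE
    if scar_path.exists():
        for line in scar_path.read_text().strip().splitlines():
            if not line:
                continue
            _, start0, end0 = line.split("\t")[:3]
            scars.append(int(start0) + 1)  # back to 1-based point
    genes = []
    gene_path = indir / GENE_FILE
    if gene_path.exists():
        df = pd.read_csv(gene_path, sep="\t", keep_default_na=False)
        for row in df.itertuples(index=False):
            regs = tuple(r for r in str(row.regulons).split(",") if r)
            genes.append(
                Gene(
                    gene_id=str(row.gene_id),
                    start=int(row.start),
                    end=int(row.end),
                    strand=str(row.strand),
                    essential=bool(int(row.essential)),
                    category=str(row.category),
                    regulons=regs,
                )
            )
    return GenomeLayout(length=length, circular=circular,
                        scars=tuple(sorted(scars)), genes=tuple(genes))


# -- plate-reader OD ---------------------------------------------------------

def write_plate_csv(curves, path) -> None:
    """Wide CSV: time_min first, one column per curve (replicate id)."""
    curves = list(curves)
    times = curves[0].times
    for c in curves[1:]:
        if not np.array_equal(c.times, times):
            raise ValueError("all curves must share one time grid")
    df = pd.DataFrame({"time_min": np.round(times * 60.0, 6)})
    for c in curves:
        df[c.replicate or f"well{len(df.columns)}"] = c.od
    df.to_csv(path, index=False)


def read_plate_csv(path, lineage_of=None):
    """Read a wide plate CSV back into GrowthCurve objects."""
    df = pd.read_csv(path)
    if df.columns[0] != "time_min":
        raise ValueError("plate CSV must start with a time_min column")
    times = df["time_min"].to_numpy(dtype=float) / 60.0
    curves = []
    for col in df.columns[1:]:
        lineage = lineage_of.get(col, "") if lineage_of else ""
        curves.append(
            GrowthCurve(times=times, od=df[col].to_numpy(dtype=float),
                        replicate=str(col), lineage=lineage)
        )
    return curves


# -- serial-transfer log -----------------------------------------------------

def write_transfer_tsv(log: TransferLog, path) -> None:
    pd.DataFrame(
        {
            "day": log.day,
            "dilution": log.dilution,
            "od_start": log.od_start,
            "od_end": log.od_end,
            "dt_hours": log.dt_hours,
            "feasible": log.feasible.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def read_transfer_tsv(path) -> TransferLog:
    df = pd.read_csv(path, sep="\t")
    return TransferLog(
        day=df["day"].to_numpy(dtype=np.int64),
        dilution=df["dilution"].to_numpy(dtype=np.int64),
        od_start=df["od_start"].to_numpy(dtype=float),
        od_end=df["od_end"].to_numpy(dtype=float),
        dt_hours=df["dt_hours"].to_numpy(dtype=float),
        feasible=df["feasible"].to_numpy(dtype=bool)
        if "feasible" in df
        else None,
    )


# -- mutation tables ---------------------------------------------------------

_MUT_COLUMNS = ["lineage", "position", "class", "context", "effect", "gene",
                "essential"]


def write_mutations_tsv(records, path) -> None:
    rows = [
        {
            "lineage": m.lineage,
            "position": m.position,
            "class": m.mclass,
            "context": m.context,
            "effect": m.effect or "NA",
            "gene": m.gene or "NA",
            "essential": "NA" if m.essential is None else int(m.essential),
        }
        for m in records
    ]
    pd.DataFrame(rows, columns=_MUT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutations_tsv(path):
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records = []
    for row in df.to_dict(orient="records"):
        effect = None if row["effect"] in ("NA", "") else str(row["effect"])
        gene = None if row["gene"] in ("NA", "") else str(row["gene"])
        ess_raw = str(row["essential"])
        ess = None if ess_raw in ("NA", "") else bool(int(ess_raw))
        records.append(
            MutationRecord(
                lineage=str(row["lineage"]),
                position=int(row["position"]),
                mclass=str(row["class"]),
                context=str(row["context"]),
                effect=effect,
                gene=gene,
                essential=ess,
            )
        )
    return records


# -- expression tables -------------------------------------------------------

def write_expression_tsv(profiles, path, gene_lengths=None,
                         total_reads=1_000_000) -> None:
    """Expression TSV: gene_id, start, end, then count/fpkm per sample.

    Counts are reconstructed from the log values so the table round-trips
    through the normalization stage.
    """
    profiles = list(profiles)
    first = profiles[0]
    df = pd.DataFrame(
        {"gene_id": first.gene_ids, "start": first.starts, "end": first.ends}
    )
    lengths = (
        np.asarray(gene_lengths, dtype=float)
        if gene_lengths is not None
        else (first.ends - first.starts + 1).astype(float)
    )
    for p in profiles:
        fpkm = 10.0 ** np.asarray(p.values, dtype=float)
        counts = np.rint(fpkm * lengths * total_reads / 1e9).astype(np.int64)
        df[f"count:{p.sample}"] = counts
        df[f"fpkm:{p.sample}"] = fpkm
    df.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path, genome_length):
    """Read expression TSV into one ExpressionProfile per sample.

    Prefers fpkm columns (log10-transformed); falls back to counts run
    through the FPKM conversion with the stored gene lengths.
    """
    from .periodicity import FPKM_FLOOR, fpkm_from_counts

    df = pd.read_csv(path, sep="\t")
    gene_ids = tuple(str(g) for g in df["gene_id"])
    starts = df["start"].to_numpy(dtype=np.int64)
    ends = df["end"].to_numpy(dtype=np.int64)
    profiles = []
    fpkm_cols = [c for c in df.columns if c.startswith("fpkm:")]
    count_cols = [c for c in df.columns if c.startswith("count:")]
    if fpkm_cols:
        for col in fpkm_cols:
            values = np.log10(np.maximum(df[col].to_numpy(dtype=float),
                                         FPKM_FLOOR))
            profiles.append(
                ExpressionProfile(gene_ids, starts, ends, values,
                                  sample=col.split(":", 1)[1],
                                  genome_length=genome_length)
            )
    else:
        lengths = (ends - starts + 1).astype(float)
        for col in count_cols:
            counts = df[col].to_numpy(dtype=float)
            fpkm = fpkm_from_counts(counts, lengths, counts.sum())
            values = np.log10(np.maximum(fpkm, FPKM_FLOOR))
            profiles.append(
                ExpressionProfile(gene_ids, starts, ends, values,
                                  sample=col.split(":", 1)[1],
                                  genome_length=genome_length)
            )
    return profiles


# -- gene sets and annotations ----------------------------------------------

def read_gene_set(path):
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


def read_annotation_tsv(path):
    """(gene_id, scheme, label) triples."""
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["gene_id"].astype(str), df["scheme"].astype(str),
                    df["label"].astype(str)))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
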