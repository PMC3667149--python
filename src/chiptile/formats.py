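"""Readers and writers for the external formats the pipeline touches.

Conventions enforced here, once, at the I/O boundary:

* internal coordinates are always 0-based half-open;
* BED is read/written as-is (0-based half-open);
* GFF3 is 1-based inclusive and converted on the way in/out;
* fixedStep WIG ``start`` is 1-based and converted;
* TRANSFAC matrix flat files are parsed via :mod:`Bio.motifs`.

All writers emit deterministic ordering (chromosome lexicographic, then
start coordinate) so that identical inputs produce byte-identical files.
"""

from __future__ import annotations

import io
from collections import OrderedDict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import GeneModel, GenomicInterval, Peak, ProbeTrack, PWM


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> "OrderedDict[str, str]":
    """Read a FASTA file into an ordered {record id: sequence} map.

    Bases are uppercased on read; duplicate record ids and empty files are
    rejected.
    """
    genome: OrderedDict[str, str] = OrderedDict()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise FormatError(f"duplicate FASTA record id: {rec.id}")
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise FormatError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: dict, path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq.upper()), id=name, description="")
        for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> list[GenomicInterval]:
    """Read a 3-6 column BED file (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if end <= start:
                raise FormatError(
                    f"{path}:{lineno}: end ({end}) <= start ({start})"
                )
            strand = fields[5] if len(fields) >= 6 else "."
            if strand not in ("+", "-", "."):
                raise FormatError(
                    f"{path}:{lineno}: unknown strand symbol {strand!r}"
                )
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return intervals


def write_bed(intervals, path, names=None, scores=None) -> None:
    """Write intervals as BED; optional per-interval names and scores."""
    order = sorted(
        range(len(intervals)),
        key=lambda i: (intervals[i].chrom, intervals[i].start, intervals[i].end),
    )
    with open(path, "w") as fh:
        for i in order:
            iv = intervals[i]
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or scores is not None or iv.strand != ".":
                cols.append(str(names[i]) if names is not None else ".")
                cols.append(f"{scores[i]:g}" if scores is not None else "0")
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GFF3 gene models


def write_gff_genes(genes: list[GeneModel], path, source: str = "chiptile") -> None:
    """Write gene models as GFF3 (1-based inclusive) gene/exon/CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
            attrs = f"ID={g.gene_id}"
            fh.write(
                "\t".join(
                    [
                        g.chrom, source, "gene",
                        str(g.tx_start + 1), str(g.tx_end),
                        ".", g.strand, ".", attrs,
                    ]
                )
                + "\n"
            )
            for k, (es, ee) in enumerate(g.exons, start=1):
                fh.write(
                    "\t".join(
                        [
                            g.chrom, source, "exon",
                            str(es + 1), str(ee), ".", g.strand, ".",
                            f"ID={g.gene_id}.exon{k};Parent={g.gene_id}",
                        ]
                    )
                    + "\n"
                )
            if g.cds_end > g.cds_start:
                fh.write(
                    "\t".join(
                        [
                            g.chrom, source, "CDS",
                            str(g.cds_start + 1), str(g.cds_end),
                            ".", g.strand, "0",
                            f"ID={g.gene_id}.cds;Parent={g.gene_id}",
                        ]
                    )
                    + "\n"
                )


def _parse_gff_attrs(field: str) -> dict:
    out = {}
    for item in field.split(";"):
        item = item.strip()
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def read_gff_genes(path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene + exon + CDS features, ID/Parent links).

    GFF's 1-based inclusive coordinates are converted to 0-based half-open.
    """
    genes: "OrderedDict[str, dict]" = OrderedDict()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: GFF line has {len(fields)} columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end ({end1}) < start ({start1})")
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_gff_attrs(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene feature lacks ID")
                genes[gid] = {
                    "chrom": chrom, "start": start, "end": end,
                    "strand": strand, "exons": [], "cds": None,
                }
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent not in genes:
                    raise FormatError(f"{path}:{lineno}: exon with unknown Parent")
                genes[parent]["exons"].append((start, end))
            elif ftype == "CDS":
                parent = attrs.get("Parent")
                if parent not in genes:
                    raise FormatError(f"{path}:{lineno}: CDS with unknown Parent")
                rec = genes[parent]
                if rec["cds"] is None:
                    rec["cds"] = (start, end)
                else:
                    rec["cds"] = (min(rec["cds"][0], start), max(rec["cds"][1], end))
    models = []
    for gid, rec in genes.items():
        exons = sorted(rec["exons"]) or [(rec["start"], rec["end"])]
        cds = rec["cds"] or (rec["start"], rec["start"])
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=rec["chrom"],
                tx_start=rec["start"],
                tx_end=rec["end"],
                strand=rec["strand"],
                exons=exons,
                cds_start=cds[0],
                cds_end=cds[1],
            )
        )
    return models


def write_gene_table(genes: list[GeneModel], path) -> None:
    """Write genes as a BED12-like TSV (0-based half-open, exon block columns)."""
    rows = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
        starts = ",".join(str(s - g.tx_start) for s, _ in g.exons)
        sizes = ",".join(str(e - s) for s, e in g.exons)
        rows.append(
            [
                g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
                g.cds_start, g.cds_end, len(g.exons), sizes, starts,
            ]
        )
    pd.DataFrame(
        rows,
        columns=[
            "chrom", "txStart", "txEnd", "name", "score", "strand",
            "cdsStart", "cdsEnd", "exonCount", "exonSizes", "exonStarts",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# WIG probe tracks


def write_wig(tracks: list[ProbeTrack], path, name: str = "log2_ratio") -> None:
    """Write probe tracks as fixedStep WIG (1-based starts)."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for tr in sorted(tracks, key=lambda t: t.chrom):
            # fixedStep requires uniform spacing; fall back to variableStep.
            diffs = np.diff(tr.positions)
            if diffs.size == 0 or np.all(diffs == tr.spacing):
                fh.write(
                    f"fixedStep chrom={tr.chrom} start={tr.positions[0] + 1} "
                    f"step={tr.spacing} span={tr.spacing}\n"
                )
                for v in tr.ratios:
                    fh.write(f"{v:.6g}\n")
            else:
                fh.write(f"variableStep chrom={tr.chrom} span={tr.spacing}\n")
                for p, v in zip(tr.positions, tr.ratios):
                    fh.write(f"{p + 1}\t{v:.6g}\n")


def read_wig(path, spacing: int | None = None) -> list[ProbeTrack]:
    """Read fixedStep or variableStep WIG into per-chromosome probe tracks."""
    chroms: "OrderedDict[str, tuple[list, list]]" = OrderedDict()
    mode = None
    chrom = step = span = None
    nxt = 0
    spacings: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                kv = dict(
                    item.split("=", 1) for item in line.split()[1:] if "=" in item
                )
                chrom = kv.get("chrom")
                if chrom is None:
                    raise FormatError(f"{path}:{lineno}: declaration lacks chrom")
                span = int(kv.get("span", 1))
                if line.startswith("fixedStep"):
                    mode = "fixed"
                    step = int(kv.get("step", 1))
                    nxt = int(kv["start"]) - 1  # to 0-based
                    spacings.setdefault(chrom, step)
                else:
                    mode = "variable"
                    spacings.setdefault(chrom, span)
                chroms.setdefault(chrom, ([], []))
                continue
            if mode is None:
                raise FormatError(f"{path}:{lineno}: data before any declaration")
            pos_list, val_list = chroms[chrom]
            if mode == "fixed":
                pos_list.append(nxt)
                val_list.append(float(line))
                nxt += step
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(
                        f"{path}:{lineno}: variableStep line needs 2 fields"
                    )
                pos_list.append(int(parts[0]) - 1)
                val_list.append(float(parts[1]))
    tracks = []
    for chrom, (pos_list, val_list) in chroms.items():
        sp = spacing or spacings.get(chrom) or 1
        pos = np.asarray(pos_list, dtype=np.int64)
        vals = np.asarray(val_list, dtype=np.float64)
        order = np.argsort(pos)
        tracks.append(ProbeTrack(chrom, pos[order], vals[order], sp))
    if not tracks:
        raise FormatError(f"no WIG data found in {path}")
    return tracks


def write_probe_tsv(tracks: list[ProbeTrack], path) -> None:
    frames = [
        pd.DataFrame(
            {"chrom": tr.chrom, "probe_start": tr.positions, "log2_ratio": tr.ratios}
        )
        for tr in sorted(tracks, key=lambda t: t.chrom)
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_probe_tsv(path, spacing: int | None = None) -> list[ProbeTrack]:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "probe_start", "log2_ratio"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: probe table must have columns {sorted(required)}")
    tracks = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("probe_start")
        pos = sub["probe_start"].to_numpy(dtype=np.int64)
        sp = spacing or (int(np.median(np.diff(pos))) if len(pos) > 1 else 1)
        tracks.append(
            ProbeTrack(str(chrom), pos, sub["log2_ratio"].to_numpy(float), sp)
        )
    return tracks


# ---------------------------------------------------------------------------
# TRANSFAC matrices


def read_transfac_matrices(path, pseudocount: float = 0.25) -> list[PWM]:
    """Read PWMs from a TRANSFAC-style matrix flat file (ID / P0 blocks)."""
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "TRANSFAC")
        except Exception as exc:
            raise FormatError(f"{path}: TRANSFAC parse failed: {exc}") from exc
    pwms = []
    for rec in records:
        counts = np.array(
            [rec.counts[b] for b in "ACGT"], dtype=np.float64
        )
        mid = rec.get("ID") or rec.get("AC") or f"matrix{len(pwms) + 1}"
        if counts.shape[1] < 1:
            raise FormatError(f"{path}: matrix {mid} has no columns")
        pwms.append(PWM(id=mid, counts=counts, pseudocount=pseudocount))
    if not pwms:
        raise FormatError(f"no TRANSFAC matrices found in {path}")
    return pwms


def write_transfac_matrices(pwms: list[PWM], path) -> None:
    buf = io.StringIO()
    for pwm in pwms:
        buf.write(f"ID  {pwm.id}\nXX\nBF  none\nXX\n")
        buf.write("P0      A      C      G      T\n")
        for i in range(pwm.width):
            vals = "  ".join(f"{v:g}" for v in pwm.counts[:, i])
            buf.write(f"{i + 1:02d}  {vals}\n")
        buf.write("XX\n//\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Expression and peak tables


def read_expression_tsv(path) -> pd.DataFrame:
    """Read an expression table (gene_id, expr, log2fc — extra columns kept).

    The fold-change column holds *signed* fold changes: +2 means 2-fold up,
    -2 means 2-fold down, values in (-1, 1) do not occur.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "expr", "fold_change"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: expression table must have columns {sorted(required)}"
        )
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene_id rows")
    return df


def write_expression_tsv(table: pd.DataFrame, path) -> None:
    table.sort_values("gene_id").to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_peaks_bed(peaks: list[Peak], path) -> None:
    """Write called peaks as BED6 with the ladder score in the score column."""
    rows = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    with open(path, "w") as fh:
        for i, p in enumerate(rows, start=1):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t{p.score:g}\t.\n"
            )


def write_peaks_gff(peaks: list[Peak], path, source: str = "chiptile") -> None:
    """Write peaks as GFF with FDR and probe count in the attribute column."""
    rows = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, p in enumerate(rows, start=1):
            fdr = "NA" if np.isnan(p.fdr) else f"{p.fdr:.6g}"
            fh.write(
                "\t".join(
                    [
                        p.chrom, source, "peak",
                        str(p.start + 1), str(p.end), f"{p.score:g}",
                        ".", ".",
                        f"ID=peak{i};n_probes={p.n_probes};"
                        f"mean_ratio={p.mean_ratio:.4f};fdr={fdr}",
                    ]
                )
                + "\n"
            )


def read_peaks_bed(path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            score = float(fields[4]) if len(fields) >= 5 else 0.0
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end),
                    score=score,
                    n_probes=0,
                    mean_ratio=float("nan"),
                )
            )
    return peaks
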