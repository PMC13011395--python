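"""Readers and writers for the on-disk formats.

Alignments travel either as minimal SAM (one file per sample, @SQ
headers from the catalog, ``AS`` tag carrying the alignment score,
secondary hits flagged 0x100) or as a 5-column TSV dialect.  SAM's
1-based coordinates are converted to 0-based half-open here and nowhere
else.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
import pysam

from virome_ap.profiling import ALIGNMENT_COLUMNS, VOTUCatalog

ALIGNMENT_TSV_COLUMNS = ["read_id", "votu_id", "start", "end", "score"]


def write_sam(records: pd.DataFrame, cat: VOTUCatalog, outdir, sample_id: str) -> Path:
    """Write one sample's alignment records as a minimal SAM file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{sample_id}.sam"
    sub = records[records["sample_id"] == sample_id]
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for votu, length in cat.genome_lengths.items():
            fh.write(f"@SQ\tSN:{votu}\tLN:{int(length)}\n")
        for row in sub.itertuples(index=False):
            flag = 256 if getattr(row, "secondary", False) else 0
            pos = int(row.start) + 1  # SAM is 1-based
            cigar = f"{int(row.end) - int(row.start)}M"
            fh.write(
                f"{row.read_id}\t{flag}\t{row.votu_id}\t{pos}\t60\t{cigar}"
                f"\t*\t0\t0\t*\t*\tAS:i:{int(row.score)}\n"
            )
    return path


def read_sam(path, sample_id: str | None = None) -> pd.DataFrame:
    """Parse a SAM file into the tabular alignment representation.

    The sample id defaults to the file stem.  Secondary alignments are
    retained (flagged in the ``secondary`` column) so best-hit resolution
    can be exercised downstream.
    """
    path = Path(path)
    sample_id = sample_id or path.stem
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            score = float(aln.get_tag("AS")) if aln.has_tag("AS") else 0.0
            rows.append(
                (
                    sample_id,
                    aln.query_name,
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    score,
                    aln.is_secondary,
                )
            )
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS + ["secondary"])


def read_sam_dir(directory) -> pd.DataFrame:
    frames = [read_sam(p) for p in sorted(Path(directory).glob("*.sam"))]
    if not frames:
        raise FileNotFoundError(f"no .sam files under {directory}")
    return pd.concat(frames, ignore_index=True)


def write_alignment_tsv(records: pd.DataFrame, outdir, sample_id: str) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{sample_id}.aln.tsv"
    sub = records.loc[records["sample_id"] == sample_id, ALIGNMENT_TSV_COLUMNS]
    sub.to_csv(path, sep="\t", index=False)
    return path


def read_alignment_tsv(path, sample_id: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if sample_id is None:
        sample_id = os.path.basename(path).removesuffix(".aln.tsv").removesuffix(".tsv")
    df = pd.read_csv(path, sep="\t")
    df.insert(0, "sample_id", sample_id)
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
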