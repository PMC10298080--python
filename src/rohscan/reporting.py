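"""Deterministic tabular output: TSV tables and BED interval files.

All tables are tab-separated with fixed schemas; floats print with 6
significant digits (scientific notation available for the F_ROH tables).
Interval files are BED, 0-based half-open — internal coordinates are
1-based inclusive and the writers convert explicitly.
"""

from __future__ import annotations

import os
from typing import Sequence

import pandas as pd

from .caller import ROHSegment
from .islands import IncidenceTrack, Island
from .stats import classify_length

ROH_COLUMNS = ["sample", "chrom", "start_bp", "end_bp", "n_snps", "length_bp", "length_class"]


def segments_to_frame(segments: Sequence[ROHSegment]) -> pd.DataFrame:
    rows = [
        {
            "sample": s.sample_id,
            "chrom": s.chrom,
            "start_bp": s.start_bp,
            "end_bp": s.end_bp,
            "n_snps": s.n_snps,
            "length_bp": s.length_bp,
            "length_class": classify_length(s.length_bp).value,
        }
        for s in segments
    ]
    return pd.DataFrame(rows, columns=ROH_COLUMNS)


def frame_to_segments(df: pd.DataFrame) -> list[ROHSegment]:
    return [
        ROHSegment(
            sample_id=str(r["sample"]),
            chrom=str(r["chrom"]),
            start_bp=int(r["start_bp"]),
            end_bp=int(r["end_bp"]),
            n_snps=int(r["n_snps"]),
        )
        for _, r in df.iterrows()
    ]


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, scientific: bool = False) -> None:
    fmt = "%.6e" if scientific else "%.6g"
    df.to_csv(path, sep="\t", index=False, float_format=fmt)


def read_roh_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = set(ROH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing ROH columns {sorted(missing)}")
    return df


def write_segments_bed(segments: Sequence[ROHSegment], path: str | os.PathLike) -> None:
    """BED with the sample id in the name column."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start_bp - 1}\t{s.end_bp}\t{s.sample_id}\n")


def write_islands(islands: Sequence[Island], tsv_path, bed_path=None) -> None:
    rows = [
        {
            "chrom": i.chrom,
            "start_bp": i.start_bp,
            "end_bp": i.end_bp,
            "n_snps": i.n_snps,
            "length_bp": i.length_bp,
            "peak_incidence": i.peak_incidence,
            "genes": ",".join(i.gene_ids) if i.gene_ids else ".",
        }
        for i in islands
    ]
    cols = ["chrom", "start_bp", "end_bp", "n_snps", "length_bp", "peak_incidence", "genes"]
    write_tsv(pd.DataFrame(rows, columns=cols), tsv_path)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for i in islands:
                fh.write(f"{i.chrom}\t{i.start_bp - 1}\t{i.end_bp}\t{i.n_snps}\n")


def write_incidence(track: IncidenceTrack, path) -> None:
    """The Manhattan-style per-SNP incidence track: chrom, pos, incidence."""
    inc = track.incidence
    frames = []
    for chrom in track.positions:
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": track.positions[chrom],
                    "incidence": inc[chrom],
                }
            )
        )
    write_tsv(pd.concat(frames, ignore_index=True), path)
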