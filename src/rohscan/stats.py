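"""Length-class stratification, F_ROH and population summaries.

The genomic inbreeding coefficient is F_ROH = L_ROH / L_AUTO: the summed
length of an individual's ROH divided by the total autosome length.  It is
computed overall and within four length classes used as a rough clock for
the inbreeding that produced the runs — short runs reflect ancient
inbreeding, long runs recent inbreeding.

Class boundaries are half-open and lower-inclusive: [min, 1), [1, 5),
[5, 10), [10, inf) Mb, so every segment maps to exactly one class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .caller import ROHSegment
from .io import AutosomeTable, SampleMap

MB = 1_000_000


class LengthClass(str, Enum):
    LT1 = "<1 Mb"
    MB1_5 = "1-5 Mb"
    MB5_10 = "5-10 Mb"
    GT10 = ">10 Mb"


CLASS_ORDER = [LengthClass.LT1, LengthClass.MB1_5, LengthClass.MB5_10, LengthClass.GT10]


def classify_length(length_bp: int) -> LengthClass:
    """Map a segment length to its class; boundaries are lower-inclusive."""
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if length_bp < 1 * MB:
        return LengthClass.LT1
    if length_bp < 5 * MB:
        return LengthClass.MB1_5
    if length_bp < 10 * MB:
        return LengthClass.MB5_10
    return LengthClass.GT10


@dataclass(frozen=True)
class FRohRecord:
    sample_id: str
    f_lt1: float
    f_1_5: float
    f_5_10: float
    f_gt10: float
    f_all: float

    def by_class(self) -> dict[LengthClass, float]:
        return {
            LengthClass.LT1: self.f_lt1,
            LengthClass.MB1_5: self.f_1_5,
            LengthClass.MB5_10: self.f_5_10,
            LengthClass.GT10: self.f_gt10,
        }


def f_roh(
    segments: Sequence[ROHSegment],
    autosomes: AutosomeTable,
    sample_id: str | None = None,
) -> FRohRecord:
    """Per-class and overall F_ROH for one sample's segments."""
    samples = {s.sample_id for s in segments}
    if sample_id is None:
        if len(samples) > 1:
            raise ValueError(f"segments from multiple samples: {sorted(samples)}")
        sample_id = next(iter(samples)) if samples else ""
    elif samples - {sample_id}:
        raise ValueError(f"segments not all from sample {sample_id!r}")

    total = autosomes.total_bp
    sums = {cls: 0 for cls in CLASS_ORDER}
    for s in segments:
        if s.chrom not in autosomes:
            raise ValueError(f"segment on unknown chromosome {s.chrom!r}")
        sums[classify_length(s.length_bp)] += s.length_bp
    by_cls = {cls: sums[cls] / total for cls in CLASS_ORDER}
    return FRohRecord(
        sample_id=sample_id,
        f_lt1=by_cls[LengthClass.LT1],
        f_1_5=by_cls[LengthClass.MB1_5],
        f_5_10=by_cls[LengthClass.MB5_10],
        f_gt10=by_cls[LengthClass.GT10],
        f_all=sum(by_cls.values()),
    )


def froh_table(
    segments: Sequence[ROHSegment],
    samples: Iterable[str],
    autosomes: AutosomeTable,
) -> pd.DataFrame:
    """Per-sample F_ROH table (one row per sample, zero rows filled in)."""
    by_sample: dict[str, list[ROHSegment]] = {s: [] for s in samples}
    for seg in segments:
        if seg.sample_id not in by_sample:
            raise ValueError(f"segment for unlisted sample {seg.sample_id!r}")
        by_sample[seg.sample_id].append(seg)
    rows = []
    for sample, segs in by_sample.items():
        r = f_roh(segs, autosomes, sample_id=sample)
        rows.append(
            {
                "sample": sample,
                "f_roh_lt1mb": r.f_lt1,
                "f_roh_1_5mb": r.f_1_5,
                "f_roh_5_10mb": r.f_5_10,
                "f_roh_gt10mb": r.f_gt10,
                "f_roh_all": r.f_all,
            }
        )
    return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize_population(
    segments: Sequence[ROHSegment],
    sample_map: SampleMap,
    autosomes: AutosomeTable,
    min_n_for_sd: int = 3,
) -> pd.DataFrame:
    """Breed-level ROH summary: counts, lengths and mean F_ROH per class.

    One row per population with total/mean/max segment statistics, per-class
    counts, the class-wise mean inbreeding coefficients, and the sample
    standard deviation (ddof=1) of F_ROH-all — reported only for populations
    with more than ``min_n_for_sd`` samples, NaN otherwise.  ``mean_n_roh``
    is rounded half-up to an integer.
    """
    for seg in segments:
        if seg.sample_id not in sample_map.mapping:
            raise ValueError(f"unlabeled sample {seg.sample_id!r}")

    rows = []
    for pop in sample_map.populations:
        pop_samples = sample_map.samples_of(pop)
        segs = [s for s in segments if sample_map[s.sample_id] == pop]
        n = len(pop_samples)
        lengths = np.array([s.length_bp for s in segs], dtype=np.int64)
        classes = [classify_length(s.length_bp) for s in segs]
        froh = froh_table(segs, pop_samples, autosomes)
        f_all = froh["f_roh_all"].to_numpy()
        row = {
            "population": pop,
            "n_samples": n,
            "total_n_roh": len(segs),
            "mean_n_roh": _round_half_up(len(segs) / n),
            "total_length_mb": lengths.sum() / MB,
            "mean_length_mb": lengths.sum() / MB / n,
            "max_length_mb": (lengths.max() / MB) if len(segs) else 0.0,
            "n_lt1mb": classes.count(LengthClass.LT1),
            "n_1_5mb": classes.count(LengthClass.MB1_5),
            "n_5_10mb": classes.count(LengthClass.MB5_10),
            "n_gt10mb": classes.count(LengthClass.GT10),
            "mean_f_roh_lt1mb": froh["f_roh_lt1mb"].mean(),
            "mean_f_roh_1_5mb": froh["f_roh_1_5mb"].mean(),
            "mean_f_roh_5_10mb": froh["f_roh_5_10mb"].mean(),
            "mean_f_roh_gt10mb": froh["f_roh_gt10mb"].mean(),
            "mean_f_roh_all": f_all.mean(),
            "sd_f_roh_all": float(np.std(f_all, ddof=1)) if n > min_n_for_sd else float("nan"),
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("mean_length_mb", ascending=False, ignore_index=True)


def per_chromosome_coverage(
    segments: Sequence[ROHSegment],
    n_samples: int,
    autosomes: AutosomeTable,
    method: str = "mean",
) -> pd.DataFrame:
    """Per-chromosome segment count and ROH coverage for one population.

    ``method='mean'`` (default): average over samples of the fraction of the
    chromosome covered by that sample's segments.  ``method='union'``: the
    fraction covered by the union of all samples' segments.
    """
    if method not in ("mean", "union"):
        raise ValueError("method must be 'mean' or 'union'")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rows = []
    for chrom, chrom_len in autosomes.lengths.items():
        segs = [s for s in segments if s.chrom == chrom]
        if method == "mean":
            covered = sum(s.length_bp for s in segs) / n_samples
        else:
            ivs = sorted((s.start_bp, s.end_bp) for s in segs)
            covered = 0
            cur_start = cur_end = None
            for a, b in ivs:
                if cur_end is None or a > cur_end + 1:
                    if cur_end is not None:
                        covered += cur_end - cur_start + 1
                    cur_start, cur_end = a, b
                else:
                    cur_end = max(cur_end, b)
            if cur_end is not None:
                covered += cur_end - cur_start + 1
        rows.append(
            {
                "chrom": chrom,
                "n_roh": len(segs),
                "covered_fraction": covered / chrom_len,
            }
        )
    return pd.DataFrame(rows)
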