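"""Truth-versus-called interval metrics for simulated panels."""

from __future__ import annotations

from typing import Sequence

from .caller import ROHSegment
from .simulate import TruthSet


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = _overlap(a[0], a[1], b[0], b[1])
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union if union else 0.0


def base_pair_recall(
    truth: TruthSet,
    segments: Sequence[ROHSegment],
    min_truth_len_bp: int = 0,
) -> float:
    """Fraction of planted base pairs (in tracts >= min_truth_len_bp)
    covered by called segments of the same sample."""
    by_sample: dict[str, list[ROHSegment]] = {}
    for s in segments:
        by_sample.setdefault(s.sample_id, []).append(s)
    covered = planted = 0
    for sample, ivs in truth.intervals.items():
        segs = by_sample.get(sample, [])
        for chrom, start, end in ivs:
            if end - start + 1 < min_truth_len_bp:
                continue
            planted += end - start + 1
            covered += sum(
                _overlap(start, end, s.start_bp, s.end_bp)
                for s in segs
                if s.chrom == chrom
            )
    return covered / planted if planted else float("nan")


def best_jaccard_per_truth(
    truth: TruthSet,
    segments: Sequence[ROHSegment],
    min_truth_len_bp: int = 0,
) -> list[float]:
    """For every planted tract (>= min length), the best Jaccard index
    against any called segment of the same sample on the same chromosome."""
    by_sample: dict[str, list[ROHSegment]] = {}
    for s in segments:
        by_sample.setdefault(s.sample_id, []).append(s)
    out = []
    for sample, ivs in truth.intervals.items():
        segs = by_sample.get(sample, [])
        for chrom, start, end in ivs:
            if end - start + 1 < min_truth_len_bp:
                continue
            best = 0.0
            for s in segs:
                if s.chrom == chrom:
                    best = max(best, interval_jaccard((start, end), (s.start_bp, s.end_bp)))
            out.append(best)
    return out


def total_called_bp(segments: Sequence[ROHSegment], sample_id: str | None = None) -> int:
    return sum(s.length_bp for s in segments if sample_id is None or s.sample_id == sample_id)
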