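"""ROH islands: population hotspots of homozygosity.

For one population, each SNP's *incidence* is the fraction of individuals
whose called ROH cover it (an individual counts once however many of its
segments contain the SNP).  SNPs in the top 1% of the empirical incidence
distribution are flagged — the cutoff is the incidence at the (1 - p)
quantile under the "higher" order-statistic convention, and ties at the
cutoff are all included — then maximal runs of flagged SNPs, split at gaps
over ``merge_gap_bp`` or chromosome boundaries, form islands.  Islands are
annotated with genes overlapping them by at least 1 bp.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .caller import ROHSegment


@dataclass
class IncidenceTrack:
    """Per-SNP ROH incidence for one population.

    ``n_covered[chrom][j]`` = number of individuals whose ROH contain SNP j;
    ``incidence`` = n_covered / n_individuals.
    """

    n_individuals: int
    positions: dict[str, np.ndarray]
    n_covered: dict[str, np.ndarray]

    @property
    def incidence(self) -> dict[str, np.ndarray]:
        return {c: nc / self.n_individuals for c, nc in self.n_covered.items()}

    def all_incidences(self) -> np.ndarray:
        vals = [v for v in self.incidence.values() if len(v)]
        return np.concatenate(vals) if vals else np.empty(0)


@dataclass
class Island:
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_incidence: float
    gene_ids: list[str] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start > end")


def incidence_track(
    segments: Sequence[ROHSegment],
    positions: Mapping[str, np.ndarray],
    population_samples: Iterable[str],
) -> IncidenceTrack:
    """Count, per SNP, the population individuals whose ROH cover it."""
    samples = list(population_samples)
    if not samples:
        raise ValueError("empty population")
    sample_set = set(samples)
    extra = {s.sample_id for s in segments} - sample_set
    if extra:
        raise ValueError(f"segments from samples outside the population: {sorted(extra)}")

    counts = {c: np.zeros(len(p), dtype=np.int32) for c, p in positions.items()}
    by_sample_chrom: dict[tuple[str, str], list[ROHSegment]] = {}
    for s in segments:
        by_sample_chrom.setdefault((s.sample_id, s.chrom), []).append(s)
    for (sample, chrom), segs in by_sample_chrom.items():
        if chrom not in counts:
            raise ValueError(f"segment on chromosome {chrom!r} absent from site track")
        pos = positions[chrom]
        covered = np.zeros(len(pos), dtype=bool)
        for s in segs:
            lo = np.searchsorted(pos, s.start_bp, side="left")
            hi = np.searchsorted(pos, s.end_bp, side="right")
            covered[lo:hi] = True
        counts[chrom] += covered
    return IncidenceTrack(
        n_individuals=len(samples),
        positions={c: np.asarray(p, dtype=np.int64) for c, p in positions.items()},
        n_covered=counts,
    )


def top_percentile_threshold(track: IncidenceTrack, top_fraction: float = 0.01) -> float:
    """Incidence cutoff at the (1 - top_fraction) empirical quantile.

    Uses the "higher" order statistic so that flagging ``incidence >=
    cutoff`` never selects fewer than ``top_fraction`` of the SNPs; ties at
    the cutoff are all flagged.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    values = track.all_incidences()
    if len(values) == 0:
        raise ValueError("empty incidence track")
    return float(np.quantile(values, 1 - top_fraction, method="higher"))


def build_islands(
    track: IncidenceTrack,
    cutoff: float,
    merge_gap_bp: int = 1_000_000,
) -> list[Island]:
    """Merge runs of flagged SNPs (incidence >= cutoff) into islands."""
    islands: list[Island] = []
    inc = track.incidence
    for chrom in track.positions:
        pos = track.positions[chrom]
        flagged = np.flatnonzero(inc[chrom] >= cutoff)
        if flagged.size == 0:
            continue
        run_start = 0
        for k in range(1, len(flagged) + 1):
            end_of_run = k == len(flagged) or (
                pos[flagged[k]] - pos[flagged[k - 1]] > merge_gap_bp
            )
            if end_of_run:
                idx = flagged[run_start:k]
                islands.append(
                    Island(
                        chrom=chrom,
                        start_bp=int(pos[idx[0]]),
                        end_bp=int(pos[idx[-1]]),
                        n_snps=len(idx),
                        peak_incidence=float(inc[chrom][idx].max()),
                    )
                )
                run_start = k
    return islands


def annotate_islands(
    islands: Sequence[Island],
    genes: Sequence[GeneFeature],
    require_containment: bool = False,
) -> list[Island]:
    """Attach overlapping gene ids to each island.

    Default rule: >= 1 bp overlap on 1-based closed intervals.  With
    ``require_containment`` a gene must lie fully inside the island.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # IntervalTree is half-open; end + 1 makes the closed interval
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start_bp, g.end_bp + 1, g)
    out: list[Island] = []
    for isl in islands:
        hits = []
        tree = trees.get(isl.chrom)
        if tree is not None:
            for iv in tree.overlap(isl.start_bp, isl.end_bp + 1):
                g: GeneFeature = iv.data
                if require_containment and not (
                    isl.start_bp <= g.start_bp and g.end_bp <= isl.end_bp
                ):
                    continue
                hits.append(g.gene_id)
        out.append(
            Island(
                chrom=isl.chrom,
                start_bp=isl.start_bp,
                end_bp=isl.end_bp,
                n_snps=isl.n_snps,
                peak_incidence=isl.peak_incidence,
                gene_ids=sorted(hits),
            )
        )
    return out


def _gff3_attr(attrs: str, *keys: str) -> str | None:
    for part in attrs.rstrip(";").split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() in keys:
                return v.strip()
    return None


def read_genes_gff3(path: str | os.PathLike, feature_types: tuple[str, ...] = ("gene",)) -> list[GeneFeature]:
    """Read gene features from a GFF3 file (9-column, 1-based inclusive)."""
    genes: list[GeneFeature] = []
    bad: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                bad.append(f"line {lineno}: expected 9 columns")
                continue
            if cols[2] not in feature_types:
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                bad.append(f"line {lineno}: non-integer coordinates")
                continue
            gid = _gff3_attr(cols[8], "ID", "gene_id", "Name") or f"gene_{lineno}"
            try:
                genes.append(GeneFeature(gid, cols[0], start, end, cols[6]))
            except ValueError as exc:
                bad.append(f"line {lineno}: {exc}")
    if bad:
        raise ValueError(f"malformed gene records in {path}: " + "; ".join(bad))
    return genes


def read_genes_bed(path: str | os.PathLike) -> list[GeneFeature]:
    """Read gene features from 4+-column BED (0-based half-open)."""
    genes: list[GeneFeature] = []
    bad: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                bad.append(f"line {lineno}: expected >= 4 columns")
                continue
            try:
                start0, end0 = int(cols[1]), int(cols[2])
            except ValueError:
                bad.append(f"line {lineno}: non-integer coordinates")
                continue
            strand = cols[5] if len(cols) > 5 else "."
            try:
                genes.append(GeneFeature(cols[3], cols[0], start0 + 1, end0, strand))
            except ValueError as exc:
                bad.append(f"line {lineno}: {exc}")
    if bad:
        raise ValueError(f"malformed gene records in {path}: " + "; ".join(bad))
    return genes


def read_genes(path: str | os.PathLike) -> list[GeneFeature]:
    """Dispatch on extension: .gff/.gff3 -> GFF3, otherwise BED."""
    p = os.fspath(path)
    if p.endswith((".gff", ".gff3")):
        return read_genes_gff3(p)
    return read_genes_bed(p)
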