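"""Synthetic diploid genotype panels with planted autozygous segments.

The generator emulates the statistical structure the windowed ROH scan
assumes: a background of independent biallelic SNPs in Hardy-Weinberg
proportions at per-site allele frequencies, overlaid per individual with
planted autozygous tracts in which both haplotypes are copies of one
ancestral allele — so every site is homozygous apart from a controllable
residual heterozygote error (mimicking genotyping error inside true IBD
tracts).  SNP positions follow a Poisson process at a chosen mean spacing,
and every call can independently be set missing.

Tract lengths follow a truncated exponential: IBD segment length decays
roughly exponentially with the number of generations to the common
ancestor, so the mean length is the knob for "recent" (long tracts) versus
"ancient" (short tracts) inbreeding.  Linkage disequilibrium between
background sites is not modelled.

An optional shared interval can be forced autozygous in a chosen fraction
of the panel, planting a population ROH island for the incidence scan.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import GT, GenotypeMatrix


@dataclass(frozen=True)
class SharedIslandSpec:
    """Force [start_bp, end_bp] on ``chrom`` autozygous in a fraction of samples."""

    chrom: str
    start_bp: int
    end_bp: int
    sample_fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")


@dataclass(frozen=True)
class SimParams:
    n_samples: int = 20
    autosomes: Mapping[str, int] = field(default_factory=lambda: {"1": 50_000_000})
    snp_spacing_bp: float = 1_000.0  # mean inter-SNP spacing (Poisson process)
    allele_freq: float | tuple[float, float] = (0.05, 0.5)  # alt-allele freq or Uniform bounds
    phi: float | Sequence[float] = 0.0  # target autozygous genome fraction per sample
    seg_mean_len_bp: float = 2_000_000.0
    seg_min_len_bp: int = 500_000
    het_error_rate: float = 0.0
    missing_rate: float = 0.0
    shared_island: SharedIslandSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.snp_spacing_bp <= 0:
            raise ValueError("snp_spacing_bp must be positive")
        phis = self.phi_per_sample()
        if any(not 0 <= p < 1 for p in phis):
            raise ValueError("phi must be in [0, 1)")
        for r in (self.het_error_rate, self.missing_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must be in [0, 1)")
        if self.seg_mean_len_bp <= self.seg_min_len_bp:
            raise ValueError("seg_mean_len_bp must exceed seg_min_len_bp")

    def phi_per_sample(self) -> list[float]:
        if isinstance(self.phi, (int, float)):
            return [float(self.phi)] * self.n_samples
        if len(self.phi) != self.n_samples:
            raise ValueError("per-sample phi list length != n_samples")
        return [float(p) for p in self.phi]

    @property
    def genome_bp(self) -> int:
        return int(sum(self.autosomes.values()))

    def to_dict(self) -> dict:
        d = {
            "n_samples": self.n_samples,
            "autosomes": dict(self.autosomes),
            "snp_spacing_bp": self.snp_spacing_bp,
            "allele_freq": list(self.allele_freq)
            if isinstance(self.allele_freq, tuple)
            else self.allele_freq,
            "phi": list(self.phi) if not isinstance(self.phi, (int, float)) else self.phi,
            "seg_mean_len_bp": self.seg_mean_len_bp,
            "seg_min_len_bp": self.seg_min_len_bp,
            "het_error_rate": self.het_error_rate,
            "missing_rate": self.missing_rate,
            "shared_island": None
            if self.shared_island is None
            else {
                "chrom": self.shared_island.chrom,
                "start_bp": self.shared_island.start_bp,
                "end_bp": self.shared_island.end_bp,
                "sample_fraction": self.shared_island.sample_fraction,
            },
            "seed": self.seed,
        }
        return d


@dataclass
class TruthSet:
    """Planted autozygous intervals per sample (1-based inclusive, disjoint)."""

    genome_bp: int
    intervals: dict[str, list[tuple[str, int, int]]]

    def fraction(self, sample_id: str) -> float:
        return sum(e - s + 1 for _, s, e in self.intervals[sample_id]) / self.genome_bp

    def total_bp(self, sample_id: str) -> int:
        return sum(e - s + 1 for _, s, e in self.intervals[sample_id])


def _draw_positions(rng: np.random.Generator, length: int, spacing: float) -> np.ndarray:
    """Poisson-process SNP positions on [1, length]."""
    out: list[np.ndarray] = []
    last = 0
    expect = int(length / spacing * 1.2) + 100
    while last < length:
        gaps = np.maximum(1, np.round(rng.exponential(spacing, size=expect))).astype(np.int64)
        pos = last + np.cumsum(gaps)
        out.append(pos)
        last = int(pos[-1])
    pos = np.concatenate(out)
    return pos[pos <= length]


def _place_intervals(
    rng: np.random.Generator,
    autosomes: Mapping[str, int],
    target_bp: float,
    mean_len: float,
    min_len: int,
    existing: list[tuple[str, int, int]],
    max_attempts: int = 10_000,
) -> list[tuple[str, int, int]]:
    """Place non-overlapping tracts until their total reaches ``target_bp``.

    The last tract is clipped toward the exact target (never below
    ``min_len``), bounding the overshoot by min_len rather than mean_len.
    """
    chroms = list(autosomes)
    lens = np.array([autosomes[c] for c in chroms], dtype=float)
    placed = list(existing)
    total = sum(e - s + 1 for _, s, e in existing)
    new: list[tuple[str, int, int]] = []
    attempts = 0
    while total < target_bp:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"cannot place autozygous tracts: target fraction too large "
                f"(placed {total} of {target_bp:.0f} bp)"
            )
        need = target_bp - total
        length = int(min_len + np.round(rng.exponential(mean_len - min_len)))
        if need < length:
            length = max(min_len, int(round(need)))
        chrom = chroms[rng.choice(len(chroms), p=lens / lens.sum())]
        if autosomes[chrom] < length:
            continue
        start = int(rng.integers(1, autosomes[chrom] - length + 2))
        end = start + length - 1
        if any(c == chrom and s <= end and start <= e for c, s, e in placed):
            continue
        placed.append((chrom, start, end))
        new.append((chrom, start, end))
        total += length
    return new


def simulate_panel(params: SimParams) -> tuple[GenotypeMatrix, TruthSet]:
    """Draw a genotype panel and its truth set, reproducibly from the seed."""
    rng = np.random.default_rng(params.seed)
    samples = [f"S{i + 1:03d}" for i in range(params.n_samples)]
    chroms = list(params.autosomes)

    positions: dict[str, np.ndarray] = {}
    freqs: dict[str, np.ndarray] = {}
    for chrom in chroms:
        pos = _draw_positions(rng, params.autosomes[chrom], params.snp_spacing_bp)
        positions[chrom] = pos
        if isinstance(params.allele_freq, tuple):
            lo, hi = params.allele_freq
            freqs[chrom] = rng.uniform(lo, hi, size=len(pos))
        else:
            freqs[chrom] = np.full(len(pos), float(params.allele_freq))

    # forced shared-island carriers
    forced = np.zeros(params.n_samples, dtype=bool)
    if params.shared_island is not None:
        isl = params.shared_island
        if isl.chrom not in params.autosomes:
            raise ValueError(f"shared island on unknown chromosome {isl.chrom!r}")
        n_forced = int(round(isl.sample_fraction * params.n_samples))
        forced[rng.choice(params.n_samples, size=n_forced, replace=False)] = True

    phis = params.phi_per_sample()
    truth: dict[str, list[tuple[str, int, int]]] = {}
    for i, sample in enumerate(samples):
        existing: list[tuple[str, int, int]] = []
        if forced[i]:
            isl = params.shared_island
            existing.append((isl.chrom, isl.start_bp, isl.end_bp))
        target = phis[i] * params.genome_bp
        new = _place_intervals(
            rng,
            params.autosomes,
            target,
            params.seg_mean_len_bp,
            params.seg_min_len_bp,
            existing,
        )
        ivs = sorted(existing + new, key=lambda t: (t[0], t[1]))
        truth[sample] = ivs

    calls: dict[str, np.ndarray] = {}
    for chrom in chroms:
        pos = positions[chrom]
        q = freqs[chrom]  # alt-allele frequency
        n_sites = len(pos)
        u = rng.random((n_sites, params.n_samples))
        geno = np.full((n_sites, params.n_samples), GT.HOM_ALT, dtype=np.int8)
        p_hom_ref = ((1 - q) ** 2)[:, None]
        p_het = (2 * q * (1 - q))[:, None]
        geno[u < p_hom_ref + p_het] = GT.HET
        geno[u < p_hom_ref] = GT.HOM_REF

        for i, sample in enumerate(samples):
            for c, s, e in truth[sample]:
                if c != chrom:
                    continue
                lo = np.searchsorted(pos, s, side="left")
                hi = np.searchsorted(pos, e, side="right")
                if hi <= lo:
                    continue
                m = hi - lo
                v = rng.random(m)
                w = rng.random(m)
                tract = np.where(
                    v < params.het_error_rate,
                    GT.HET,
                    np.where(w < 1 - q[lo:hi], GT.HOM_REF, GT.HOM_ALT),
                ).astype(np.int8)
                geno[lo:hi, i] = tract

        if params.missing_rate > 0:
            miss = rng.random((n_sites, params.n_samples)) < params.missing_rate
            geno[miss] = GT.MISSING
        calls[chrom] = geno

    matrix = GenotypeMatrix(samples=samples, positions=positions, calls=calls)
    matrix.validate()
    return matrix, TruthSet(genome_bp=params.genome_bp, intervals=truth)


def write_truth_bed(truth: TruthSet, path: str | os.PathLike) -> None:
    """Write planted intervals as BED (0-based half-open) with a sample name column."""
    with open(path, "w") as fh:
        for sample in truth.intervals:
            for chrom, start, end in truth.intervals[sample]:
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{sample}\n")


def read_truth_bed(path: str | os.PathLike, genome_bp: int) -> TruthSet:
    intervals: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, start0, end0, sample = line.split("\t")[:4]
            intervals.setdefault(sample, []).append((chrom, int(start0) + 1, int(end0)))
    return TruthSet(genome_bp=genome_bp, intervals=intervals)


def write_params_json(params: SimParams, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
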