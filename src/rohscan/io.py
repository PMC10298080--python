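"""Genotype, sample-map and autosome-table input.

Reads a multi-sample VCF into the internal genotype model used by the
windowed homozygosity scan: per chromosome, a sorted position vector plus a
sites x samples matrix of genotype codes.  Only biallelic SNPs are kept —
the scan asserts homozygosity at assayed SNPs and indels/multi-allelics are
outside its model.  Phasing is irrelevant to homozygosity and is ignored.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np


class GT(IntEnum):
    """Genotype codes. Half-missing calls (e.g. ``0/.``) are MISSING:
    homozygosity cannot be asserted from a single observed allele."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = 3


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int  # 1-based
    site_id: str | None = None


@dataclass
class GenotypeMatrix:
    """Per-chromosome genotype calls for a sample panel.

    Attributes
    ----------
    samples : list of str
        Sample identifiers in VCF header order.
    positions : dict chrom -> int64 array
        1-based positions, strictly increasing within each chromosome.
    calls : dict chrom -> int8 array of shape (n_sites, n_samples)
        Genotype codes (:class:`GT`).
    """

    samples: list[str]
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    calls: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    @property
    def n_sites(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample: {sample_id!r}") from None

    def sample_calls(self, chrom: str, sample_id: str) -> np.ndarray:
        return self.calls[chrom][:, self.sample_index(sample_id)]

    def validate(self) -> None:
        for chrom, pos in self.positions.items():
            if len(pos) and not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            c = self.calls[chrom]
            if c.shape != (len(pos), len(self.samples)):
                raise ValueError(f"calls shape mismatch on {chrom}")
            if c.size and (c.min() < 0 or c.max() > 3):
                raise ValueError(f"invalid genotype code on {chrom}")


@dataclass(frozen=True)
class SampleMap:
    """sample_id -> population (breed) label."""

    mapping: Mapping[str, str]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.mapping.values():
            seen.setdefault(p)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.mapping.items() if p == population]

    def __getitem__(self, sample_id: str) -> str:
        return self.mapping[sample_id]

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class AutosomeTable:
    """Chromosome label -> length in bp, with the derived genome total."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"non-positive length for chromosome {chrom}: {n}")

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths.values()))

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


def _normalize_chrom(chrom: str, strip_chr_prefix: bool) -> str:
    if strip_chr_prefix and chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


def read_vcf(
    path: str | os.PathLike,
    region_filter: Iterable[str] | None = None,
    strip_chr_prefix: bool = False,
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained.  Genotypes map to the four
    codes; any genotype with an unobserved allele maps to MISSING.  Records
    on chromosomes outside ``region_filter`` (if given) are dropped.

    Raises on unreadable files, duplicated (chrom, pos) coordinates, or when
    no site survives filtering.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(os.fspath(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise OSError(f"cannot read VCF {path}: {exc}") from exc

    wanted = None
    if region_filter is not None:
        wanted = {_normalize_chrom(c, strip_chr_prefix) for c in region_filter}

    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} has no samples")

    pos_by_chrom: dict[str, list[int]] = {}
    calls_by_chrom: dict[str, list[np.ndarray]] = {}
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        chrom = _normalize_chrom(var.CHROM, strip_chr_prefix)
        if wanted is not None and chrom not in wanted:
            continue
        row = np.empty(len(samples), dtype=np.int8)
        for j, g in enumerate(var.genotypes):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                row[j] = GT.MISSING
            elif a0 == a1:
                row[j] = GT.HOM_REF if a0 == 0 else GT.HOM_ALT
            else:
                row[j] = GT.HET
        pos_by_chrom.setdefault(chrom, []).append(var.POS)
        calls_by_chrom.setdefault(chrom, []).append(row)
    vcf.close()

    positions: dict[str, np.ndarray] = {}
    calls: dict[str, np.ndarray] = {}
    for chrom in sorted(pos_by_chrom, key=_chrom_sort_key):
        pos = np.asarray(pos_by_chrom[chrom], dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        dup = np.flatnonzero(np.diff(pos) == 0)
        if dup.size:
            raise ValueError(
                f"duplicated site at {chrom}:{int(pos[dup[0]])} in {path}"
            )
        positions[chrom] = pos
        calls[chrom] = np.asarray(calls_by_chrom[chrom], dtype=np.int8)[order]

    if not positions:
        raise ValueError(f"no biallelic SNP sites survive filtering in {path}")
    return GenotypeMatrix(samples=samples, positions=positions, calls=calls)


def _chrom_sort_key(chrom: str):
    # numeric chromosomes in numeric order, others lexicographic after them
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


def read_sample_map(path: str | os.PathLike) -> SampleMap:
    """Read a two-column (sample_id, population) delimited table."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            sample, pop = parts[0], parts[1]
            if sample in mapping and mapping[sample] != pop:
                raise ValueError(
                    f"{path}:{lineno}: sample {sample!r} mapped to both "
                    f"{mapping[sample]!r} and {pop!r}"
                )
            mapping[sample] = pop
    if not mapping:
        raise ValueError(f"empty sample map: {path}")
    return SampleMap(mapping)


def read_autosome_table(path: str | os.PathLike) -> AutosomeTable:
    """Read a two-column (chrom, length_bp) delimited table."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            lengths[parts[0]] = int(parts[1])
    if not lengths:
        raise ValueError(f"empty autosome table: {path}")
    return AutosomeTable(lengths)


def packaged_autosome_table() -> AutosomeTable:
    """The packaged synthetic equine autosome table (31 autosomes,
    total exactly 2,280,940,000 bp)."""
    path = os.path.join(os.path.dirname(__file__), "data", "equine_autosomes_synthetic.tsv")
    return read_autosome_table(path)


_VCF_GT_STR = {GT.HOM_REF: "0/0", GT.HET: "0/1", GT.HOM_ALT: "1/1", GT.MISSING: "./."}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | os.PathLike,
    contig_lengths: Mapping[str, int] | None = None,
    ref_alt: Mapping[str, tuple[Sequence[str], Sequence[str]]] | None = None,
) -> None:
    """Write the matrix as plain-text VCF (deterministic byte output).

    Genotype codes carry no allele identity, so REF/ALT default to A/G
    unless ``ref_alt`` supplies per-chromosome allele columns.
    """
    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=rohscan\n")
    for chrom in matrix.chroms:
        if contig_lengths and chrom in contig_lengths:
            buf.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
        else:
            buf.write(f"##contig=<ID={chrom}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
        + "\n"
    )
    for chrom in matrix.chroms:
        pos = matrix.positions[chrom]
        calls = matrix.calls[chrom]
        refs = alts = None
        if ref_alt and chrom in ref_alt:
            refs, alts = ref_alt[chrom]
        for i in range(len(pos)):
            ref = refs[i] if refs is not None else "A"
            alt = alts[i] if alts is not None else "G"
            gts = "\t".join(_VCF_GT_STR[GT(c)] for c in calls[i])
            buf.write(f"{chrom}\t{int(pos[i])}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
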