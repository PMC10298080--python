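import numpy as np
import pytest

from rohscan.io import GenotypeMatrix


def make_matrix(positions, calls, samples=None, chrom="1"):
    """Build a single-chromosome GenotypeMatrix from plain lists.

    ``calls`` is per-site; for one sample a flat list, otherwise a list of
    per-sample rows.
    """
    pos = np.asarray(positions, dtype=np.int64)
    c = np.asarray(calls, dtype=np.int8)
    if c.ndim == 1:
        c = c[:, None]
    if samples is None:
        samples = [f"s{i}" for i in range(c.shape[1])]
    m = GenotypeMatrix(samples=list(samples), positions={chrom: pos}, calls={chrom: c})
    m.validate()
    return m


def write_text_vcf(path, records, samples=("s0",)):
    """Write a minimal VCF. records: (chrom, pos, ref, alt, [gt strings])."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in dict.fromkeys(r[0] for r in records):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for chrom, pos, ref, alt, gts in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def tiny_vcf(tmp_path):
    return write_text_vcf(
        tmp_path / "tiny.vcf",
        [
            ("1", 100, "A", "G", ["0/0"]),
            ("1", 200, "C", "T", ["0/1"]),
            ("1", 300, "G", "A", ["./."]),
        ],
    )
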