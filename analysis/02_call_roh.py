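#!/usr/bin/env python
"""Call runs of homozygosity on the simulated panel.

Applies the windowed scan (50-SNP windows, 1 het / 4 missing allowed,
1 Mb max gap, 1 SNP / 50 kb density, 500 kb / 25 SNP segment floor) to
every sample of results/panel/panel.vcf and writes the segment table and
BED under results/.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from rohscan.caller import CallerParams, call_all, validate_segments
from rohscan.io import read_vcf
from rohscan.reporting import segments_to_frame, write_segments_bed, write_tsv

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    matrix = read_vcf(os.path.join(BASE, "panel", "panel.vcf"))
    params = CallerParams()
    segments = call_all(matrix, params)
    validate_segments(segments, matrix, params)

    df = segments_to_frame(segments)
    write_tsv(df, os.path.join(BASE, "roh.tsv"))
    write_segments_bed(segments, os.path.join(BASE, "roh.bed"))

    print(f"called {len(segments)} ROH segments in {len(matrix.samples)} samples")
    print(df["length_class"].value_counts().rename("segments per length class"))
    print(f"wrote {BASE}/roh.tsv and roh.bed")


if __name__ == "__main__":
    main()
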