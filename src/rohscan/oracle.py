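"""Exhaustive reference implementation of the windowed ROH scan.

Everything is recomputed from first principles per SNP and per window —
no prefix sums, no searchsorted, no incremental state — so the production
caller can be checked against it on small instances.  Refuses instances
above ``MAX_ORACLE_SNPS`` sites.
"""

from __future__ import annotations

import numpy as np

from .caller import CallerParams, ROHSegment
from .io import GT, GenotypeMatrix

MAX_ORACLE_SNPS = 500


def _check_size(n: int) -> None:
    if n > MAX_ORACLE_SNPS:
        raise ValueError(f"oracle limited to {MAX_ORACLE_SNPS} SNPs, got {n}")


def oracle_hit_fractions(positions, calls, params: CallerParams) -> np.ndarray:
    """Hit fractions by direct enumeration of every window."""
    pos = [int(p) for p in positions]
    c = [int(x) for x in calls]
    n = len(pos)
    _check_size(n)

    def counts_ok(members: list[int]) -> bool:
        n_het = sum(1 for k in members if c[k] == GT.HET)
        n_mis = sum(1 for k in members if c[k] == GT.MISSING)
        return (
            n_het <= params.het_allowed_per_window
            and n_mis <= params.missing_allowed_per_window
        )

    if params.window_mode == "snp":
        k = min(params.window_snps, n)
        windows = [list(range(i, i + k)) for i in range(n - k + 1)]
    else:
        windows = [
            [j for j in range(n) if pos[i] <= pos[j] < pos[i] + params.window_span_bp]
            for i in range(n)
        ]
    ok = [counts_ok(w) for w in windows]
    fractions = []
    for j in range(n):
        # windows hold contiguous index runs, so containment is a bounds check
        containing = [w for w in range(len(windows)) if windows[w][0] <= j <= windows[w][-1]]
        n_pass = sum(1 for w in containing if ok[w])
        fractions.append(n_pass / len(containing))
    return np.asarray(fractions)


def oracle_call_segments(
    matrix: GenotypeMatrix, sample_id: str, params: CallerParams | None = None
) -> list[ROHSegment]:
    """Same contract as :func:`rohscan.caller.call_segments`, brute force."""
    params = params or CallerParams()
    col = matrix.sample_index(sample_id)
    out: list[ROHSegment] = []
    for chrom in matrix.chroms:
        pos = [int(p) for p in matrix.positions[chrom]]
        _check_size(len(pos))
        calls = [int(x) for x in matrix.calls[chrom][:, col]]
        frac = oracle_hit_fractions(pos, calls, params)
        eligible = [
            frac[j] >= params.hit_fraction_threshold
            and not (params.exclude_het_sites and calls[j] == GT.HET)
            for j in range(len(pos))
        ]
        # maximal eligible runs, split where the inter-SNP gap is too wide
        n = len(pos)
        for i in range(n):
            if not eligible[i]:
                continue
            if i > 0 and eligible[i - 1] and pos[i] - pos[i - 1] <= params.max_gap_bp:
                continue  # not a run start
            j = i
            while (
                j + 1 < n
                and eligible[j + 1]
                and pos[j + 1] - pos[j] <= params.max_gap_bp
            ):
                j += 1
            n_snps = j - i + 1
            length = pos[j] - pos[i] + 1
            if (
                length >= params.min_segment_length_bp
                and n_snps >= params.min_segment_snps
                and length / n_snps <= params.min_density_bp_per_snp
            ):
                out.append(
                    ROHSegment(
                        sample_id=sample_id,
                        chrom=chrom,
                        start_bp=pos[i],
                        end_bp=pos[j],
                        n_snps=n_snps,
                    )
                )
    return out
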