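"""End-to-end validation measurements.

Two families:

* arithmetic reproduction — the published breed tables are internally
  linked (mean total length / L_AUTO = mean F_ROH-all; pooled class counts
  give the printed class shares; total count / n gives the printed mean
  counts); these functions recompute each relationship with this package's
  own arithmetic;

* simulation recovery — seeded synthetic panels measure caller/oracle
  agreement, F_ROH parameter recovery, recall under heterozygote error,
  and ROH-island recovery.

All stochastic measurements take an explicit seed and are deterministic
given it.
"""

from __future__ import annotations

import numpy as np

from . import reference_tables as ref
from .caller import CallerParams, call_all, call_segments
from .evaluate import base_pair_recall
from .io import AutosomeTable, GenotypeMatrix
from .islands import build_islands, incidence_track, top_percentile_threshold
from .oracle import oracle_call_segments
from .simulate import SharedIslandSpec, SimParams, simulate_panel
from .stats import froh_table

#: study-scale conditions for the recovery experiments: 20 individuals on a
#: 50 Mb genome at 1 SNP/kb, planted tracts >= 1 Mb (mean 2.5 Mb)
RECOVERY_PANEL = dict(
    n_samples=20,
    autosomes={"1": 50_000_000},
    snp_spacing_bp=1_000.0,
    seg_min_len_bp=1_000_000,
    seg_mean_len_bp=2_500_000,
)


def froh_arithmetic_checks() -> dict[str, dict[str, float]]:
    """Per breed: F_ROH-all recomputed from the published mean total ROH
    length versus the published coefficient, both at 3 significant figures."""
    summary = ref.load_breed_roh_summary().set_index("population")
    froh = ref.load_breed_froh().set_index("population")
    out = {}
    for breed in summary.index:
        computed = ref.froh_all_from_mean_length(summary.loc[breed, "total_mean_length_mb"])
        out[breed] = {
            "computed": computed,
            "computed_3sf": ref.round_sig(computed, 3),
            "published": float(froh.loc[breed, "f_roh_all"]),
        }
    return out


def class_share_checks() -> dict[str, float]:
    """Pooled length-class percentages across the 16 breeds."""
    shares = ref.pooled_class_shares()
    return {"lt1mb_pct": shares["n_lt1mb"], "mb1_5_pct": shares["n_1_5mb"]}


def mean_count_checks() -> dict[str, dict[str, int]]:
    """Per breed: recomputed rounded mean segment count vs the published one."""
    summary = ref.load_breed_roh_summary().set_index("population")
    computed = ref.mean_counts()
    return {
        breed: {
            "computed": int(computed[breed]),
            "published": int(summary.loc[breed, "mean_n_roh"]),
        }
        for breed in summary.index
    }


def _random_instance(rng: np.random.Generator, max_snps: int) -> tuple[GenotypeMatrix, CallerParams]:
    n = int(rng.integers(2, max_snps + 1))
    spacing = int(rng.integers(2_000, 60_000))
    pos = np.cumsum(rng.integers(1, 2 * spacing, size=n)).astype(np.int64)
    calls = rng.choice([0, 1, 2, 3], size=n, p=[0.55, 0.15, 0.25, 0.05]).astype(np.int8)
    params = CallerParams(
        window_mode=("snp", "span")[int(rng.integers(0, 2))],
        window_snps=int(rng.integers(2, 80)),
        window_span_bp=int(rng.integers(100_000, 1_000_000)),
        het_allowed_per_window=int(rng.integers(0, 3)),
        missing_allowed_per_window=int(rng.integers(0, 6)),
        max_gap_bp=int(rng.integers(100_000, 1_500_000)),
        min_density_bp_per_snp=int(rng.integers(10_000, 100_000)),
        min_segment_length_bp=int(rng.integers(100_000, 1_000_000)),
        min_segment_snps=int(rng.integers(2, 30)),
        hit_fraction_threshold=float(rng.uniform(0.01, 1.0)),
        exclude_het_sites=bool(rng.integers(0, 2)),
    )
    matrix = GenotypeMatrix(samples=["s0"], positions={"1": pos}, calls={"1": calls[:, None]})
    return matrix, params


def oracle_agreement(seed: int, n_instances: int = 1000) -> dict[str, float]:
    """Fraction of random instances on which the production caller and the
    exhaustive oracle return identical segment lists.  Mixes mostly small
    instances with a tail up to the oracle's 500-SNP limit."""
    rng = np.random.default_rng(seed)
    n_agree = 0
    for trial in range(n_instances):
        max_snps = 150 if trial % 10 < 7 else 500
        matrix, params = _random_instance(rng, max_snps)
        if call_segments(matrix, "s0", params) == oracle_call_segments(matrix, "s0", params):
            n_agree += 1
    return {"agreement_fraction": n_agree / n_instances, "n_instances": n_instances}


def froh_recovery(seed: int, phis: tuple[float, ...] = (0.05, 0.15, 0.30)) -> dict[float, dict[str, float]]:
    """Mean F_ROH-all of the caller versus the planted autozygous fraction,
    on error-free panels under the study conditions."""
    out = {}
    for k, phi in enumerate(phis):
        params = SimParams(phi=phi, het_error_rate=0.0, missing_rate=0.0,
                           seed=seed + k, **RECOVERY_PANEL)
        matrix, truth = simulate_panel(params)
        segments = call_all(matrix)
        ft = froh_table(segments, matrix.samples, AutosomeTable(dict(params.autosomes)))
        mean_f = float(ft["f_roh_all"].mean())
        out[phi] = {"mean_f_all": mean_f, "abs_bias": abs(mean_f - phi)}
    return out


def het_error_recall(seed: int, phi: float = 0.15, het_error: float = 0.01) -> float:
    """Base-pair recall of planted >= 1 Mb tracts under heterozygote error."""
    params = SimParams(phi=phi, het_error_rate=het_error, seed=seed + 100, **RECOVERY_PANEL)
    matrix, truth = simulate_panel(params)
    segments = call_all(matrix)
    return base_pair_recall(truth, segments, min_truth_len_bp=1_000_000)


def island_recovery(seed: int) -> dict[str, int]:
    """Plant a 2 Mb interval autozygous in 90% of 20 individuals over 8%
    background autozygosity; count top-1% islands overlapping it."""
    island = SharedIslandSpec(chrom="1", start_bp=20_000_001, end_bp=22_000_000, sample_fraction=0.9)
    params = SimParams(phi=0.08, shared_island=island, seed=seed + 200, **RECOVERY_PANEL)
    matrix, truth = simulate_panel(params)
    segments = call_all(matrix)
    track = incidence_track(segments, matrix.positions, matrix.samples)
    cutoff = top_percentile_threshold(track, top_fraction=0.01)
    islands = build_islands(track, cutoff)
    overlapping = [
        i for i in islands
        if i.chrom == island.chrom and i.start_bp <= island.end_bp and island.start_bp <= i.end_bp
    ]
    return {"n_islands": len(islands), "n_overlapping_planted": len(overlapping)}
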