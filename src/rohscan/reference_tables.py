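"""Published breed-level ROH tables and the arithmetic that links them.

A 97-horse, 16-breed whole-genome resequencing panel published breed-level
ROH summaries (segment counts, total/mean lengths, per-length-class counts)
and the matching mean genomic inbreeding coefficients.  The raw genotypes
are not redistributable at desk scale, but the printed tables are linked by
exact arithmetic this package also performs on its own output:

* mean F_ROH-all  =  mean total ROH length / L_AUTO (2280.94 Mb),
* pooled length-class shares = class counts summed over breeds / grand total,
* mean segment count = total count / sample count, rounded half-up.

These loaders feed the validation that the package's summary arithmetic
reproduces the printed relationships.
"""

from __future__ import annotations

import math
import os

import pandas as pd

L_AUTO_MB = 2280.94

_DATA_DIR = os.path.join(os.path.dirname(__file__), "data")


def load_breed_roh_summary() -> pd.DataFrame:
    """Breed-level ROH summary table (counts, lengths in Mb, class counts)."""
    return pd.read_csv(os.path.join(_DATA_DIR, "breed_roh_summary.tsv"), sep="\t", comment="#")


def load_breed_froh() -> pd.DataFrame:
    """Breed-level mean F_ROH by length class (unitless fractions)."""
    return pd.read_csv(
        os.path.join(_DATA_DIR, "breed_froh.tsv"), sep="\t", comment="#", na_values=["NA"]
    )


def froh_all_from_mean_length(mean_total_length_mb: float, l_auto_mb: float = L_AUTO_MB) -> float:
    """F_ROH-all implied by a breed's mean total ROH length."""
    return mean_total_length_mb / l_auto_mb


def pooled_class_shares(summary: pd.DataFrame | None = None) -> dict[str, float]:
    """Percentage of all segments (pooled over breeds) in each length class."""
    df = load_breed_roh_summary() if summary is None else summary
    cols = ["n_lt1mb", "n_1_5mb", "n_5_10mb", "n_gt10mb"]
    totals = df[cols].sum()
    grand = totals.sum()
    return {c: 100.0 * totals[c] / grand for c in cols}


def mean_counts(summary: pd.DataFrame | None = None) -> pd.Series:
    """Per-breed mean segment count: total count / n samples, rounded half-up."""
    df = load_breed_roh_summary() if summary is None else summary
    ratio = df["total_n_roh"] / df["n_samples"]
    return pd.Series(
        [int(math.floor(x + 0.5)) for x in ratio], index=df["population"].tolist()
    )


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{sig}g}")
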