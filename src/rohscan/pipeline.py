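"""End-to-end pipeline: VCF -> ROH calls -> summaries -> islands.

Each stage writes its deterministic tables into the output directory and
logs parameter echoes plus counts; a failure in any stage propagates with
the stage name attached.
"""

from __future__ import annotations

import json
import logging
import os

from . import io, islands as islands_mod, reporting, stats
from .caller import call_all, validate_segments
from .config import RunConfig

log = logging.getLogger("rohscan")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> str:
    """Run call -> stats -> islands per the config; returns the output dir."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    log.info("parameters: %s", json.dumps(config.to_dict(), sort_keys=True))

    try:
        matrix = io.read_vcf(config.vcf, region_filter=config.chroms or None)
        sample_map = io.read_sample_map(config.samples)
        autosomes = (
            io.read_autosome_table(config.autosomes)
            if config.autosomes
            else io.packaged_autosome_table()
        )
    except Exception as exc:
        raise StageError("load", exc) from exc
    log.info("loaded %d sites, %d samples", matrix.n_sites, len(matrix.samples))

    try:
        segments = call_all(matrix, config.caller)
        validate_segments(segments, matrix, config.caller)
        roh_df = reporting.segments_to_frame(segments)
        reporting.write_tsv(roh_df, os.path.join(out, "roh.tsv"))
        reporting.write_segments_bed(segments, os.path.join(out, "roh.bed"))
    except Exception as exc:
        raise StageError("call", exc) from exc
    log.info("called %d ROH segments", len(segments))

    try:
        froh = stats.froh_table(segments, matrix.samples, autosomes)
        reporting.write_tsv(froh, os.path.join(out, "froh.tsv"), config.scientific_floats)
        summary = stats.summarize_population(segments, sample_map, autosomes)
        reporting.write_tsv(summary, os.path.join(out, "breed_summary.tsv"))
        per_chrom_frames = []
        for pop in sample_map.populations:
            pop_samples = sample_map.samples_of(pop)
            pop_segs = [s for s in segments if sample_map[s.sample_id] == pop]
            pc = stats.per_chromosome_coverage(
                pop_segs, len(pop_samples), autosomes, method=config.coverage_method
            )
            pc.insert(0, "population", pop)
            per_chrom_frames.append(pc)
        import pandas as pd

        reporting.write_tsv(
            pd.concat(per_chrom_frames, ignore_index=True),
            os.path.join(out, "per_chrom.tsv"),
        )
    except Exception as exc:
        raise StageError("stats", exc) from exc
    log.info("summarized %d populations", len(sample_map.populations))

    try:
        pops = [config.population] if config.population else sample_map.populations
        genes = islands_mod.read_genes(config.genes) if config.genes else []
        all_islands = []
        for pop in pops:
            pop_samples = sample_map.samples_of(pop)
            pop_segs = [s for s in segments if sample_map[s.sample_id] == pop]
            track = islands_mod.incidence_track(pop_segs, matrix.positions, pop_samples)
            cutoff = islands_mod.top_percentile_threshold(track, config.top_fraction)
            isl = islands_mod.build_islands(track, cutoff, config.merge_gap_bp)
            isl = islands_mod.annotate_islands(isl, genes)
            suffix = f".{pop}" if len(pops) > 1 else ""
            reporting.write_incidence(track, os.path.join(out, f"incidence{suffix}.tsv"))
            reporting.write_islands(
                isl,
                os.path.join(out, f"islands{suffix}.tsv"),
                os.path.join(out, f"islands{suffix}.bed"),
            )
            log.info("population %s: cutoff %.4f, %d islands", pop, cutoff, len(isl))
            all_islands.extend(isl)
    except Exception as exc:
        raise StageError("islands", exc) from exc

    config.to_toml(os.path.join(out, "run_config.toml"))
    return out
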