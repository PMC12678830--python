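"""End-to-end pipeline: normalize -> DE -> classify -> decompose ->
concordance -> embeddings -> enrichment, with every stage's table written as
TSV under an output directory.

Outputs are byte-stable for a fixed configuration and seed, so a rerun can
be diffed against a previous one.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .model import FitSettings, ShutoffExperiment, ShutoffResults
from .simulate import SimConfig, default_config

log = logging.getLogger("shutoffseq")


@dataclass
class PipelineConfig:
    """Paths, thresholds, and seeds of a full pipeline run."""

    counts: str | None = None
    design: str | None = None
    gmt: str | None = None
    outdir: str = "shutoffseq_out"
    simulate: bool = False
    sim: SimConfig = field(default_factory=default_config)
    settings: FitSettings = field(default_factory=FitSettings)
    run_tsne: bool = True
    run_enrichment: bool = True

    def validate(self) -> None:
        self.settings.validate()
        if not self.simulate and (self.counts is None or self.design is None):
            raise ValueError("provide counts and design paths, or set simulate=True")


def _write_stage_tables(results: ShutoffResults, outdir: Path, config: PipelineConfig) -> None:
    io.write_table(
        results.normalization.size_factors.to_frame(), outdir / "size_factors.tsv"
    )
    io.write_table(results.normalization.condition_means, outdir / "condition_means.tsv")
    for name, res in results.contrasts.items():
        io.write_table(res.table, outdir / f"contrast_{name}.tsv")
    io.write_table(results.annotated_table(), outdir / "merged_gene_table.tsv")
    io.write_table(results.ranking(), outdir / "shutoff_ranking.tsv")
    with open(outdir / "overlap_summary.json", "w", encoding="utf-8") as fh:
        json.dump(results.overlap(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_concordance(results: ShutoffResults, outdir: Path) -> None:
    candidates = results.candidate_classes()
    if len(candidates) < 3:
        log.info("too few late-induced candidates for concordance tables")
        return
    io.write_table(results.effect_vectors(), outdir / "effect_vectors.tsv")
    io.write_table(results.similarity(), outdir / "similarity.tsv")
    io.write_table(results.effect_correlations(), outdir / "effect_correlations.tsv")


def _write_embeddings(results: ShutoffResults, outdir: Path, config: PipelineConfig) -> None:
    io.write_table(results.condition_l2fc(), outdir / "condition_l2fc.tsv")
    informative = results.informative_genes()
    io.write_table(informative, outdir / "informative_genes.tsv")
    if len(informative) >= 2:
        _, _, row_order, col_order = results.heatmap_clustering()
        leaf = pd.DataFrame({"row_order": pd.Series(row_order)})
        io.write_table(leaf, outdir / "heatmap_row_order.tsv", index=False)
        io.write_table(
            pd.DataFrame({"col_order": pd.Series(col_order)}),
            outdir / "heatmap_col_order.tsv", index=False,
        )
    coords, var_frac = results.pca()
    io.write_table(coords, outdir / "pca_coordinates.tsv")
    io.write_table(
        pd.DataFrame({"variance_fraction": var_frac},
                     index=[f"PC{i+1}" for i in range(len(var_frac))]),
        outdir / "pca_variance.tsv",
    )
    if config.run_tsne:
        genes = results.candidate_classes()
        perp = min(results.settings.tsne_perplexity, max((len(genes) - 1) / 3.0, 2.0))
        if len(genes) >= 3 * perp and len(genes) >= 10:
            io.write_table(results.tsne(perplexity=perp), outdir / "tsne_coordinates.tsv")
        else:
            log.info("skipping t-SNE: %d candidates is too few", len(genes))


def run_pipeline(config: PipelineConfig) -> ShutoffResults:
    """Execute every stage and write the declared outputs under
    ``config.outdir``. Returns the fitted results object."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        experiment = ShutoffExperiment.simulate(config.sim)
        io.write_counts(experiment.counts, outdir / "simulated_counts.tsv")
        io.write_design(experiment.design, outdir / "simulated_design.tsv")
        io.write_table(experiment.truth, outdir / "simulated_truth.tsv")
    else:
        experiment = ShutoffExperiment.from_tsv(config.counts, config.design)

    resolved = {
        "settings": dataclasses.asdict(config.settings),
        "simulate": config.simulate,
        "sim_seed": config.sim.seed if config.simulate else None,
        "counts": config.counts,
        "design": config.design,
        "gmt": config.gmt,
    }
    log.info("resolved config: %s", json.dumps(resolved, sort_keys=True))
    with open(outdir / "run_config.json", "w", encoding="utf-8") as fh:
        json.dump(resolved, fh, indent=2, sort_keys=True)
        fh.write("\n")

    results = experiment.fit(config.settings)
    _write_stage_tables(results, outdir, config)
    _write_concordance(results, outdir)
    _write_embeddings(results, outdir, config)

    if config.run_enrichment and config.gmt:
        gene_sets = io.read_gmt(config.gmt)
        io.write_table(results.enrich(gene_sets), outdir / "enrichment.tsv", index=False)

    if experiment.truth is not None:
        with open(outdir / "truth_evaluation.json", "w", encoding="utf-8") as fh:
            json.dump(results.evaluate(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    with open(outdir / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(results.summary() + "\n")
    return results


def validate_against_reference(
    merged: pd.DataFrame, reference: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Compare a merged gene table against an externally supplied one.

    Joins on gene id and reports, per shared numeric column, the count of
    compared genes and the Pearson correlation — a quick consistency check
    against a deposited results table.
    """
    shared = merged.index.intersection(reference.index)
    if len(shared) == 0:
        raise ValueError("no shared gene ids between the tables")
    cols = columns or [
        c for c in merged.columns
        if c in reference.columns and pd.api.types.is_numeric_dtype(merged[c])
    ]
    rows = []
    for c in cols:
        a = merged.loc[shared, c]
        b = reference.loc[shared, c]
        ok = a.notna() & b.notna()
        r = a[ok].corr(b[ok]) if ok.sum() >= 3 else float("nan")
        rows.append({"column": c, "n": int(ok.sum()), "pearson_r": r})
    return pd.DataFrame(rows)
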