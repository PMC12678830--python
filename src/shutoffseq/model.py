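"""Model / results objects tying the pipeline stages together.

``ShutoffExperiment`` holds a count matrix and design sheet (read from TSV,
passed in directly, or simulated with truth labels); ``fit()`` runs
normalization, differential expression, activity classification, and
shut-off decomposition, returning a ``ShutoffResults`` carrying every
per-gene table plus ``summary()``. Embeddings, concordance, and enrichment
hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import activity, concordance, de, embedding, enrichment, io, shutoff
from .conditions import BIC_SERIES, DEFAULT_CONTRASTS, ContrastSpec
from .simulate import (
    SimConfig,
    build_design,
    default_config,
    generate_truth,
    simulate_counts,
    with_seed,
)


@dataclass
class FitSettings:
    """Thresholds and switches of a fit; defaults follow the study design."""

    fdr_cutoff: float = 0.05
    anova_fdr_cutoff: float = 0.01
    heatmap_sd_threshold: float = 0.5
    pseudocount: float = 1.0
    tsne_seed: int = 102
    tsne_perplexity: float = 30.0
    use_shrunk: bool = True
    extremum_significance: bool = True
    top_n_ranking: int = 20

    def validate(self) -> None:
        for name in ("fdr_cutoff", "anova_fdr_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.heatmap_sd_threshold < 0 or self.pseudocount < 0:
            raise ValueError("thresholds must be non-negative")


class ShutoffExperiment:
    """A nine-condition interference experiment ready for analysis."""

    def __init__(
        self,
        counts: pd.DataFrame,
        design: pd.DataFrame,
        contrasts: list[ContrastSpec] | None = None,
        truth: pd.DataFrame | None = None,
    ):
        design = io.validate_design(design) if "condition" not in design.columns else design
        io.check_counts_design(counts, design)
        self.counts = counts
        self.design = design.reset_index(drop=True)
        self.contrast_specs = contrasts if contrasts is not None else list(DEFAULT_CONTRASTS)
        self.truth = truth

    @classmethod
    def from_tsv(cls, counts_path, design_path, **kwargs) -> "ShutoffExperiment":
        counts = io.read_counts(counts_path)
        design = io.read_design(design_path)
        return cls(counts, design, **kwargs)

    @classmethod
    def simulate(cls, config: SimConfig | None = None, seed: int | None = None,
                 **kwargs) -> "ShutoffExperiment":
        """Simulate a truth-labeled experiment (default configuration unless
        a config is given; ``seed`` overrides the config's seed)."""
        cfg = config or default_config()
        if seed is not None:
            cfg = with_seed(cfg, seed)
        truth = generate_truth(cfg)
        design = build_design(cfg.n_replicates)
        counts = simulate_counts(truth, design, cfg)
        return cls(counts, design, truth=truth, **kwargs)

    def fit(self, settings: FitSettings | None = None) -> "ShutoffResults":
        settings = settings or FitSettings()
        settings.validate()
        norm = de.estimate_size_factors(self.counts, self.design)
        disp = de.estimate_dispersions(self.counts, norm, self.design)
        contrasts = de.run_contrasts(
            self.counts, self.design, self.contrast_specs, norm, disp
        )
        merged = de.merge_contrasts(contrasts)
        anova = activity.anova_screen(norm.normalized, self.design)
        classification = activity.classify_activity(
            contrasts,
            norm.condition_means,
            fdr_cutoff=settings.fdr_cutoff,
            extremum_significance=settings.extremum_significance,
        )
        calls = shutoff.classify_shutoff(
            classification, contrasts,
            fdr_cutoff=settings.fdr_cutoff, use_shrunk=settings.use_shrunk,
        )
        candidates = activity.select_candidates(
            classification, merged, anova, settings.anova_fdr_cutoff
        )
        return ShutoffResults(
            experiment=self,
            settings=settings,
            normalization=norm,
            dispersions=disp,
            contrasts=contrasts,
            merged_table=merged,
            anova=anova,
            classification=classification,
            calls=calls,
            candidates=candidates,
        )


@dataclass
class ShutoffResults:
    """Fitted pipeline state: per-gene tables and report constructors."""

    experiment: ShutoffExperiment
    settings: FitSettings
    normalization: de.NormalizationResult
    dispersions: de.DispersionEstimate
    contrasts: dict[str, de.ContrastResult]
    merged_table: pd.DataFrame
    anova: pd.DataFrame
    classification: pd.DataFrame
    calls: pd.DataFrame
    candidates: pd.Index
    _cache: dict = field(default_factory=dict, repr=False)

    # ------------------------------------------------------------------ gene table
    def annotated_table(self) -> pd.DataFrame:
        """The merged wide table with activity and shut-off annotations."""
        out = self.merged_table.join(self.anova, how="left")
        out = out.join(self.classification, how="left")
        out = out.join(self.calls.drop(columns=["protocol"], errors="ignore"), how="left")
        out["candidate"] = out.index.isin(self.candidates)
        return out

    # ------------------------------------------------------------ shut-off reports
    def ranking(self, top_n: int | None = None) -> pd.DataFrame:
        return shutoff.build_ranking(
            self.calls, self.classification, top_n or self.settings.top_n_ranking
        )

    def overlap(self) -> dict:
        return shutoff.overlap_summary(self.calls)

    # -------------------------------------------------------------- concordance
    def candidate_classes(self, classes=("late.induced",)) -> pd.Index:
        keep = self.classification["activity_class"].isin(classes)
        return self.candidates.intersection(self.classification.index[keep])

    def effect_vectors(self, classes=("late.induced",)) -> pd.DataFrame:
        key = ("effects", tuple(classes))
        if key not in self._cache:
            self._cache[key] = concordance.build_effect_vectors(
                self.merged_table,
                self.candidate_classes(classes),
                use_shrunk=self.settings.use_shrunk,
            )
        return self._cache[key]

    def similarity(self, a: str = "total", b: str = "spillover",
                   classes=("late.induced",)) -> pd.DataFrame:
        return concordance.similarity_table(self.effect_vectors(classes), a, b)

    def effect_correlations(self, classes=("late.induced",)) -> pd.DataFrame:
        return concordance.pairwise_pearson(self.effect_vectors(classes))

    # ---------------------------------------------------------------- embeddings
    def condition_l2fc(self) -> pd.DataFrame:
        if "cond_l2fc" not in self._cache:
            self._cache["cond_l2fc"] = embedding.condition_l2fc_matrix(
                self.normalization.condition_means, self.settings.pseudocount
            )
        return self._cache["cond_l2fc"]

    def informative_genes(self) -> pd.DataFrame:
        return embedding.informative_gene_filter(
            self.condition_l2fc(), self.settings.heatmap_sd_threshold
        )

    def heatmap_clustering(self):
        return embedding.hierarchical_cluster(self.informative_genes())

    def pca(self, top_n: int = 500):
        return embedding.pca_embed(self.normalization.normalized, top_n)

    def tsne(self, classes=("late.induced",), perplexity: float | None = None,
             seed: int | None = None) -> pd.DataFrame:
        genes = self.candidate_classes(classes)
        lfc_cols = [c for c in self.merged_table.columns if c.endswith(".l2fc_shrunk")]
        mat = self.merged_table.loc[genes, lfc_cols].dropna()
        return embedding.tsne_embed(
            mat,
            seed=self.settings.tsne_seed if seed is None else seed,
            perplexity=self.settings.tsne_perplexity if perplexity is None else perplexity,
        )

    # ---------------------------------------------------------------- enrichment
    def expressed_background(self) -> pd.Index:
        """Genes with DE statistics available in every Bic-vs-untreated
        comparison — the effective genomic background for enrichment."""
        cols = [f"bic_{t}_vs_untreated.fdr" for t in ("0.5h", "1h", "2h")]
        have = self.merged_table[cols].notna().all(axis=1)
        return self.merged_table.index[have]

    def enrich(self, gene_sets: dict[str, list[str]],
               queries: dict[str, list] | None = None) -> pd.DataFrame:
        bg = self.expressed_background()
        if queries is None:
            ev = self.calls[self.calls["evaluable"]]
            queries = {
                "active_shutoff": list(ev.index[ev["active_call"] == "down"]),
                "passive_shutoff": list(ev.index[ev["passive_call"] == "down"]),
                "resistant": list(
                    ev.index[(ev["active_call"] != "down") & (ev["passive_call"] != "down")]
                ),
            }
        return enrichment.compare_queries(queries, gene_sets, bg,
                                          p_cutoff=1.0, fdr_cutoff=1.0)

    # ------------------------------------------------------------------- scoring
    def evaluate(self) -> dict:
        """Score calls against simulation truth (simulated experiments only)."""
        from .simulate import truth_eval

        if self.experiment.truth is None:
            raise ValueError("experiment carries no truth labels")
        ann = self.classification.join(
            self.calls.drop(columns=["protocol"], errors="ignore"), how="left"
        )
        return truth_eval(ann, self.experiment.truth)

    # -------------------------------------------------------------------- summary
    def summary(self) -> str:
        cls_counts = self.classification["activity_class"].value_counts()
        ov = self.overlap()
        lines = [
            "Excitotoxic shut-off decomposition",
            "==================================",
            f"genes: {len(self.experiment.counts)}   samples: {self.experiment.counts.shape[1]}"
            f"   contrasts: {len(self.contrasts)}",
            "",
            "Activity classes (Bic time course):",
        ]
        for name in activity.ACTIVITY_CLASSES:
            lines.append(f"  {name:<16} {int(cls_counts.get(name, 0)):>6}")
        lines += [
            "",
            f"candidate genes (ANOVA FDR < {self.settings.anova_fdr_cutoff},"
            f" classified, complete L2FC): {len(self.candidates)}",
            "",
            "Shut-off decomposition of evaluable induced genes:",
            f"  evaluable: {ov['n_evaluable']}",
            f"  passive only: {ov['passive_only']}   active only: {ov['active_only']}"
            f"   both: {ov['both']}",
            f"  boosted: {ov['boosted']}   resistant: {ov['resistant']}"
            f"   boosted by both: {ov['boosted_both']}",
        ]
        ev = self.effect_vectors() if len(self.candidate_classes()) >= 3 else None
        if ev is not None and len(ev) >= 3:
            r = self.effect_correlations()
            lines += [
                "",
                "Effect-vector Pearson correlations (late-induced candidates):",
                f"  r(passive, active)    = {r.loc['passive', 'active']:+.3f}",
                f"  r(total, active)      = {r.loc['total', 'active']:+.3f}",
                f"  r(spillover, active)  = {r.loc['spillover', 'active']:+.3f}",
                f"  r(spillover, total)   = {r.loc['spillover', 'total']:+.3f}",
            ]
        top = self.ranking(5)
        if len(top):
            lines += ["", "Strongest total shut-off (top 5):"]
            for gene, row in top.iterrows():
                lines.append(
                    f"  {gene:<12} {row['induction_category']:<6}"
                    f" shut-off {row['shutoff_pct']:+7.1f}%"
                    f"  passive {row['passive_pct']:+7.1f}%  active {row['active_pct']:+7.1f}%"
                )
        return "\n".join(lines)
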