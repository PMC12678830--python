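"""Bic time-course activity classes and the per-gene ANOVA screen.

Genes are categorized by their response over the Bic induction series
(untreated, 0.5 h, 1 h, 2 h): "early" genes reach their expression extremum
at 1 h of AP firing and are assayed with the short protocol; "late" genes at
2 h (long protocol); genes significant only at the 0.5 h time point are
"transient" and excluded from the interference assays; everything else is
unresponsive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import conditions as cond
from .de import ContrastResult, bh_adjust

ACTIVITY_CLASSES = [
    "early.induced",
    "late.induced",
    "early.repressed",
    "late.repressed",
    "transient",
    "unresponsive",
]

BIC_CONTRAST_NAMES = {
    0.5: "bic_0.5h_vs_untreated",
    1.0: "bic_1h_vs_untreated",
    2.0: "bic_2h_vs_untreated",
}


def anova_screen(
    normalized: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """One-way ANOVA per gene across the Bic series, BH-FDR across genes.

    Groups are the four Bic-series conditions on size-factor-normalized
    counts. Requires >= 2 replicates in every group. Genes with zero variance
    everywhere are assigned p = 1.
    """
    groups = []
    for c in cond.BIC_SERIES:
        samples = design.loc[design["condition"] == c, "sample_id"].tolist()
        samples = [s for s in samples if s in normalized.columns]
        if len(samples) < 2:
            raise ValueError(f"ANOVA screen needs >= 2 replicates in condition {c!r}")
        groups.append(normalized[samples].to_numpy())
    if len(groups) < 2:
        raise ValueError("ANOVA screen needs >= 2 groups")
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = stats.f_oneway(*groups, axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    fdr = bh_adjust(p)
    return pd.DataFrame(
        {"anova_f": stat, "anova_p": p, "anova_fdr": fdr}, index=normalized.index
    )


def classify_activity(
    contrasts: dict[str, ContrastResult],
    condition_means: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    tie_tolerance: float = 0.01,
    extremum_significance: bool = True,
) -> pd.DataFrame:
    """Assign each gene one activity class and a protocol allocation.

    Rules, applied to the three Bic-vs-untreated contrasts and the normalized
    condition means:

    * unresponsive — no Bic contrast with FDR < ``fdr_cutoff``;
    * transient — significant (in the response direction) only at 0.5 h;
    * early.induced / late.induced — significant upregulation with the
      condition-mean maximum over 1 h / 2 h at the class-defining time
      (means within ``tie_tolerance`` relative of each other classify late,
      since the long protocol covers genes still high at 2 h);
    * early.repressed / late.repressed — mirrored for downregulation.

    With ``extremum_significance`` (default) the gene must be significant at
    the class-defining time point itself; otherwise significance anywhere in
    the direction suffices. Early classes are allocated to the short
    protocol, late classes to the long protocol.
    """
    for t, name in BIC_CONTRAST_NAMES.items():
        if name not in contrasts:
            raise ValueError(f"missing Bic contrast {name!r}")
    for c in cond.BIC_SERIES:
        if c not in condition_means.columns:
            raise ValueError(f"missing condition means for {c!r}")

    genes = condition_means.index
    sig_up = {}
    sig_dn = {}
    for t, name in BIC_CONTRAST_NAMES.items():
        tab = contrasts[name].table.reindex(genes)
        sig = (tab["fdr"] < fdr_cutoff) & (tab["status"] == "ok")
        sig_up[t] = (sig & (tab["l2fc_mle"] > 0)).to_numpy()
        sig_dn[t] = (sig & (tab["l2fc_mle"] < 0)).to_numpy()

    m1 = condition_means[cond.BIC_1H].to_numpy(dtype=float)
    m2 = condition_means[cond.BIC_2H].to_numpy(dtype=float)
    # late when the 2 h mean exceeds the 1 h mean or ties within tolerance
    late_mean = m2 >= m1 * (1 - tie_tolerance)

    classes = np.full(len(genes), "unresponsive", dtype=object)

    for direction, sig_t in (("induced", sig_up), ("repressed", sig_dn)):
        any_sig = sig_t[0.5] | sig_t[1.0] | sig_t[2.0]
        transient = sig_t[0.5] & ~sig_t[1.0] & ~sig_t[2.0]
        if direction == "repressed":
            late_extremum = m2 <= m1 * (1 + tie_tolerance)
        else:
            late_extremum = late_mean
        if extremum_significance:
            late = any_sig & ~transient & late_extremum & sig_t[2.0]
            early = any_sig & ~transient & ~late_extremum & sig_t[1.0]
        else:
            late = any_sig & ~transient & late_extremum
            early = any_sig & ~transient & ~late_extremum
        unassigned = classes == "unresponsive"
        classes[unassigned & transient] = "transient"
        classes[unassigned & late] = f"late.{direction}"
        classes[unassigned & early] = f"early.{direction}"

    protocol = np.where(
        np.isin(classes, ["early.induced", "early.repressed"]), "sp",
        np.where(np.isin(classes, ["late.induced", "late.repressed"]), "lp", "none"),
    )
    return pd.DataFrame(
        {"activity_class": classes, "protocol": protocol}, index=genes
    )


def select_candidates(
    classification: pd.DataFrame,
    merged_table: pd.DataFrame,
    anova: pd.DataFrame,
    anova_fdr_cutoff: float = 0.01,
    contrast_names: list[str] | None = None,
) -> pd.Index:
    """Candidate genes for embedding and concordance analyses.

    Intersection of three criteria: ANOVA FDR below the cutoff, membership in
    an early/late activity class, and an L2FC assigned in every pair-wise
    comparison (no NA in any contrast of the merged table).
    """
    classified = classification["activity_class"].isin(
        ["early.induced", "late.induced", "early.repressed", "late.repressed"]
    )
    anova_pass = anova["anova_fdr"].reindex(classification.index) < anova_fdr_cutoff
    if contrast_names is None:
        lfc_cols = [c for c in merged_table.columns if c.endswith(".l2fc_shrunk")]
    else:
        lfc_cols = [f"{n}.l2fc_shrunk" for n in contrast_names]
    complete = merged_table[lfc_cols].notna().all(axis=1)
    complete = complete.reindex(classification.index, fill_value=False)
    keep = classified & anova_pass & complete
    return classification.index[keep]
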