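"""Passive / active / TBOA shut-off calls, percentages, ranking, overlaps.

For each activity-responsive gene, the interference contrasts of its
allocated protocol decompose the excitotoxic dysregulation of its induction:

* passive — TTX vs Bic-only (AP-firing cessation),
* active — TTX+NMDA vs TTX (toxic esNMDAR signaling on top of silencing),
* total — TTX+NMDA vs Bic-only,
* TBOA — TBOA vs Bic-only (glutamate spillover; long protocol only).

A component is called "down" (shut-off) when the shrunken L2FC of the
defining contrast is negative at FDR < 0.05, "up" (boosted) when positive,
"ns" otherwise. Percent metrics translate an L2FC into the percent change of
induced expression, ``100 * (2**L2FC - 1)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .conditions import COMPONENT_CONTRASTS, PROTOCOL_CONTRASTS
from .de import ContrastResult

CALL_LEVELS = ["down", "up", "ns", "not_tested"]


def shutoff_percent(l2fc):
    """Percent change of induction implied by an L2FC: ``100*(2**l2fc - 1)``.

    Sign-carrying (negative = reduction); NA passes through.
    """
    arr = np.asarray(l2fc, dtype=float)
    out = 100.0 * (np.exp2(arr) - 1.0)
    if np.ndim(l2fc) == 0:
        return float(out)
    return out


def _call(lfc: pd.Series, fdr: pd.Series, cutoff: float) -> pd.Series:
    call = pd.Series("ns", index=lfc.index, dtype=object)
    sig = (fdr < cutoff) & lfc.notna()
    call[sig & (lfc < 0)] = "down"
    call[sig & (lfc > 0)] = "up"
    call[lfc.isna() | fdr.isna()] = "ns"
    return call


def classify_shutoff(
    classification: pd.DataFrame,
    contrasts: dict[str, ContrastResult],
    fdr_cutoff: float = 0.05,
    use_shrunk: bool = True,
) -> pd.DataFrame:
    """Shut-off calls and percent metrics for allocated (early/late) genes.

    A gene is evaluable only if statistics exist (status ok) for every
    pair-wise comparison of its allocated protocol; non-evaluable genes carry
    no calls. TBOA is tested in the long protocol only; short-protocol genes
    get ``tboa = not_tested``.

    Output columns: protocol, evaluable, {passive,active,tboa}_call, and
    {shutoff,passive,active,tboa}_pct computed from the shrunken L2FC of the
    respective contrast (MLE variant via ``use_shrunk=False``).
    """
    alloc = classification[classification["protocol"].isin(["sp", "lp"])]
    if (classification["protocol"].isna()).any():
        raise ValueError("every gene needs a protocol allocation (may be 'none')")
    lfc_col = "l2fc_shrunk" if use_shrunk else "l2fc_mle"

    rows = []
    for protocol in ("sp", "lp"):
        genes = alloc.index[alloc["protocol"] == protocol]
        if len(genes) == 0:
            continue
        needed = PROTOCOL_CONTRASTS[protocol]
        missing = [n for n in needed if n not in contrasts]
        if missing:
            raise ValueError(f"missing contrasts for protocol {protocol}: {missing}")
        ok_all = pd.Series(True, index=genes)
        for name in needed:
            status = contrasts[name].table["status"].reindex(genes)
            ok_all &= status == "ok"

        comp = COMPONENT_CONTRASTS[protocol]
        sub = pd.DataFrame(index=genes)
        sub["protocol"] = protocol
        sub["evaluable"] = ok_all
        for component in ("passive", "active", "total", "tboa"):
            if component not in comp:
                sub[f"{component}_call"] = "not_tested"
                sub[f"{component}_pct" if component != "total" else "shutoff_pct"] = np.nan
                continue
            tab = contrasts[comp[component]].table.reindex(genes)
            lfc = tab[lfc_col]
            call = _call(lfc, tab["fdr"], fdr_cutoff)
            pct = pd.Series(shutoff_percent(lfc.to_numpy()), index=genes)
            call[~ok_all] = "ns"
            pct[~ok_all] = np.nan
            if component == "total":
                sub["shutoff_pct"] = pct
                sub["total_call"] = call
            else:
                sub[f"{component}_call"] = call
                sub[f"{component}_pct"] = pct
        not_eval = ~ok_all
        for c in ("passive_call", "active_call", "total_call"):
            sub.loc[not_eval, c] = "ns"
        rows.append(sub)
    if not rows:
        return pd.DataFrame(
            columns=["protocol", "evaluable", "passive_call", "passive_pct",
                     "active_call", "active_pct", "total_call", "shutoff_pct",
                     "tboa_call", "tboa_pct"]
        )
    out = pd.concat(rows)
    return out.reindex(alloc.index)


def build_ranking(
    calls: pd.DataFrame,
    classification: pd.DataFrame,
    top_n: int = 20,
) -> pd.DataFrame:
    """Rank evaluable genes by total shut-off percent, most negative first.

    Ties break lexicographically by gene id. Columns mirror the reporting
    table: induction category, shut-off %, then call + percent for the
    passive, active, and TBOA components.
    """
    evaluable = calls[calls["evaluable"] & calls["shutoff_pct"].notna()].copy()
    if len(evaluable) == 0:
        return pd.DataFrame(
            columns=["induction_category", "shutoff_pct", "passive_call", "passive_pct",
                     "active_call", "active_pct", "tboa_call", "tboa_pct"]
        )
    evaluable["induction_category"] = (
        classification["activity_class"].reindex(evaluable.index)
        .str.replace(r"\..*", "", regex=True)
    )
    # stable sort on a lexicographically pre-sorted index -> deterministic ties
    evaluable = evaluable.sort_index().sort_values("shutoff_pct", kind="mergesort")
    cols = ["induction_category", "shutoff_pct", "passive_call", "passive_pct",
            "active_call", "active_pct", "tboa_call", "tboa_pct"]
    return evaluable[cols].head(top_n)


def overlap_summary(calls: pd.DataFrame) -> dict:
    """Mutually exclusive shut-off categories plus TBOA set overlaps.

    Categories partition the evaluable genes: both (passive and active down),
    passive_only, active_only, boosted (no down call but some up call),
    resistant (all ns). ``boosted_both`` counts genes boosted by both
    interventions — reported so the "never both" observation is a query, not
    an assumption.
    """
    ev = calls[calls["evaluable"]]
    p = ev["passive_call"]
    a = ev["active_call"]
    t = ev["tboa_call"] if "tboa_call" in ev else pd.Series("not_tested", index=ev.index)
    both = (p == "down") & (a == "down")
    passive_only = (p == "down") & (a != "down")
    active_only = (a == "down") & (p != "down")
    any_down = (p == "down") | (a == "down")
    boosted = ~any_down & ((p == "up") | (a == "up"))
    resistant = ~any_down & ~boosted
    tboa_down = t == "down"
    summary = {
        "n_evaluable": int(len(ev)),
        "both": int(both.sum()),
        "passive_only": int(passive_only.sum()),
        "active_only": int(active_only.sum()),
        "boosted": int(boosted.sum()),
        "resistant": int(resistant.sum()),
        "boosted_both": int(((p == "up") & (a == "up")).sum()),
        "passive_down": int((p == "down").sum()),
        "active_down": int((a == "down").sum()),
        "tboa_down": int(tboa_down.sum()),
        "tboa_and_active": int((tboa_down & (a == "down")).sum()),
        "tboa_and_passive": int((tboa_down & (p == "down")).sum()),
    }
    return summary
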