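"""Gene-wise concordance of interference effects and their correlation
structure.

The similarity statistic ``s = a*b / sqrt(a**2 + b**2)`` measures, per gene,
the concordance in directionality and strength of two effect L2FCs: positive
when the effects agree in sign, negative when they disagree, and bounded in
magnitude by the smaller of the two inputs. It is extended continuously with
``s(0, 0) = 0``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .conditions import EFFECT_VECTOR_CONTRASTS


def similarity(a, b):
    """Signed concordance ``a*b/sqrt(a^2+b^2)`` of two L2FC values (or arrays).

    Symmetric, positively homogeneous of degree 1, and ``|s| <= min(|a|,|b|)``.
    Raises on non-finite input.
    """
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a_arr)) and np.all(np.isfinite(b_arr))):
        raise ValueError("similarity requires finite inputs")
    denom = np.sqrt(a_arr**2 + b_arr**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, a_arr * b_arr / np.where(denom > 0, denom, 1.0), 0.0)
    if np.ndim(a) == 0 and np.ndim(b) == 0:
        return float(s)
    return s


def build_effect_vectors(
    merged_table: pd.DataFrame,
    candidate_set,
    use_shrunk: bool = True,
) -> pd.DataFrame:
    """Per-gene effect L2FC matrix over the long-protocol comparisons.

    Columns: passive (TTX vs Bic-only), spillover (TBOA vs Bic-only), total
    (TTX+NMDA vs Bic-only), active (TTX+NMDA vs TTX), active_tboa (TBOA vs
    TTX). Restricted to ``candidate_set``; genes lacking any value are
    dropped (their count is in ``.attrs['n_dropped']``).
    """
    candidates = pd.Index(candidate_set)
    if len(candidates) == 0:
        raise ValueError("empty candidate set")
    stat = "l2fc_shrunk" if use_shrunk else "l2fc_mle"
    cols = {}
    for effect, contrast in EFFECT_VECTOR_CONTRASTS.items():
        col = f"{contrast}.{stat}"
        if col not in merged_table.columns:
            raise ValueError(f"merged table lacks column {col!r}")
        cols[effect] = merged_table[col]
    mat = pd.DataFrame(cols).reindex(candidates)
    complete = mat.notna().all(axis=1)
    out = mat.loc[complete]
    out.attrs["n_dropped"] = int((~complete).sum())
    return out


def similarity_table(effect_vectors: pd.DataFrame, a: str = "total",
                     b: str = "spillover") -> pd.DataFrame:
    """Per-gene similarity between two effect columns (default: total
    excitotoxicity vs glutamate spillover)."""
    s = similarity(effect_vectors[a].to_numpy(), effect_vectors[b].to_numpy())
    return pd.DataFrame({"a": effect_vectors[a], "b": effect_vectors[b],
                         "similarity": s}, index=effect_vectors.index)


def pairwise_pearson(effect_vectors: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between every pair of effect columns.

    Diagonal = 1; zero-variance columns yield NA (with a warning from pandas
    suppressed — the NA is the contract).
    """
    if len(effect_vectors) < 3:
        raise ValueError("pairwise correlation needs >= 3 genes")
    x = effect_vectors.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r, dtype=float)
    bad = sd == 0
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    np.fill_diagonal(r, np.where(bad, np.nan, 1.0))
    return pd.DataFrame(r, index=effect_vectors.columns, columns=effect_vectors.columns)
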