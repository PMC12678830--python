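"""Canonical condition labels and contrast definitions.

The experimental design has nine conditions on mouse hippocampal primary
neurons: an untreated control; a bicuculline (Bic) induction time course
(0.5, 1, 2 h of action-potential firing); a short protocol (SP: 0.5 h Bic
followed by 0.5 h intervention with TTX or TTX+NMDA, harvested at 1 h); and
a long protocol (LP: 1 h Bic followed by 1 h intervention with TTX,
TTX+NMDA, or TBOA, harvested at 2 h). Five biological replicates each by
default.

Pair-wise contrasts are expressed as (numerator condition, denominator
condition); the log2 fold change reports numerator relative to denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

UNTREATED = "untreated"
BIC_05H = "bic_0.5h"
BIC_1H = "bic_1h"
BIC_2H = "bic_2h"
SP_TTX = "sp_ttx"
SP_TTX_NMDA = "sp_ttx_nmda"
LP_TTX = "lp_ttx"
LP_TTX_NMDA = "lp_ttx_nmda"
LP_TBOA = "lp_tboa"

CONDITIONS = [
    UNTREATED,
    BIC_05H,
    BIC_1H,
    BIC_2H,
    SP_TTX,
    SP_TTX_NMDA,
    LP_TTX,
    LP_TTX_NMDA,
    LP_TBOA,
]

#: Bic induction series used for the per-gene ANOVA screen and activity classes.
BIC_SERIES = [UNTREATED, BIC_05H, BIC_1H, BIC_2H]

#: Bic-only endpoint of each interference protocol.
PROTOCOL_ENDPOINT = {"sp": BIC_1H, "lp": BIC_2H}

VALID_PROTOCOLS = {"none", "bic", "sp", "lp"}
VALID_TREATMENTS = {"untreated", "bic", "ttx", "ttx_nmda", "tboa"}

#: Elapsed time (h) from Bic onset to RNA harvest for each condition.
CONDITION_TIME_H = {
    UNTREATED: 0.0,
    BIC_05H: 0.5,
    BIC_1H: 1.0,
    BIC_2H: 2.0,
    SP_TTX: 1.0,
    SP_TTX_NMDA: 1.0,
    LP_TTX: 2.0,
    LP_TTX_NMDA: 2.0,
    LP_TBOA: 2.0,
}


def condition_of(protocol: str, treatment: str, time_h: float) -> str:
    """Map a design-sheet row to its canonical condition label."""
    if protocol not in VALID_PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    if treatment not in VALID_TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    if treatment == "untreated":
        return UNTREATED
    if protocol == "bic":
        label = {0.5: BIC_05H, 1.0: BIC_1H, 2.0: BIC_2H}.get(float(time_h))
        if label is None:
            raise ValueError(f"Bic time point {time_h} h is not part of the design")
        return label
    if protocol == "sp":
        if treatment == "ttx":
            return SP_TTX
        if treatment == "ttx_nmda":
            return SP_TTX_NMDA
        raise ValueError(f"treatment {treatment!r} is not applied in the short protocol")
    if protocol == "lp":
        return {"ttx": LP_TTX, "ttx_nmda": LP_TTX_NMDA, "tboa": LP_TBOA}[treatment]
    raise ValueError(f"inconsistent design row: {protocol!r}/{treatment!r}")


@dataclass(frozen=True)
class ContrastSpec:
    """A pair-wise differential-expression comparison.

    ``tag`` names the biological effect the contrast measures, following the
    passive / active / spillover vocabulary of the interference protocols.
    """

    name: str
    numerator: str
    denominator: str
    tag: str = ""

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("numerator and denominator conditions must differ")


#: Default contrast set: each treated condition vs untreated, plus the
#: within-protocol interference comparisons (passive, total, active, spillover).
DEFAULT_CONTRASTS = [
    ContrastSpec("bic_0.5h_vs_untreated", BIC_05H, UNTREATED, "bic_series"),
    ContrastSpec("bic_1h_vs_untreated", BIC_1H, UNTREATED, "bic_series"),
    ContrastSpec("bic_2h_vs_untreated", BIC_2H, UNTREATED, "bic_series"),
    ContrastSpec("sp_ttx_vs_untreated", SP_TTX, UNTREATED, "sp"),
    ContrastSpec("sp_ttx_nmda_vs_untreated", SP_TTX_NMDA, UNTREATED, "sp"),
    ContrastSpec("lp_ttx_vs_untreated", LP_TTX, UNTREATED, "lp"),
    ContrastSpec("lp_ttx_nmda_vs_untreated", LP_TTX_NMDA, UNTREATED, "lp"),
    ContrastSpec("lp_tboa_vs_untreated", LP_TBOA, UNTREATED, "lp"),
    ContrastSpec("sp_ttx_vs_bic_1h", SP_TTX, BIC_1H, "sp_passive"),
    ContrastSpec("sp_ttx_nmda_vs_bic_1h", SP_TTX_NMDA, BIC_1H, "sp_total"),
    ContrastSpec("sp_ttx_nmda_vs_sp_ttx", SP_TTX_NMDA, SP_TTX, "sp_active"),
    ContrastSpec("lp_ttx_vs_bic_2h", LP_TTX, BIC_2H, "lp_passive"),
    ContrastSpec("lp_ttx_nmda_vs_bic_2h", LP_TTX_NMDA, BIC_2H, "lp_total"),
    ContrastSpec("lp_ttx_nmda_vs_lp_ttx", LP_TTX_NMDA, LP_TTX, "lp_active"),
    ContrastSpec("lp_tboa_vs_bic_2h", LP_TBOA, BIC_2H, "lp_spillover"),
    ContrastSpec("lp_tboa_vs_lp_ttx", LP_TBOA, LP_TTX, "lp_active_tboa"),
]

#: Contrasts a gene's shut-off decomposition relies on, keyed by protocol.
PROTOCOL_CONTRASTS = {
    "sp": ["sp_ttx_vs_bic_1h", "sp_ttx_nmda_vs_bic_1h", "sp_ttx_nmda_vs_sp_ttx"],
    "lp": [
        "lp_ttx_vs_bic_2h",
        "lp_ttx_nmda_vs_bic_2h",
        "lp_ttx_nmda_vs_lp_ttx",
        "lp_tboa_vs_bic_2h",
        "lp_tboa_vs_lp_ttx",
    ],
}

#: Shut-off component -> contrast name, keyed by protocol.
COMPONENT_CONTRASTS = {
    "sp": {"passive": "sp_ttx_vs_bic_1h", "total": "sp_ttx_nmda_vs_bic_1h",
           "active": "sp_ttx_nmda_vs_sp_ttx"},
    "lp": {"passive": "lp_ttx_vs_bic_2h", "total": "lp_ttx_nmda_vs_bic_2h",
           "active": "lp_ttx_nmda_vs_lp_ttx", "tboa": "lp_tboa_vs_bic_2h"},
}

#: Effect-vector columns for the concordance analysis (long protocol).
EFFECT_VECTOR_CONTRASTS = {
    "passive": "lp_ttx_vs_bic_2h",
    "spillover": "lp_tboa_vs_bic_2h",
    "total": "lp_ttx_nmda_vs_bic_2h",
    "active": "lp_ttx_nmda_vs_lp_ttx",
    "active_tboa": "lp_tboa_vs_lp_ttx",
}


def contrast_by_name(name: str) -> ContrastSpec:
    for spec in DEFAULT_CONTRASTS:
        if spec.name == name:
            return spec
    raise KeyError(name)
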