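"""Truth-labeled synthetic counts for the nine-condition interference design.

The generator emulates the statistical structure of the experiment: per-gene
baseline abundances (log-normal), negative-binomial overdispersion (gamma),
per-sample library-size factors, archetype-specific Bic induction kinetics,
and multiplicative intervention effects (passive shut-off by TTX, active
shut-off by TTX+NMDA, milder TBOA spillover effects, and boosting). Every
gene carries a truth label so downstream classification can be scored.

Negative-binomial parameterization throughout: ``var = mu + alpha * mu**2``
with ``alpha`` the reciprocal of the "size" parameter. ``alpha = 0`` is the
Poisson limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import conditions as cond
from .conditions import CONDITIONS, PROTOCOL_ENDPOINT

ARCHETYPES = [
    "unresponsive",
    "early.induced",
    "late.induced",
    "transient.induced",
    "early.repressed",
    "late.repressed",
]

#: Archetypes whose intervention response is modelled with an effect triple.
EFFECT_ARCHETYPES = {"early.induced", "late.induced"}

_TRUTH_STREAM = 0
_COUNTS_STREAM = 1


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class EffectComponent:
    """One mixture component of intervention effects within an archetype.

    Multipliers act on the Bic-only endpoint mean of the allocated protocol:
    ``passive`` scales the TTX condition, ``active`` scales TTX+NMDA relative
    to TTX, ``tboa`` scales the TBOA condition. Values below 1 are shut-off,
    above 1 boosting, exactly 1 no effect.
    """

    name: str
    fraction: float
    passive: float = 1.0
    active: float = 1.0
    tboa: float = 1.0


#: Default effect mixture for activity-induced genes. Encodes the observed
#: response diversity: genes untouched by the interventions; passive-only
#: shut-off; active-dominant shut-off (TBOA-sensitive); genes hit by both;
#: passive shut-off targets boosted by the NMDA signal; and genes boosted by
#: AP-firing cessation but actively suppressed. The boosted components give
#: the passive/active effect vectors their anticorrelated structure.
DEFAULT_EFFECT_COMPONENTS = (
    EffectComponent("null", 0.30, 1.0, 1.0, 1.0),
    EffectComponent("passive_only", 0.15, 0.5, 1.0, 1.0),
    EffectComponent("active_only", 0.25, 1.0, 0.4, 0.6),
    EffectComponent("both", 0.10, 0.5, 0.4, 0.5),
    EffectComponent("passive_nmda_boosted", 0.10, 0.5, 1.7, 1.0),
    EffectComponent("ttx_boosted_active_down", 0.10, 1.5, 0.4, 0.7),
)

DEFAULT_ARCHETYPE_FRACTIONS = {
    "unresponsive": 0.70,
    "early.induced": 0.05,
    "late.induced": 0.15,
    "transient.induced": 0.04,
    "early.repressed": 0.03,
    "late.repressed": 0.03,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    ``baseline_meanlog``/``baseline_sdlog`` parameterize the log-normal draw
    of per-gene baseline expected counts; ``dispersion_shape`` and
    ``dispersion_mean`` the gamma draw of per-gene NB dispersions;
    ``induction_fold`` the peak Bic induction multiplier F of responsive
    archetypes.
    """

    n_genes: int = 10_000
    n_replicates: int = 5
    baseline_meanlog: float = 5.0
    baseline_sdlog: float = 1.0
    dispersion_shape: float = 2.0
    dispersion_mean: float = 0.05
    lib_size_range: tuple[float, float] = (0.7, 1.3)
    induction_fold: float = 8.0
    archetype_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_FRACTIONS)
    )
    effect_components: tuple[EffectComponent, ...] = DEFAULT_EFFECT_COMPONENTS
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0 or self.n_replicates < 0:
            raise ConfigurationError("n_genes and n_replicates must be non-negative")
        unknown = set(self.archetype_fractions) - set(ARCHETYPES)
        if unknown:
            raise ConfigurationError(f"unknown archetypes: {sorted(unknown)}")
        fracs = np.array(list(self.archetype_fractions.values()), dtype=float)
        if np.any(fracs < 0) or not np.isclose(fracs.sum(), 1.0, atol=1e-9):
            raise ConfigurationError("archetype fractions must be non-negative and sum to 1")
        comp_fracs = np.array([c.fraction for c in self.effect_components])
        if np.any(comp_fracs < 0) or not np.isclose(comp_fracs.sum(), 1.0, atol=1e-9):
            raise ConfigurationError("effect-component fractions must sum to 1")
        for c in self.effect_components:
            if min(c.passive, c.active, c.tboa) <= 0:
                raise ConfigurationError(f"effect multipliers must be > 0 ({c.name})")
        if self.induction_fold <= 0:
            raise ConfigurationError("induction fold must be > 0")
        if self.dispersion_mean < 0 or self.dispersion_shape <= 0:
            raise ConfigurationError("dispersion parameters invalid")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ConfigurationError("library-size factor range must be positive")


def default_config(**overrides) -> SimConfig:
    cfg = SimConfig(**overrides)
    cfg.validate()
    return cfg


def kinetics_multipliers(archetype: str, fold: float) -> tuple[float, float, float]:
    """Expected expression multipliers at (0.5 h, 1 h, 2 h) of Bic vs untreated.

    Shapes are chosen so the max-at-time classification rules fire
    unambiguously: early genes peak by 1 h and decay, late genes keep rising
    from 1 h to 2 h, transient genes are elevated only at 0.5 h.
    """
    f = float(fold)
    if archetype == "unresponsive":
        return (1.0, 1.0, 1.0)
    if archetype == "early.induced":
        return (f, f, f / 2)
    if archetype == "late.induced":
        return (1.0, f / 2, f)
    if archetype == "transient.induced":
        return (f, 1.0, 1.0)
    if archetype == "early.repressed":
        return (1 / f, 1 / f, 2 / f)
    if archetype == "late.repressed":
        return (1.0, 2 / f, 1 / f)
    raise ConfigurationError(f"unknown archetype {archetype!r}")


def _quota_counts(fractions: dict[str, float] | list[tuple[str, float]], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` items to categories.

    Keeps realized category sizes within one item of ``fraction * n``
    regardless of the random seed (labels are shuffled afterwards).
    """
    items = list(fractions.items()) if isinstance(fractions, dict) else list(fractions)
    raw = {k: f * n for k, f in items}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    remainders = sorted(items, key=lambda kv: (-(raw[kv[0]] - counts[kv[0]]), kv[0]))
    for k, _ in remainders[:short]:
        counts[k] += 1
    return counts


def _protocol_of(archetype: str) -> str:
    if archetype.startswith("early."):
        return "sp"
    if archetype.startswith("late."):
        return "lp"
    return "none"


def generate_truth(config: SimConfig) -> pd.DataFrame:
    """Draw per-gene truth: archetype, effect triple, and condition means.

    Deterministic given ``config.seed``. Condition means follow the archetype
    kinetics times the effect multipliers applied to the allocated protocol's
    Bic endpoint mean; interventions of the other protocol carry the same
    triple relative to that protocol's endpoint.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _TRUTH_STREAM])
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]

    arch_counts = _quota_counts(config.archetype_fractions, n)
    archetypes = np.concatenate(
        [np.repeat(a, arch_counts.get(a, 0)) for a in ARCHETYPES]
    ) if n else np.array([], dtype=object)
    rng.shuffle(archetypes)

    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=n)
    if config.dispersion_mean == 0:
        dispersion = np.zeros(n)
    else:
        scale = config.dispersion_mean / config.dispersion_shape
        dispersion = rng.gamma(config.dispersion_shape, scale, size=n)

    passive = np.ones(n)
    active = np.ones(n)
    tboa = np.ones(n)
    component = np.array(["none"] * n, dtype=object)
    for arch in sorted(EFFECT_ARCHETYPES):
        idx = np.flatnonzero(archetypes == arch)
        if idx.size == 0:
            continue
        comp_counts = _quota_counts(
            [(c.name, c.fraction) for c in config.effect_components], idx.size
        )
        labels = np.concatenate(
            [np.repeat(c.name, comp_counts[c.name]) for c in config.effect_components]
        )
        rng.shuffle(labels)
        comp_by_name = {c.name: c for c in config.effect_components}
        component[idx] = labels
        passive[idx] = [comp_by_name[l].passive for l in labels]
        active[idx] = [comp_by_name[l].active for l in labels]
        tboa[idx] = [comp_by_name[l].tboa for l in labels]

    truth = pd.DataFrame(
        {
            "archetype": archetypes,
            "component": component,
            "baseline": baseline,
            "dispersion": dispersion,
            "passive_effect": passive,
            "active_effect": active,
            "tboa_effect": tboa,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth["protocol"] = [_protocol_of(a) for a in archetypes]

    means = _condition_means(truth, config)
    for c in CONDITIONS:
        truth[f"mean.{c}"] = means[c]
    return truth


def _condition_means(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    lam = truth["baseline"].to_numpy()
    k = np.array(
        [kinetics_multipliers(a, config.induction_fold) for a in truth["archetype"]]
    )
    means = pd.DataFrame(index=truth.index)
    means[cond.UNTREATED] = lam
    means[cond.BIC_05H] = lam * k[:, 0]
    means[cond.BIC_1H] = lam * k[:, 1]
    means[cond.BIC_2H] = lam * k[:, 2]
    p = truth["passive_effect"].to_numpy()
    a = truth["active_effect"].to_numpy()
    t = truth["tboa_effect"].to_numpy()
    sp_base = means[PROTOCOL_ENDPOINT["sp"]].to_numpy()
    lp_base = means[PROTOCOL_ENDPOINT["lp"]].to_numpy()
    means[cond.SP_TTX] = sp_base * p
    means[cond.SP_TTX_NMDA] = sp_base * p * a
    means[cond.LP_TTX] = lp_base * p
    means[cond.LP_TTX_NMDA] = lp_base * p * a
    means[cond.LP_TBOA] = lp_base * t
    return means


def condition_means(truth: pd.DataFrame) -> pd.DataFrame:
    """Extract the gene x condition expected-count table from a truth table."""
    out = truth[[f"mean.{c}" for c in CONDITIONS]].copy()
    out.columns = CONDITIONS
    return out


def build_design(n_replicates: int = 5) -> pd.DataFrame:
    """Design sheet for the full nine-condition experiment."""
    rows = []
    spec = [
        ("none", "untreated", 0.0, cond.UNTREATED),
        ("bic", "bic", 0.5, cond.BIC_05H),
        ("bic", "bic", 1.0, cond.BIC_1H),
        ("bic", "bic", 2.0, cond.BIC_2H),
        ("sp", "ttx", 1.0, cond.SP_TTX),
        ("sp", "ttx_nmda", 1.0, cond.SP_TTX_NMDA),
        ("lp", "ttx", 2.0, cond.LP_TTX),
        ("lp", "ttx_nmda", 2.0, cond.LP_TTX_NMDA),
        ("lp", "tboa", 2.0, cond.LP_TBOA),
    ]
    for protocol, treatment, time_h, label in spec:
        for r in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{label}_r{r}",
                    "protocol": protocol,
                    "treatment": treatment,
                    "time_h": time_h,
                    "replicate": r,
                    "condition": label,
                }
            )
    return pd.DataFrame(rows, columns=["sample_id", "protocol", "treatment",
                                       "time_h", "replicate", "condition"])


def simulate_counts(
    truth: pd.DataFrame, design: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """Draw NB counts for every gene x sample of the design.

    ``counts ~ NB(mean = lib_factor_j * mean_{g, cond(j)}, dispersion
    alpha_g)``. Library-size factors are drawn uniformly from
    ``config.lib_size_range`` per sample and stored in
    ``counts.attrs['lib_factors']``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _COUNTS_STREAM])
    missing = set(design["condition"]) - set(CONDITIONS)
    if missing:
        raise ConfigurationError(f"design conditions absent from truth: {sorted(missing)}")
    mean_cols = {c: truth[f"mean.{c}"].to_numpy() for c in CONDITIONS}
    n_samples = len(design)
    lib = rng.uniform(*config.lib_size_range, size=n_samples)
    alpha = truth["dispersion"].to_numpy()
    out = np.zeros((len(truth), n_samples), dtype=np.int64)
    for j, (_, row) in enumerate(design.iterrows()):
        mu = mean_cols[row["condition"]] * lib[j]
        out[:, j] = _nb_draw(rng, mu, alpha)
    counts = pd.DataFrame(out, index=truth.index, columns=list(design["sample_id"]))
    counts.attrs["lib_factors"] = pd.Series(lib, index=list(design["sample_id"]))
    return counts


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    out = np.zeros(mu.shape, dtype=np.int64)
    pois = (alpha <= 0) | (mu <= 0)
    out[pois] = rng.poisson(np.clip(mu[pois], 0, None))
    nb = ~pois
    if np.any(nb):
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_experiment(config: SimConfig | None = None):
    """Convenience: (truth, design, counts) for a config (default if None)."""
    cfg = config or default_config()
    truth = generate_truth(cfg)
    design = build_design(cfg.n_replicates)
    counts = simulate_counts(truth, design, cfg)
    return truth, design, counts


_EFFECT_TOL = 1e-9


def _truth_call(multiplier: np.ndarray) -> np.ndarray:
    call = np.where(multiplier < 1 - _EFFECT_TOL, "down",
                    np.where(multiplier > 1 + _EFFECT_TOL, "up", "ns"))
    return call


def truth_eval(annotation: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Score recovered gene annotations against simulation truth.

    ``annotation`` is the merged per-gene output (activity_class, protocol,
    passive_call / active_call / tboa_call, evaluable). Returns confusion
    summaries: per-archetype activity-class sensitivity, transient exclusion
    specificity, and per-component shut-off sensitivity / specificity /
    observed false discovery rate.
    """
    if set(annotation.index) != set(truth.index):
        raise ValueError("annotation and truth gene universes differ")
    ann = annotation.reindex(truth.index)

    out: dict = {"activity": {}, "shutoff": {}}
    cls = ann["activity_class"].fillna("unresponsive")
    for arch in ARCHETYPES:
        mask = truth["archetype"] == arch
        if mask.sum() == 0:
            continue
        target = "transient" if arch == "transient.induced" else arch
        out["activity"][arch] = {
            "n": int(mask.sum()),
            "sensitivity": float((cls[mask] == target).mean()),
        }
    transient = truth["archetype"] == "transient.induced"
    if transient.any():
        allocated = cls[transient].isin(
            ["early.induced", "late.induced", "early.repressed", "late.repressed"]
        )
        out["activity"]["transient_exclusion_specificity"] = float(1 - allocated.mean())

    induced = truth["archetype"].isin(EFFECT_ARCHETYPES)
    for comp, col in [("passive", "passive_effect"), ("active", "active_effect"),
                      ("tboa", "tboa_effect")]:
        truth_call = pd.Series(_truth_call(truth[col].to_numpy()), index=truth.index)
        universe = induced if comp != "tboa" else induced & (truth["protocol"] == "lp")
        call = ann[f"{comp}_call"] if f"{comp}_call" in ann else pd.Series("ns", index=ann.index)
        call = call.where(call.isin(["down", "up"]), "ns")
        t_down = universe & (truth_call == "down")
        t_null = universe & (truth_call == "ns")
        c_down = call == "down"
        n_down = int(t_down.sum())
        n_null = int(t_null.sum())
        called = int((universe & c_down).sum())
        null_down = int((t_null & c_down).sum())
        false_calls = int((universe & c_down & (truth_call != "down")).sum())
        out["shutoff"][comp] = {
            "n_true_down": n_down,
            "sensitivity": float((t_down & c_down).sum() / n_down) if n_down else float("nan"),
            "specificity": float(1 - null_down / n_null) if n_null else float("nan"),
            "fdr": float(false_calls / called) if called else 0.0,
        }
    return out


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=int(seed))
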