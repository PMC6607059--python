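"""Synthetic multi-treatment phenotyping trials.

Generates balanced trial datasets with the covariance structure the
downstream mixed-model analysis assumes: a Gaussian two-way layout

    y_ijk = mu + t_j + r_k + g_i + (gt)_ij + eps_ijk

with genotype effects g ~ N(0, sigma2_G), genotype-by-treatment effects
gt ~ N(0, sigma2_GT) and residuals eps ~ N(0, sigma2_E(j)) whose variance
may differ between treatments.  Treatment effects t_j and replicate
effects r_k are fixed offsets.  A multi-trait panel layered on top of this
model supplies correlated predictor traits and biomass responses (fresh
weight ``BFw`` and dry weight ``BDw``) for the correlation-network,
penalized-regression and stress-classification stages.

Default settings emulate a glasshouse maize trial: 20 genotypes, four
treatments (control ``C``, nitrogen deficiency ``N``, water stress ``W``
and combined stress ``N+W``), eight replicate plants per cell (640 plants
per trait), a 20 g mean dry weight, and treatment effects that reproduce
average biomass reductions of roughly 3, 19 and 22 % relative to control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "PanelConfig",
    "simulate_trial",
    "simulate_trait_panel",
    "read_trait_table",
    "write_trait_table",
    "validate_trait_table",
    "DEFAULT_TREATMENTS",
    "DEFAULT_ARCHETYPES",
]

DEFAULT_TREATMENTS: tuple[str, ...] = ("C", "N", "W", "N+W")

#: (Yp, Ys) dry-weight profiles, in grams, for the four response archetypes:
#: A productive and resilient, B productive but stress-susceptible,
#: C unproductive but resilient, D poor on both axes.
DEFAULT_ARCHETYPES: Mapping[str, tuple[float, float]] = {
    "A": (20.0, 18.0),
    "B": (24.0, 12.0),
    "C": (10.0, 9.5),
    "D": (12.0, 4.0),
}

TRAIT_TABLE_COLUMNS = ("genotype", "treatment", "replicate", "trait", "value")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a single-trait balanced trial simulation.

    Parameters
    ----------
    n_genotypes, treatments, n_reps
        Trial dimensions; defaults give the 20 x 4 x 8 = 640-plant design.
    mu
        Global mean, in trait units (default 20 g, a dry-weight scale).
    treatment_effects
        One fixed offset per treatment.  The defaults reproduce average
        reductions of 3.2 %, 19.3 % and 21.8 % under N, W and N+W relative
        to control, so expected means are ordered C > N > W > N+W.
    sigma2_G, sigma2_GT
        Genotype and genotype-by-treatment variance components.
    sigma2_E
        Residual variance; a scalar is shared by all treatments, a
        sequence gives one residual variance per treatment.
    replicate_effects
        Optional fixed replicate offsets (default all zero), used to
        exercise the fixed replication term of the downstream model.
    log_scale
        If True the linear predictor is simulated on the log scale and
        exponentiated, producing strictly positive trait values.
    seed
        Master RNG seed; per-stage streams are spawned from it.
    """

    n_genotypes: int = 20
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    n_reps: int = 8
    mu: float = 20.0
    treatment_effects: tuple[float, ...] = (0.0, -0.64, -3.86, -4.36)
    sigma2_G: float = 2.0
    sigma2_GT: float = 0.5
    sigma2_E: float | tuple[float, ...] = 1.0
    replicate_effects: tuple[float, ...] | None = None
    trait_name: str = "BDw"
    log_scale: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genotypes < 1:
            raise ConfigurationError("n_genotypes must be >= 1")
        if len(self.treatments) < 2:
            raise ConfigurationError("at least 2 treatments required")
        if len(set(self.treatments)) != len(self.treatments):
            raise ConfigurationError("treatment labels must be unique")
        if self.n_reps < 2:
            raise ConfigurationError("n_reps must be >= 2")
        if len(self.treatment_effects) != len(self.treatments):
            raise ConfigurationError(
                "treatment_effects must have one entry per treatment"
            )
        for name in ("sigma2_G", "sigma2_GT"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        s2e = self.residual_variances()
        if np.any(s2e < 0):
            raise ConfigurationError("sigma2_E must be >= 0")
        if self.replicate_effects is not None and len(self.replicate_effects) != self.n_reps:
            raise ConfigurationError("replicate_effects must have n_reps entries")

    def residual_variances(self) -> np.ndarray:
        """Residual variance per treatment (scalar input broadcast)."""
        s2e = np.atleast_1d(np.asarray(self.sigma2_E, dtype=float))
        if s2e.size == 1:
            s2e = np.repeat(s2e, len(self.treatments))
        if s2e.size != len(self.treatments):
            raise ConfigurationError(
                "sigma2_E must be scalar or one value per treatment"
            )
        return s2e

    def genotype_labels(self) -> list[str]:
        width = max(2, len(str(self.n_genotypes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genotypes)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PanelConfig:
    """Parameters of a correlated multi-trait panel with biomass responses.

    Predictor traits are partitioned into correlated blocks: two traits in
    the same block share a common latent component so their pairwise
    correlation is ``rho_b`` at replicate level (and at genotype level),
    while traits in different blocks are uncorrelated.  The responses BFw
    and BDw are sparse linear combinations X @ beta of the predictor
    traits plus Gaussian noise; alternatively, ``planted_groups`` assigns
    genotypes to the A-D response archetypes and replaces the regression
    response with archetype-specific dry weights under control versus
    stress (the fixture for classification-recovery checks).
    """

    n_traits: int = 12
    block_structure: tuple[tuple[int, ...], ...] = (
        (0, 1, 2, 3),
        (4, 5, 6, 7),
        (8, 9, 10, 11),
    )
    rho_b: float = 0.8
    beta: tuple[float, ...] = (0.6, 0, 0, 0, 0.5, 0, 0, 0, 0.8, 0, 0, 0)
    noise_sd: float = 1.0
    fresh_to_dry_ratio: float = 4.2
    planted_groups: Mapping[str, str] | None = None
    archetypes: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    trait_categories: tuple[str, ...] = ("architectural", "physiological", "biomass-related")

    def __post_init__(self) -> None:
        if self.n_traits < 1:
            raise ConfigurationError("n_traits must be >= 1")
        covered = sorted(i for block in self.block_structure for i in block)
        if covered != list(range(self.n_traits)):
            raise ConfigurationError(
                "block_structure must partition trait indices 0..n_traits-1"
            )
        if not -1 < self.rho_b < 1:
            raise ConfigurationError("|rho_b| must be < 1")
        if len(self.beta) != self.n_traits:
            raise ConfigurationError("beta length must equal n_traits")
        b = np.asarray(self.beta, float)
        if not (np.any(b == 0) and np.any(b != 0)):
            raise ConfigurationError("beta must contain a zero and a non-zero entry")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    def trait_names(self) -> list[str]:
        """Predictor trait names, prefixed by block category."""
        names = []
        cats = self.trait_categories
        for b, block in enumerate(self.block_structure):
            cat = cats[b % len(cats)]
            prefix = {"architectural": "arch", "physiological": "phys",
                      "biomass-related": "bio"}.get(cat, cat[:4])
            for j, _ in enumerate(block):
                names.append(f"{prefix}_{b + 1}{chr(ord('a') + j)}")
        # names indexed by position within blocks; reorder to trait index
        ordered = [""] * self.n_traits
        k = 0
        for b, block in enumerate(self.block_structure):
            for j, idx in enumerate(block):
                ordered[idx] = names[k]
                k += 1
        return ordered

    def trait_category_map(self) -> dict[str, str]:
        cats = {}
        names = self.trait_names()
        for b, block in enumerate(self.block_structure):
            cat = self.trait_categories[b % len(self.trait_categories)]
            for idx in block:
                cats[names[idx]] = cat
        cats["BFw"] = "manual"
        cats["BDw"] = "manual"
        return cats

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["planted_groups"] is not None:
            d["planted_groups"] = dict(d["planted_groups"])
        d["archetypes"] = {k: list(v) for k, v in d["archetypes"].items()}
        return d


# ---------------------------------------------------------------------------
# single-trait trial


def _effect_draws(config: SimConfig, rng: np.random.Generator):
    """Draw the random-effect layers (genotype, GxT, residual) once."""
    G, T, R = config.n_genotypes, len(config.treatments), config.n_reps
    g = rng.normal(0.0, np.sqrt(config.sigma2_G), size=G)
    gt = rng.normal(0.0, np.sqrt(config.sigma2_GT), size=(G, T))
    s2e = config.residual_variances()
    eps = rng.normal(0.0, 1.0, size=(G, T, R)) * np.sqrt(s2e)[None, :, None]
    return g, gt, eps


def _assemble(config: SimConfig, g, gt, eps, trait_name: str) -> pd.DataFrame:
    G, T, R = config.n_genotypes, len(config.treatments), config.n_reps
    te = np.asarray(config.treatment_effects, float)
    re = (
        np.zeros(R)
        if config.replicate_effects is None
        else np.asarray(config.replicate_effects, float)
    )
    values = (
        config.mu
        + te[None, :, None]
        + re[None, None, :]
        + g[:, None, None]
        + gt[:, :, None]
        + eps
    )
    if config.log_scale:
        values = np.exp(values)
    genos = config.genotype_labels()
    idx = pd.MultiIndex.from_product(
        [genos, list(config.treatments), np.arange(1, R + 1)],
        names=["genotype", "treatment", "replicate"],
    )
    out = pd.DataFrame(
        {"trait": trait_name, "value": values.reshape(-1)}, index=idx
    ).reset_index()
    return out[list(TRAIT_TABLE_COLUMNS)]


def simulate_trial(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one balanced single-trait trial.

    Returns a long-format trait table with columns
    ``genotype, treatment, replicate, trait, value`` containing
    ``n_genotypes * n_treatments * n_reps`` rows.  Identical configs (and
    seed) produce bitwise-identical tables.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g, gt, eps = _effect_draws(config, rng)
    return _assemble(config, g, gt, eps, config.trait_name)


# ---------------------------------------------------------------------------
# multi-trait panel


def simulate_trait_panel(
    sim: SimConfig, panel: PanelConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate a multi-trait panel plus BFw/BDw biomass responses.

    Each predictor trait follows the single-trait trial model; traits in
    the same block share a latent component with weight sqrt(rho_b), so
    within-block correlations equal ``rho_b`` and cross-block
    correlations are zero in expectation.  Responses are built at
    replicate level as ``X @ beta + noise`` (BFw additionally scaled by
    the fresh-to-dry ratio), or from planted A-D archetype dry-weight
    profiles when ``panel.planted_groups`` is given.
    """
    if rng is None:
        rng = np.random.default_rng(sim.seed)
    G, T, R = sim.n_genotypes, len(sim.treatments), sim.n_reps
    n_cells = G * T * R
    genos = sim.genotype_labels()

    sqr = np.sqrt(panel.rho_b)
    sqi = np.sqrt(1.0 - panel.rho_b)

    trait_values = np.empty((panel.n_traits, G, T, R))
    names = panel.trait_names()
    te = np.asarray(sim.treatment_effects, float)
    base = sim.mu + te[None, :, None]  # broadcast over (G, T, R)

    for block in panel.block_structure:
        shared = _zero_mean_field(sim, rng)
        for idx in block:
            idio = _zero_mean_field(sim, rng)
            trait_values[idx] = base + sqr * shared + sqi * idio

    frames = [
        _panel_frame(sim, genos, names[i], trait_values[i]) for i in range(panel.n_traits)
    ]

    beta = np.asarray(panel.beta, float)
    if panel.planted_groups is None:
        X = trait_values.reshape(panel.n_traits, n_cells).T
        signal = X @ beta
        bdw = signal + rng.normal(0.0, panel.noise_sd, size=n_cells)
        bfw = panel.fresh_to_dry_ratio * signal + rng.normal(
            0.0, panel.noise_sd, size=n_cells
        )
        bdw = bdw.reshape(G, T, R)
        bfw = bfw.reshape(G, T, R)
    else:
        groups = dict(panel.planted_groups)
        missing = [g for g in genos if g not in groups]
        if missing:
            raise ConfigurationError(
                f"planted_groups must cover all genotypes; missing {missing[:3]}"
            )
        control = sim.treatments[0]
        bdw = np.empty((G, T, R))
        for gi, gname in enumerate(genos):
            yp, ys = panel.archetypes[groups[gname]]
            for tj, tname in enumerate(sim.treatments):
                bdw[gi, tj, :] = yp if tname == control else ys
        bdw = bdw + rng.normal(0.0, panel.noise_sd, size=(G, T, R))
        bfw = panel.fresh_to_dry_ratio * bdw + rng.normal(
            0.0, panel.noise_sd, size=(G, T, R)
        )

    frames.append(_panel_frame(sim, genos, "BDw", bdw))
    frames.append(_panel_frame(sim, genos, "BFw", bfw))
    return pd.concat(frames, ignore_index=True)


def _zero_mean_field(sim: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """One zero-mean draw of the genotype + GxT + residual layers."""
    g, gt, eps = _effect_draws(sim, rng)
    return g[:, None, None] + gt[:, :, None] + eps


def _panel_frame(sim: SimConfig, genos, trait: str, values: np.ndarray) -> pd.DataFrame:
    idx = pd.MultiIndex.from_product(
        [genos, list(sim.treatments), np.arange(1, sim.n_reps + 1)],
        names=["genotype", "treatment", "replicate"],
    )
    out = pd.DataFrame({"trait": trait, "value": values.reshape(-1)}, index=idx)
    return out.reset_index()[list(TRAIT_TABLE_COLUMNS)]


# ---------------------------------------------------------------------------
# trait-table I/O and validation


def validate_trait_table(table: pd.DataFrame) -> None:
    """Check the long-format trait-table contract.

    Required columns, finite values, and no duplicated
    (genotype, treatment, replicate, trait) keys.
    """
    missing = set(TRAIT_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(table["value"].to_numpy(float))):
        raise ValueError("trait table contains non-finite values")
    keys = ["genotype", "treatment", "replicate", "trait"]
    if table.duplicated(subset=keys).any():
        raise ValueError("duplicate (genotype, treatment, replicate, trait) keys")


def write_trait_table(table: pd.DataFrame, path) -> None:
    table[list(TRAIT_TABLE_COLUMNS)].to_csv(path, index=False)


def read_trait_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"genotype": str, "treatment": str})
    validate_trait_table(table)
    return table
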