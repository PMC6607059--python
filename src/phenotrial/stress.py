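"""Stress-tolerance indices, 10-grade scoring, RCI/PCI classification.

From each genotype's dry-weight performance under non-stress (Yp) and
stress (Ys) conditions, five classical drought-adaptation indices are
computed:

    SSI = (1 - Ys/Yp) / SI   with SI = 1 - mean(Ys)/mean(Yp)
    TOL = Yp - Ys
    MP  = (Yp + Ys) / 2
    GMP = sqrt(Yp * Ys)
    STI = Yp * Ys / mean(Yp)^2

Each index is mapped to an integer 1-10 score (lower-is-better indices
SSI and TOL are reversed first), and the scores are averaged into the
resilience capacity index RCI = mean(score_SSI, score_TOL) and the
production capacity index PCI = mean(score_MP, score_GMP, score_STI).
Genotypes are then classified into quadrant groups relative to the
population means of RCI and PCI: A (high/high), B (productive but not
resilient), C (resilient but not productive), D (low/low).  Extreme
groups A and D are compared trait-by-trait with Welch t-tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_stress_indices",
    "score_indices",
    "compute_rci_pci",
    "classify_groups",
    "stress_score_table",
    "compare_extreme_groups",
    "welch_from_summary",
    "DerivedIndexConfig",
    "compute_derived_indices",
    "INDEX_ORIENTATION",
]

#: which direction of each index indicates a better (more tolerant /
#: more productive) genotype
INDEX_ORIENTATION: Mapping[str, str] = {
    "SSI": "lower_better",
    "TOL": "lower_better",
    "MP": "higher_better",
    "GMP": "higher_better",
    "STI": "higher_better",
}

RCI_INDICES = ("SSI", "TOL")
PCI_INDICES = ("MP", "GMP", "STI")


def compute_stress_indices(
    yp: Sequence[float] | pd.Series, ys: Sequence[float] | pd.Series
) -> pd.DataFrame:
    """Five stress indices from non-stress (Yp) and stress (Ys) yields.

    Returns a per-genotype table with Yp, Ys, SSI, TOL, MP, GMP, STI; the
    population means and the stress intensity SI = 1 - mean(Ys)/mean(Yp)
    are attached as ``DataFrame.attrs``.  Requires strictly positive
    yields and a positive SI (stress must depress the population mean).
    """
    if isinstance(yp, pd.Series) and isinstance(ys, pd.Series):
        index = yp.index
        if not index.equals(ys.index):
            ys = ys.reindex(index)
    else:
        index = None
    yp_a = np.asarray(yp, dtype=float)
    ys_a = np.asarray(ys, dtype=float)
    if yp_a.shape != ys_a.shape or yp_a.ndim != 1:
        raise ValueError("Yp and Ys must be equal-length vectors")
    if np.any(~np.isfinite(yp_a)) or np.any(~np.isfinite(ys_a)):
        raise ValueError("yields must be finite")
    if np.any(yp_a <= 0) or np.any(ys_a <= 0):
        raise ValueError("yields must be strictly positive")
    yp_bar = float(yp_a.mean())
    ys_bar = float(ys_a.mean())
    si = 1.0 - ys_bar / yp_bar
    if si <= 0:
        raise ValueError(
            "no population-level stress detected (mean Ys >= mean Yp, SI <= 0)"
        )
    out = pd.DataFrame(
        {
            "Yp": yp_a,
            "Ys": ys_a,
            "SSI": (1.0 - ys_a / yp_a) / si,
            "TOL": yp_a - ys_a,
            "MP": (yp_a + ys_a) / 2.0,
            "GMP": np.sqrt(yp_a * ys_a),
            "STI": yp_a * ys_a / yp_bar**2,
        },
        index=index,
    )
    out.attrs["Yp_mean"] = yp_bar
    out.attrs["Ys_mean"] = ys_bar
    out.attrs["SI"] = si
    return out


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def score_indices(
    values: Sequence[float] | pd.Series,
    orientation: str = "higher_better",
    variant: str = "minmax",
) -> np.ndarray | pd.Series:
    """Map index values to integer scores on a 1-10 grading scale.

    ``minmax`` (default): score = round(1 + 9 (x - min)/(max - min)),
    half-up rounding, after reversing the values for ``lower_better``
    indices; constant input maps to the neutral score 5.  ``decile``:
    scores are the deciles of the rank distribution,
    ceil(10 * rank / n), an alternative grading that is insensitive to
    outliers.  Both variants are invariant under strictly increasing
    affine transforms of the input.
    """
    if orientation not in ("higher_better", "lower_better"):
        raise ValueError("orientation must be higher_better|lower_better")
    if variant not in ("minmax", "decile"):
        raise ValueError("variant must be minmax|decile")
    index = values.index if isinstance(values, pd.Series) else None
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if orientation == "lower_better":
        x = -x
    span = x.max() - x.min()
    if span == 0:
        scores = np.full(x.size, 5, dtype=int)
    elif variant == "minmax":
        scores = _round_half_up(1.0 + 9.0 * (x - x.min()) / span)
    else:
        ranks = stats.rankdata(x, method="average")
        scores = np.ceil(10.0 * ranks / x.size).astype(int)
    scores = np.clip(scores, 1, 10)
    if index is not None:
        return pd.Series(scores, index=index)
    return scores


def compute_rci_pci(scores: pd.DataFrame) -> pd.DataFrame:
    """Average index scores into RCI and PCI.

    ``scores`` must hold the five score columns SSI, TOL, MP, GMP, STI.
    RCI is the mean of the SSI and TOL scores, PCI the mean of the MP,
    GMP and STI scores; both therefore lie in [1, 10].
    """
    missing = set(INDEX_ORIENTATION) - set(scores.columns)
    if missing:
        raise ValueError(f"missing score columns: {sorted(missing)}")
    out = scores.copy()
    out["RCI"] = scores[list(RCI_INDICES)].mean(axis=1)
    out["PCI"] = scores[list(PCI_INDICES)].mean(axis=1)
    return out


def classify_groups(score_table: pd.DataFrame) -> pd.Series:
    """Assign quadrant groups A-D from RCI and PCI.

    Quadrant boundaries are the population means of RCI and PCI; values
    exactly at a boundary count as "high".  A: high RCI and high PCI;
    B: high PCI only (productive, not resilient); C: high RCI only
    (resilient, not productive); D: low on both.
    """
    rci = score_table["RCI"]
    pci = score_table["PCI"]
    hi_r = rci >= rci.mean()
    hi_p = pci >= pci.mean()
    group = np.where(
        hi_r & hi_p, "A", np.where(hi_p, "B", np.where(hi_r, "C", "D"))
    )
    return pd.Series(group, index=score_table.index, name="group")


def stress_score_table(
    yp: pd.Series, ys: pd.Series, variant: str = "minmax"
) -> pd.DataFrame:
    """Full per-genotype table: indices, scores, RCI, PCI and group."""
    indices = compute_stress_indices(yp, ys)
    scores = pd.DataFrame(index=indices.index)
    for name, orientation in INDEX_ORIENTATION.items():
        scores[name] = score_indices(indices[name], orientation, variant)
    scored = compute_rci_pci(scores)
    scored["group"] = classify_groups(scored)
    out = indices.join(scored, rsuffix="_score")
    out.attrs.update(indices.attrs)
    return out


def compare_extreme_groups(
    trait_values: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    alpha_strict: float = 0.01,
) -> pd.DataFrame:
    """Welch t-tests of group A versus group D, trait by trait.

    ``trait_values`` is a genotype x trait matrix (typically BLUPs of one
    treatment); ``groups`` maps genotypes to A-D.  Output rows carry the
    group means with standard errors, the Welch statistic with
    Satterthwaite df, and star flags at the two significance levels.
    Traits are skipped with a warning when either extreme group has
    fewer than two members.
    """
    a_ids = groups.index[groups == "A"]
    d_ids = groups.index[groups == "D"]
    if len(a_ids) < 2 or len(d_ids) < 2:
        warnings.warn(
            "group A or D has fewer than 2 members; comparison skipped",
            UserWarning,
        )
        return pd.DataFrame(
            columns=[
                "trait", "mean_A", "se_A", "n_A", "mean_D", "se_D", "n_D",
                "t", "df", "p", "significant", "stars",
            ]
        )
    rows = []
    for trait in trait_values.columns:
        a = trait_values.loc[trait_values.index.isin(a_ids), trait].to_numpy(float)
        d = trait_values.loc[trait_values.index.isin(d_ids), trait].to_numpy(float)
        res = stats.ttest_ind(a, d, equal_var=False)
        se_a = a.std(ddof=1) / math.sqrt(a.size)
        se_d = d.std(ddof=1) / math.sqrt(d.size)
        p = float(res.pvalue)
        if np.isnan(p):  # both groups constant and equal
            p, t_stat, df = 1.0, 0.0, float(a.size + d.size - 2)
        else:
            t_stat, df = float(res.statistic), float(res.df)
        rows.append(
            {
                "trait": trait,
                "mean_A": a.mean(), "se_A": se_a, "n_A": a.size,
                "mean_D": d.mean(), "se_D": se_d, "n_D": d.size,
                "t": t_stat, "df": df, "p": p,
                "significant": p < alpha,
                "stars": "**" if p < alpha_strict else ("*" if p < alpha else ""),
            }
        )
    return pd.DataFrame(rows)


def welch_from_summary(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> tuple[float, float, float]:
    """Welch t-test from group summaries (mean, standard error, n).

    Returns (t, Satterthwaite df, two-sided p).  Useful for checking
    published group-comparison tables that report mean +/- se only.
    """
    v1, v2 = se1**2, se2**2
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p


# ---------------------------------------------------------------------------
# derived manual indices


@dataclass(frozen=True)
class DerivedIndexConfig:
    """Configurable formulas for the derived dry-weight-based indices.

    Each entry maps an output column to (required input columns,
    function of those columns).  Defaults: specific plant weight
    SPW = BDw / PHg (g per cm of plant height), water use efficiency
    WUE = BDw / water (g per litre of water applied), and physiological
    nitrogen use efficiency PNUE = BDw / (BDw * NC / 100) (g biomass per
    g plant nitrogen, with NC the nitrogen concentration in %).
    """

    formulas: Mapping[str, tuple[tuple[str, ...], Callable[..., np.ndarray]]] = field(
        default_factory=lambda: {
            "SPW": (("BDw", "PHg"), lambda bdw, phg: bdw / phg),
            "WUE": (("BDw", "water"), lambda bdw, water: bdw / water),
            "PNUE": (("BDw", "NC"), lambda bdw, nc: bdw / (bdw * nc / 100.0)),
        }
    )


def compute_derived_indices(
    table: pd.DataFrame, config: DerivedIndexConfig | None = None
) -> pd.DataFrame:
    """Append derived index columns to a wide trait table.

    ``table`` has one row per observation (or genotype) and one column
    per trait.  Input columns are never modified; each configured
    formula adds one output column.  Missing inputs or non-finite
    results (division by zero) raise, naming the formula.
    """
    config = config or DerivedIndexConfig()
    out = table.copy()
    applied = {}
    for name, (inputs, func) in config.formulas.items():
        missing = [c for c in inputs if c not in table.columns]
        if missing:
            raise ValueError(f"formula {name!r} requires missing columns {missing}")
        args = [table[c].to_numpy(dtype=float) for c in inputs]
        with np.errstate(divide="ignore", invalid="ignore"):
            value = func(*args)
        if not np.all(np.isfinite(value)):
            raise ValueError(f"formula {name!r} produced non-finite values")
        out[name] = value
        applied[name] = list(inputs)
    out.attrs["derived_formulas"] = applied
    return out
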