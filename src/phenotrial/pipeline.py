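"""End-to-end orchestration: simulate/load -> fit -> BLUPs -> downstream.

``run_pipeline`` executes the full analysis sequence on one trial
dataset: per-trait mixed-model fits with AIC selection of the residual
model, heritability and variance contributions, genotype BLUPs per
treatment, descriptive summaries and correlation networks, penalized
trait selection against the biomass responses, stress-index scoring and
A-D classification per stress treatment, and the AMMI stability
decomposition of the dry-weight genotype x treatment table.  All outputs
are plain CSV/JSON files in the configured output directory, and a
manifest records the config hash, seed and per-stage files; identical
config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import (
    SimConfig,
    PanelConfig,
    simulate_trait_panel,
    read_trait_table,
    write_trait_table,
)
from .mixedmodel import (
    ModelSpec,
    fit_reml,
    select_residual_model,
    heritability_and_contributions,
    genotype_blups,
    blup_matrix,
    flag_outliers,
)
from .summaries import summarize_traits, correlation_matrix, build_network
from .penalized import standardize, cross_validate_lambda, coefficient_table
from .stress import stress_score_table, compare_extreme_groups
from .ammi import double_center, decompose, stability_summary

logger = logging.getLogger("phenotrial")

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the name of the stage that failed."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    ``mode`` is "synthetic" (simulate a trait panel from ``sim`` and
    ``panel``) or "csv" (read a long trait table from ``csv_path``).
    ``responses`` are the biomass traits modelled by penalized
    regression; the stress classification uses the first response that
    looks like a dry weight (default ``BDw``).
    """

    mode: str = "synthetic"
    csv_path: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    control: str = "C"
    responses: tuple[str, ...] = ("BFw", "BDw")
    classification_response: str = "BDw"
    alpha: float = 0.05
    scoring_variant: str = "minmax"
    outdir: str = "phenotrial_out"
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "csv"):
            raise ValueError("mode must be synthetic|csv")
        if self.mode == "csv" and not self.csv_path:
            raise ValueError("csv mode requires csv_path")
        if self.control not in self.sim.treatments:
            raise ValueError(
                f"control {self.control!r} not among treatments {self.sim.treatments}"
            )
        if self.classification_response not in self.responses:
            raise ValueError("classification_response must be one of responses")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.scoring_variant not in ("minmax", "decile"):
            raise ValueError("scoring_variant must be minmax|decile")

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["panel"] = self.panel.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        panel = d.pop("panel", {})
        if isinstance(sim, dict):
            sim = {
                k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()
            }
            sim = SimConfig(**sim)
        if isinstance(panel, dict):
            panel = {
                k: (
                    tuple(tuple(b) for b in v)
                    if k == "block_structure"
                    else tuple(v) if isinstance(v, list) and k != "archetypes" else v
                )
                for k, v in panel.items()
            }
            if "archetypes" in panel:
                panel["archetypes"] = {
                    k: tuple(v) for k, v in panel["archetypes"].items()
                }
            panel = PanelConfig(**panel)
        for key in ("responses",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(sim=sim, panel=panel, **d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        return cls.from_dict(data)


def _slug(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9+_.-]", "_", label)


def _config_hash(config: PipelineConfig) -> str:
    d = config.to_dict()
    d.pop("outdir", None)  # hash the analysis configuration, not the location
    canon = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Raises :class:`PipelineError` naming the failing stage; partial
    outputs are kept and flagged by a ``manifest.partial`` marker file.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    partial_marker = outdir / "manifest.partial"
    partial_marker.write_text("run in progress\n")

    master = np.random.SeedSequence(config.seed)
    sim_seed, cv_seed_seq = master.spawn(2)
    cv_seed = int(cv_seed_seq.generate_state(1)[0] % (2**31 - 1))

    stage = "load_data"
    try:
        if config.mode == "synthetic":
            rng = np.random.default_rng(sim_seed)
            data = simulate_trait_panel(config.sim, config.panel, rng=rng)
        else:
            data = read_trait_table(config.csv_path)
        traits = list(pd.unique(data["trait"]))
        treatments = list(pd.unique(data["treatment"]))
        missing = set(config.responses) - set(traits)
        if missing:
            raise ValueError(f"responses missing from data: {sorted(missing)}")
        if config.control not in treatments:
            raise ValueError(f"control {config.control!r} not present in data")
        path = outdir / "trait_table.csv"
        write_trait_table(data, path)
        manifest["stages"][stage] = {"files": ["trait_table.csv"], "n_rows": len(data)}

        stage = "variance_components"
        fits = {}
        fit_records = []
        blup_frames = []
        outlier_frames = []
        for trait in traits:
            hom = fit_reml(data, ModelSpec(trait, "homogeneous"))
            het = fit_reml(data, ModelSpec(trait, "heterogeneous"))
            fit = select_residual_model(hom, het)
            fits[trait] = fit
            h2, shares = heritability_and_contributions(fit)
            rec = fit.to_dict()
            rec["h2"] = h2
            rec["contributions"] = shares
            fit_records.append(rec)
            blup_frames.append(genotype_blups(fit, data))
            flagged = flag_outliers(data, fit)
            if not flagged.empty:
                outlier_frames.append(flagged)
        blups = pd.concat(blup_frames, ignore_index=True)
        blups.to_csv(outdir / "blups.csv", index=False)
        with open(outdir / "fits.json", "w", encoding="utf-8") as fh:
            json.dump(fit_records, fh, indent=1)
        outliers = (
            pd.concat(outlier_frames, ignore_index=True)
            if outlier_frames
            else pd.DataFrame(
                columns=["genotype", "treatment", "replicate", "trait", "value",
                         "residual", "studentized"]
            )
        )
        outliers.to_csv(outdir / "outliers.csv", index=False)
        manifest["stages"][stage] = {
            "files": ["fits.json", "blups.csv", "outliers.csv"],
            "n_outliers": len(outliers),
            "heritability": {r["trait"]: r["h2"] for r in fit_records},
        }

        stage = "summaries_network"
        summary = summarize_traits(data, control=config.control)
        summary.to_csv(outdir / "summary.csv", index=False)
        files = ["summary.csv"]
        categories = (
            config.panel.trait_category_map() if config.mode == "synthetic" else {}
        )
        edge_counts = {}
        for treatment in treatments:
            wide = blups[blups["treatment"] == treatment].pivot_table(
                index="genotype", columns="trait", values="value", sort=False,
                aggfunc="first",
            )[traits]
            r, p = correlation_matrix(wide)
            name = _slug(str(treatment))
            r.to_csv(outdir / f"correlations_{name}.csv")
            net = build_network(
                r, p, alpha=config.alpha, categories=categories,
                treatment=str(treatment),
            )
            net.to_json(outdir / f"network_{name}.json")
            files += [f"correlations_{name}.csv", f"network_{name}.json"]
            edge_counts[str(treatment)] = len(net.edges)
        manifest["stages"][stage] = {"files": files, "edge_counts": edge_counts}

        stage = "penalized_selection"
        predictors = [t for t in traits if t not in config.responses]
        lasso_models, ridge_models = {}, {}
        support = {}
        for treatment in treatments:
            wide = blups[blups["treatment"] == treatment].pivot_table(
                index="genotype", columns="trait", values="value", sort=False,
                aggfunc="first",
            )
            X = wide[predictors]
            for response in config.responses:
                Xs, yc, scaling = standardize(X, wide[response])
                key = (str(treatment), response)
                lasso_models[key] = cross_validate_lambda(
                    Xs, yc, "lasso", seed=cv_seed, scaling=scaling
                )
                ridge_models[key] = cross_validate_lambda(
                    Xs, yc, "ridge", seed=cv_seed, scaling=scaling
                )
                support[f"{treatment}:{response}"] = [
                    predictors[j]
                    for j in np.nonzero(lasso_models[key].coef)[0]
                ]
        coefficient_table(lasso_models, predictors).to_csv(
            outdir / "lasso_coefficients.csv"
        )
        coefficient_table(ridge_models, predictors).to_csv(
            outdir / "ridge_coefficients.csv"
        )
        manifest["stages"][stage] = {
            "files": ["lasso_coefficients.csv", "ridge_coefficients.csv"],
            "lasso_support": support,
        }

        stage = "stress_classification"
        resp = config.classification_response
        resp_blups = blup_matrix(blups, resp)
        yp = resp_blups[config.control]
        files = []
        group_info = {}
        stress_treatments = [t for t in treatments if t != config.control]
        for treatment in stress_treatments:
            name = _slug(str(treatment))
            table = stress_score_table(
                yp, resp_blups[treatment], variant=config.scoring_variant
            )
            table.index.name = "genotype"
            table.to_csv(outdir / f"stress_indices_{name}.csv")
            score_cols = ["SSI_score", "TOL_score", "MP_score", "GMP_score",
                          "STI_score", "RCI", "PCI", "group"]
            have = [c for c in score_cols if c in table.columns]
            table[have].to_csv(outdir / f"scores_{name}.csv")
            wide = blups[blups["treatment"] == treatment].pivot_table(
                index="genotype", columns="trait", values="value", sort=False,
                aggfunc="first",
            )[traits]
            comparison = compare_extreme_groups(
                wide, table["group"], alpha=config.alpha
            )
            comparison.to_csv(outdir / f"group_comparison_{name}.csv", index=False)
            files += [
                f"stress_indices_{name}.csv",
                f"scores_{name}.csv",
                f"group_comparison_{name}.csv",
            ]
            group_info[str(treatment)] = table["group"].to_dict()
        manifest["stages"][stage] = {"files": files, "groups": group_info}
        if config.panel.planted_groups is not None:
            planted = dict(config.panel.planted_groups)
            recovery = {}
            for treatment, assigned in group_info.items():
                hits = [
                    g for g, grp in assigned.items()
                    if planted.get(g) in ("A", "D") and planted[g] == grp
                ]
                extremes = [g for g in planted if planted[g] in ("A", "D")]
                recovery[treatment] = (
                    len(hits) / len(extremes) if extremes else float("nan")
                )
            manifest["stages"][stage]["extreme_group_recovery"] = recovery

        stage = "ammi"
        inter = double_center(resp_blups)
        result = decompose(inter, n_components=2)
        result.scores_table().to_csv(outdir / "ammi_scores.csv", index=False)
        result.to_json(outdir / "ammi_summary.json")
        stability_summary(result).to_csv(outdir / "ammi_stability.csv")
        manifest["stages"][stage] = {
            "files": ["ammi_scores.csv", "ammi_summary.json", "ammi_stability.csv"],
            "variance_explained_percent": [
                float(v) for v in result.variance_explained
            ],
        }
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        partial_marker.write_text(f"failed at stage {stage}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    partial_marker.unlink(missing_ok=True)
    logger.info("pipeline complete: %s", outdir / "manifest.json")
    return manifest
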