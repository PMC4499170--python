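"""End-to-end pipeline: simulate → extract → associate → predict/select.

A run is described by a plain config dict (usually loaded from YAML);
:func:`run_pipeline` executes the requested stages, writes the feature
CSV, the four report TSVs and a JSON manifest into the output
directory, and returns the paths.  Reruns with the same config and seed
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import yaml

from .association import AssociationAnalysis
from .params import FACTOR_NAMES, BeatModelParams, CohortSpec, SweepParams
from .prediction import PredictionAnalysis, cv_evaluate
from .report import (
    association_table,
    prediction_table,
    selection_table,
    write_manifest,
)
from .synthetic import generate_cohort_features

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "load_config", "build_params", "run_pipeline"]


class ConfigError(ValueError):
    """A run config violates the schema; the message names the field."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def _complete_section(cfg: dict, name: str, cls):
    """Build a params dataclass from a config section.

    A present section must be complete (every field) with no unknown
    keys; an absent section falls back to the defaults.
    """
    if name not in cfg or cfg[name] is None:
        return cls()
    section = cfg[name]
    if not isinstance(section, dict):
        raise ConfigError(f"{name}: must be a mapping")
    names = [f.name for f in dataclasses.fields(cls)]
    for key in section:
        if key not in names:
            raise ConfigError(f"{name}.{key}: unknown field")
    for key in names:
        if key not in section:
            raise ConfigError(f"{name}.{key}: missing")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
    }
    return cls(**kwargs)


def _cohort_section(cfg: dict) -> CohortSpec:
    """Cohort section: partial overrides on top of the reference cohort."""
    if "cohort" not in cfg or cfg["cohort"] is None:
        return CohortSpec()
    section = cfg["cohort"]
    allowed = {f.name for f in dataclasses.fields(CohortSpec)}
    for key in section:
        if key not in allowed:
            raise ConfigError(f"cohort.{key}: unknown field")
    kwargs = dict(section)
    if "factor_stats" in kwargs:
        kwargs["factor_stats"] = {
            (w, f): tuple(map(tuple, v))
            for (w, f), v in (
                ((k.split("_", 1)[0], k.split("_", 1)[1]), v)
                for k, v in kwargs["factor_stats"].items()
            )
        }
    if "demographic_stats" in kwargs:
        kwargs["demographic_stats"] = {
            k: tuple(map(tuple, v)) for k, v in kwargs["demographic_stats"].items()
        }
    base = CohortSpec()
    kwargs.setdefault("factor_stats", base.factor_stats)
    kwargs.setdefault("demographic_stats", base.demographic_stats)
    return CohortSpec(**kwargs)


def build_params(cfg: dict) -> tuple[BeatModelParams, SweepParams, CohortSpec]:
    beat = _complete_section(cfg, "beat", BeatModelParams)
    sweep = _complete_section(cfg, "sweep", SweepParams)
    cohort = _cohort_section(cfg)
    return beat, sweep, cohort


def run_pipeline(config: dict, out_dir=None, seed: int | None = None) -> dict[str, Path]:
    """Execute the full analysis on a simulated cohort.

    Writes ``features.csv``, per-wrist association tables
    (``association_L.tsv`` / ``association_R.tsv``), the combined-model
    metrics (``prediction.tsv``), the selected subsets
    (``selection.tsv``), the resolved config and a JSON manifest.
    """
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else config.get("seed", 0))
    wrists = config.get("wrists", ["L", "R"])
    factors = config.get("factors", list(FACTOR_NAMES))
    for f in factors:
        if f not in FACTOR_NAMES:
            raise ConfigError(f"factors.{f}: unknown factor")
    _, _, cohort = build_params(config)

    caught: list[str] = []
    paths: dict[str, Path] = {}
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        table = generate_cohort_features(cohort, seed=seed)
        paths["features"] = out / "features.csv"
        table.to_csv(paths["features"], index=False)

        pred_results = {}
        selections = {}
        for wrist in wrists:
            assoc = AssociationAnalysis(table, wrist=wrist, factors=factors).fit()
            nb_auc, lr_auc = {}, {}
            for r, fname in zip(assoc.rows, factors):
                col = table[f"{wrist}_{fname}"].to_numpy()
                y = table["label"].to_numpy()
                nb_auc[r.factor] = cv_evaluate(col, y, model="nb", seed=seed).auc
                lr_auc[r.factor] = cv_evaluate(col, y, model="lr", seed=seed).auc
            tab = association_table(assoc, nb_auc=nb_auc, lr_auc=lr_auc)
            paths[f"association_{wrist}"] = out / f"association_{wrist}.tsv"
            tab.to_csv(paths[f"association_{wrist}"], sep="\t", index=False)

            for model, select, label in (
                ("nb", "wrapper", "Wrapper: NB"),
                ("lr", "wrapper", "Wrapper: LR"),
                ("lr", "lasso", "LASSO: LR"),
            ):
                res, sel = PredictionAnalysis(
                    table,
                    wrist=wrist,
                    model=model,
                    select=select,
                    factors=factors,
                    seed=seed,
                ).fit()
                pred_results[(wrist, label)] = res
                selections[(wrist, label)] = sel

        paths["prediction"] = out / "prediction.tsv"
        prediction_table(pred_results).to_csv(paths["prediction"], sep="\t", index=False)
        paths["selection"] = out / "selection.tsv"
        selection_table(selections).to_csv(paths["selection"], sep="\t", index=False)
        caught = [str(w.message) for w in wlist]

    resolved = dict(config)
    resolved.update({"seed": seed, "wrists": list(wrists), "factors": list(factors)})
    paths["config"] = out / "config_resolved.yaml"
    paths["config"].write_text(yaml.safe_dump(resolved, sort_keys=True))
    paths["manifest"] = out / "manifest.json"
    write_manifest(
        paths["manifest"],
        seed=seed,
        config=resolved,
        row_counts={"features": len(table)},
        warnings_seen=caught,
    )
    return paths
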