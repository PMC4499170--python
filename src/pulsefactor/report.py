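"""Report tables for the association/prediction pipeline.

Renders the four result tables of the analysis — per-wrist association
tables (crude and adjusted odds ratios plus single-factor AUCs),
combined-model prediction metrics, and the selected factor subsets — as
TSV-ready DataFrames, plus a JSON reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .association import AssociationResults, _fmt_p
from .prediction import PredictionResult, SelectionResult

__all__ = [
    "association_table",
    "prediction_table",
    "selection_table",
    "write_manifest",
]


def _fmt_or(or_, lo, hi) -> str:
    return f"{or_:.3f} ({lo:.3f}-{hi:.3f})"


def association_table(
    assoc: AssociationResults,
    nb_auc: dict[str, float] | None = None,
    lr_auc: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-factor association + predictive-power table (one wrist).

    Columns: Variable, crude p / OR (CI), adjusted p / OR (CI), and the
    single-factor NB/LR cross-validated AUCs when supplied.
    """
    rows = []
    for r in assoc.rows:
        row = {
            "Variable": r.factor,
            "Crude p": _fmt_p(r.crude_p),
            "Crude OR (95% CI)": _fmt_or(r.crude_or, r.crude_ci_lo, r.crude_ci_hi),
            "Adjusted p": _fmt_p(r.adj_p),
            "Adjusted OR (95% CI)": _fmt_or(r.adj_or, r.adj_ci_lo, r.adj_ci_hi),
        }
        if nb_auc is not None:
            row["NB-AUC"] = round(nb_auc[r.factor], 3)
        if lr_auc is not None:
            row["LR-AUC"] = round(lr_auc[r.factor], 3)
        rows.append(row)
    return pd.DataFrame(rows)


def prediction_table(results: dict[tuple[str, str], PredictionResult]) -> pd.DataFrame:
    """Combined-model per-class metrics table.

    ``results`` maps (wrist, method label) -> PredictionResult; one row
    per class per model, in the printed layout (AUC on the first row of
    each block).
    """
    rows = []
    for (wrist, method), res in results.items():
        for i, (cls, m) in enumerate(res.per_class.items()):
            rows.append(
                {
                    "Wrist": wrist if i == 0 else "",
                    "Method": method if i == 0 else "",
                    "Status": cls.capitalize(),
                    "AUC": round(res.auc, 3) if i == 0 else "",
                    "Sensitivity": round(m.sensitivity, 3),
                    "1-specificity": round(m.fpr, 3),
                    "Precision": round(m.precision, 3),
                    "F-measure": round(m.f_measure, 3),
                }
            )
    return pd.DataFrame(rows)


def selection_table(selections: dict[tuple[str, str], SelectionResult]) -> pd.DataFrame:
    """Selected-factor subsets per wrist and selection method."""
    rows = []
    for (wrist, method), sel in selections.items():
        rows.append(
            {
                "Wrist": wrist,
                "Method": method,
                "Selected factors": ", ".join(sel.selected),
                "Criterion": round(sel.criterion, 4),
                "Subsets evaluated": sel.search_size,
            }
        )
    return pd.DataFrame(rows)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(
    path: Path,
    seed: int,
    config: dict,
    row_counts: dict[str, int],
    warnings_seen: list[str] | None = None,
) -> None:
    """JSON run manifest: seed, config hash, row counts, warnings."""
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "row_counts": row_counts,
        "warnings": warnings_seen or [],
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
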