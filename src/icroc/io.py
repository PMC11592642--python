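"""Plain-text interchange: CSV for tables and curves, JSON for fits and masks.

CSV is the single tabular format (scores, ROC point sets, criterion
reports, frequency tables); JSON carries fitted-parameter records and GA
masks; YAML carries run configuration.  Every CLI command drops a run
manifest (seed, configuration, library versions) next to its outputs so a
run can be reproduced exactly.
"""

from __future__ import annotations

import json
import platform
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import FeatureTable
from .families import FittedDistribution
from .roc import ROCCurve
from .simulate import FrequencyTable

__all__ = [
    "read_scores",
    "write_scores",
    "read_class_sample",
    "write_class_sample",
    "write_fit",
    "read_fit",
    "write_curve",
    "read_curve",
    "write_reports",
    "write_frequency_table",
    "read_feature_table",
    "write_feature_table",
    "write_mask",
    "read_mask",
    "write_manifest",
]


def write_scores(path, scores, labels, score_column="score", label_column="label") -> None:
    pd.DataFrame({score_column: scores, label_column: labels}).to_csv(path, index=False)


def read_scores(path, score_column="score", label_column="label") -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (score_column, label_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    return df[score_column].to_numpy(float), df[label_column].to_numpy(int)


def write_class_sample(path, values, column="value") -> None:
    pd.DataFrame({column: np.asarray(values, dtype=float)}).to_csv(path, index=False)


def read_class_sample(path) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    return df[df.columns[0]].to_numpy(float)


def write_fit(path, fit: FittedDistribution) -> None:
    Path(path).write_text(json.dumps(fit.to_record(), indent=2) + "\n")


def read_fit(path) -> FittedDistribution:
    return FittedDistribution.from_record(json.loads(Path(path).read_text()))


def write_curve(path, curve: ROCCurve) -> None:
    thresholds = (
        curve.thresholds
        if curve.thresholds is not None
        else np.full(len(curve), np.nan)
    )
    pd.DataFrame(
        {"threshold": thresholds, "fpr": curve.fpr, "tpr": curve.tpr}
    ).to_csv(path, index=False)


def read_curve(path, kind="empirical", source="") -> ROCCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    return ROCCurve(
        fpr=df["fpr"].to_numpy(float),
        tpr=df["tpr"].to_numpy(float),
        kind=kind,
        source=source,
        thresholds=df["threshold"].to_numpy(float) if "threshold" in df else None,
    )


def write_reports(path, reports) -> None:
    """Criterion reports as CSV rows (candidate, auc, aic_roc, icomp_roc, c1, r, n)."""
    pd.DataFrame([rep.to_row() for rep in reports]).to_csv(path, index=False)


def write_frequency_table(path, table: FrequencyTable) -> None:
    table.to_frame().rename_axis("candidate").to_csv(path)


def write_feature_table(path, table: FeatureTable, label_column="label") -> None:
    table.to_frame(label_column).to_csv(path, index=False)


def read_feature_table(path, label_column="label") -> FeatureTable:
    return FeatureTable.from_frame(
        pd.read_csv(path, float_precision="round_trip"), label_column=label_column
    )


def write_mask(path, mask, feature_names=None, fitness=None) -> None:
    mask = np.asarray(mask, dtype=bool)
    record = {
        "mask": mask.astype(int).tolist(),
        "selected_indices": np.flatnonzero(mask).tolist(),
    }
    if feature_names is not None:
        record["selected_features"] = [feature_names[i] for i in np.flatnonzero(mask)]
    if fitness is not None:
        record["fitness"] = float(fitness)
    Path(path).write_text(json.dumps(record, indent=2) + "\n")


def read_mask(path) -> np.ndarray:
    return np.asarray(json.loads(Path(path).read_text())["mask"], dtype=bool)


def write_manifest(out_dir, command: str, seed, config: dict) -> Path:
    """YAML run manifest recording the command, seed, config and versions."""
    import scipy
    import sklearn

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "seed": seed,
        "config": config,
        "versions": {
            "python": sys.version.split()[0],
            "platform": platform.platform(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    path = out_dir / "run_manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path
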