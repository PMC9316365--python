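"""Serialization helpers: trained models, surface counts, annotations.

Regression models round-trip through plain JSON (coefficients stay
human-readable, as a coefficient table should be); tree ensembles carry a
JSON sidecar with their hyperparameters next to a joblib payload.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .models import (
    MODEL_FAMILIES,
    GradientBoostedInterfaceScorer,
    LinearInterfaceScorer,
    LogisticInterfaceScorer,
    RandomForestInterfaceScorer,
)

__all__ = ["save_model", "load_model", "read_surface_counts", "write_surface_counts"]

FORMAT_VERSION = 1

_FAMILY_OF = {
    LinearInterfaceScorer: "linear",
    LogisticInterfaceScorer: "logistic",
    RandomForestInterfaceScorer: "rf",
    GradientBoostedInterfaceScorer: "gbt",
}


def save_model(model, path: str | Path) -> Path:
    """Persist a fitted integration model.

    Writes ``<path>.json`` always; tree ensembles additionally write
    ``<path>.joblib`` holding the fitted sklearn object.
    """
    path = Path(path)
    family = _FAMILY_OF.get(type(model))
    if family is None:
        raise ValueError(f"not an integration model: {type(model).__name__}")
    meta = {
        "format_version": FORMAT_VERSION,
        "family": family,
        "params": model.get_params(),
        "n_features": int(model.n_features_in_),
    }
    if family in ("linear", "logistic"):
        meta["coefficients"] = list(map(float, model.coef_))
        meta["intercept"] = float(model.intercept_)
    else:
        import joblib

        joblib.dump(model, path.with_suffix(".joblib"))
        meta["payload"] = path.with_suffix(".joblib").name
    json_path = path.with_suffix(".json")
    json_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return json_path


def load_model(path: str | Path):
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    meta = json.loads(path.read_text())
    if meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {meta.get('format_version')}")
    family = meta["family"]
    if family in ("linear", "logistic"):
        import numpy as np

        model = MODEL_FAMILIES[family](**meta["params"])
        model.coef_ = np.asarray(meta["coefficients"], dtype=float)
        model.intercept_ = float(meta["intercept"])
        model.n_features_in_ = int(meta["n_features"])
        if family == "logistic":
            model.separation_ = False
        else:
            model.rank_deficient_ = False
        return model
    import joblib

    return joblib.load(path.parent / meta["payload"])


def read_surface_counts(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["protein_id"].astype(str), df["R"].astype(int)))


def write_surface_counts(surface: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"protein_id": list(surface), "R": [int(v) for v in surface.values()]}
    ).to_csv(path, sep="\t", index=False)
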