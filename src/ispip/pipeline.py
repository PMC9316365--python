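"""End-to-end orchestration: annotate/simulate → split → train → predict →
evaluate, with a run manifest that makes reruns reproducible.

Randomness flows from one master seed: each stage draws its own named
substream (protein split, fold assignment, model fitting), so stages are
individually reproducible and independent of each other's draw counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import evaluate_model
from .models import DEFAULT_GRIDS, CVResult, cross_validate, predict
from .table import ScoreTable, normalize_scores

__all__ = ["RunConfig", "split_dataset", "run_pipeline", "PipelineError"]

logger = logging.getLogger("ispip")

_SUBSTREAMS = {"split": 1, "folds": 2, "fit": 3}


def _substream(master_seed: int, name: str) -> int:
    """Derive a named child seed below 2**31 from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), _SUBSTREAMS[name]])
    return int(ss.generate_state(1)[0] % (2**31))


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def split_dataset(
    protein_ids: Sequence[str],
    test: float | int | Sequence[str] = 0.2,
    folds: int = 5,
    seed: int = 0,
) -> tuple[list[str], dict[str, int]]:
    """Hold out a test set and partition the remainder into CV folds.

    ``test`` is a fraction, an absolute count, or an explicit id list.
    Train folds are near-equal (remainders fill the lowest fold numbers);
    deterministic given seed.  Residues never enter the split — the unit is
    always the protein.
    """
    ids = list(protein_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    rng = np.random.default_rng(seed)
    if isinstance(test, (list, tuple, set)):
        test_ids = list(test)
        unknown = set(test_ids) - set(ids)
        if unknown:
            raise ValueError(f"test ids not in dataset: {sorted(unknown)[:3]}")
    else:
        n_test = int(round(test * len(ids))) if isinstance(test, float) else int(test)
        if not 0 <= n_test < len(ids):
            raise ValueError("test size out of range")
        order = rng.permutation(len(ids))
        test_ids = [ids[i] for i in order[:n_test]]
    train_ids = [p for p in ids if p not in set(test_ids)]
    if len(train_ids) < folds:
        raise ValueError(f"need at least {folds} training proteins")
    # shuffle then deal round-robin: fold sizes differ by at most one
    order = rng.permutation(len(train_ids))
    fold_of = {train_ids[j]: (i % folds) + 1 for i, j in enumerate(order)}
    return test_ids, fold_of


@dataclass
class RunConfig:
    """Declarative description of one integration run."""

    scores_path: str | None = None  # omit to simulate
    output_dir: str = "ispip_run"
    model_families: tuple[str, ...] = ("linear", "logistic", "rf", "gbt")
    folds: int = 5
    seed: int = 0
    test_fraction: float = 0.2
    test_ids: tuple[str, ...] | None = None
    cutoff_mode: str = "round"
    normalization: str = "none"
    surface_path: str | None = None
    grids: dict | None = None
    # simulation fallback when scores_path is None
    n_proteins: int = 50

    def to_dict(self) -> dict:
        return asdict(self)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: RunConfig) -> tuple[ScoreTable, dict[str, int]]:
    if config.scores_path is None:
        from .simulate import SyntheticConfig, generate_dataset

        return generate_dataset(
            SyntheticConfig(n_proteins=config.n_proteins, seed=config.seed)
        )
    table = ScoreTable.read(config.scores_path)
    if config.surface_path is None:
        raise PipelineError("load", "surface counts file required with external scores")
    surf_df = pd.read_csv(config.surface_path, sep="\t")
    surface = dict(zip(surf_df["protein_id"].astype(str), surf_df["R"].astype(int)))
    return table, surface


def run_pipeline(config: RunConfig) -> dict:
    """Execute the staged workflow and write models, predictions, metrics
    and a manifest under ``config.output_dir``.

    Deterministic: a rerun with the same config reproduces every metrics
    file byte-identically.  Returns the manifest dict.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage load: reading inputs")
    try:
        table, surface = _load_inputs(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc

    try:
        table = normalize_scores(table, config.normalization)
        if not table.has_labels:
            raise ValueError("score table has no label column; cannot train")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("train", str(exc)) from exc

    logger.info("stage split: %d proteins", len(table.protein_ids()))
    test_ids, fold_of = split_dataset(
        table.protein_ids(),
        test=list(config.test_ids) if config.test_ids else config.test_fraction,
        folds=config.folds,
        seed=_substream(config.seed, "split"),
    )
    train_table = table.subset(fold_of.keys())
    test_table = table.subset(test_ids)
    # leakage guard: no residue of a test protein may appear in training
    overlap = set(train_table.protein_ids()) & set(test_ids)
    assert not overlap, f"test proteins leaked into training: {sorted(overlap)}"

    fit_seed = _substream(config.seed, "fit")
    results: dict[str, CVResult] = {}
    predictions = test_table.frame.copy()
    for family in config.model_families:
        logger.info("stage train: %s (grouped %d-fold CV)", family, config.folds)
        grid = (config.grids or {}).get(family) if config.grids else None
        try:
            from .models import CVPlan

            plan = CVPlan(
                folds=fold_of,
                grid=list(grid) if grid is not None else list(DEFAULT_GRIDS[family]),
                rounding=config.cutoff_mode,
            )
            res = cross_validate(
                train_table, surface, family, plan=plan, seed=fit_seed
            )
        except Exception as exc:
            raise PipelineError("train", f"{family}: {exc}") from exc
        results[family] = res
        predictions[family] = predict(res.model, test_table)

    pred_path = out / "predictions.tsv"
    predictions.to_csv(pred_path, sep="\t", index=False)

    logger.info("stage evaluate: %d test proteins", len(test_ids))
    metrics_rows = []
    averages: dict[str, dict[str, float]] = {}
    pred_table = ScoreTable(predictions, predictors=list(table.predictors))
    for column in list(table.predictors) + list(config.model_families):
        try:
            report = evaluate_model(pred_table, column, surface, config.cutoff_mode)
        except Exception as exc:
            raise PipelineError("evaluate", f"{column}: {exc}") from exc
        averages[column] = report.averages
        df = report.per_protein.copy()
        df.insert(0, "method", column)
        metrics_rows.append(df)
    metrics = pd.concat(metrics_rows, ignore_index=True)
    metrics_path = out / "metrics.tsv"
    metrics.to_csv(metrics_path, sep="\t", index=False)

    models_payload = {
        family: {
            "best_params": res.best_params,
            "cv_mean_fscore": res.best_score,
            "coefficients": getattr(res.model, "coef_", None).tolist()
            if getattr(res.model, "coef_", None) is not None
            else None,
            "intercept": getattr(res.model, "intercept_", None),
        }
        for family, res in results.items()
    }
    (out / "models.json").write_text(json.dumps(models_payload, indent=2, sort_keys=True))

    import ispip

    manifest = {
        "tool": "ispip",
        "version": ispip.__version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "substream_seeds": {k: _substream(config.seed, k) for k in _SUBSTREAMS},
        "test_proteins": sorted(test_ids),
        "cv_folds": {k: int(v) for k, v in sorted(fold_of.items())},
        "averages": averages,
        "outputs": {
            "predictions": pred_path.name,
            "metrics": metrics_path.name,
            "models": "models.json",
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
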