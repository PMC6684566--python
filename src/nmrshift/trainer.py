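"""Training orchestration: config files, per-nucleus runs, checkpoints.

Thin layer over :class:`~nmrshift.gnn.GraphConvShiftRegressor`: it selects
one nucleus's assignments as targets, fits the estimator (which carves its
own structure-blind validation split and early-stops on validation loss),
and emits a metrics log plus a reloadable checkpoint.  The upstream
train/test split is ``nmrshift.io.split_by_structure``'s job and happens
before this module is involved.

The optimizer and schedule (Adam, fixed learning rate, minibatches) are this
package's choices; at the default desk scale (4 layers, width 128) a run
takes minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gnn import GraphConvShiftRegressor
from .graphs import MolecularGraph
from .io import ShiftAssignment
from .synthetic import targets_from_assignments


@dataclass
class TrainConfig:
    """Reproducible training run description (YAML-serializable)."""

    nucleus: str = "C13"
    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 3e-3
    seed: int = 0
    n_layers: int = 4
    width: int = 128
    head_width: int = 128
    m_max: int = 64
    validation_fraction: float = 0.1
    patience: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def train(
    mols: list[MolecularGraph],
    assignments: list[ShiftAssignment],
    config: TrainConfig,
) -> tuple[GraphConvShiftRegressor, pd.DataFrame]:
    """Fit one per-nucleus model; returns (fitted estimator, metrics log).

    Targets are the chosen nucleus's shifts; when a nucleus has several
    measurements (multiple spectra) they are averaged into one target per
    atom.  Raises if the nucleus has no observations at all.
    """
    y = targets_from_assignments(mols, assignments, config.nucleus)
    if not any(np.isfinite(t).any() for t in y):
        raise ValueError(f"no observed {config.nucleus} shifts in the training data")
    est = GraphConvShiftRegressor(
        n_layers=config.n_layers,
        width=config.width,
        head_width=config.head_width,
        m_max=config.m_max,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        validation_fraction=config.validation_fraction,
        patience=config.patience,
        seed=config.seed,
    )
    est.fit(mols, y)
    metrics = pd.DataFrame(
        {
            "epoch": np.arange(len(est.loss_curve_)),
            "train_loss": est.loss_curve_,
            "val_loss": est.val_loss_curve_,
            "val_mae": est.val_mae_curve_,
        }
    )
    return est, metrics


def evaluate_checkpoint(
    est: GraphConvShiftRegressor,
    mols: list[MolecularGraph],
    assignments: list[ShiftAssignment],
    nucleus: str,
) -> pd.DataFrame:
    """Per-atom prediction table (y, mu, sigma) over observed test nuclei."""
    from .evaluate import prediction_table

    y = targets_from_assignments(mols, assignments, nucleus)
    preds = est.predict_dist(mols) if mols else []
    return prediction_table(mols, y, preds, nucleus=nucleus)
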