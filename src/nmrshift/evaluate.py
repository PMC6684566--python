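"""Evaluation machinery: confidence-fraction curves, error metrics, strata, CIs.

Prediction tables are pandas DataFrames with (at least) columns
``molecule_id``, ``atom_index``, ``y`` (observed ppm), ``mu`` (predicted
ppm), and a confidence column — ``sigma`` (continuous, lower = more
confident) for the network, ``matched_sphere`` (discrete, higher = more
confident) for the HOSE baseline.

The central comparison statistic is the confidence-fraction curve: for each
fraction f, the mean absolute error over the ceil(f*N) most-confident
predictions.  At f = 1 it equals the global MAE by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import MolecularGraph

DEFAULT_FRACTIONS = (0.10, 0.25, 0.50, 0.80, 0.95, 1.00)


@dataclass
class ConfidenceCurve:
    """(retained fraction, MAE) pairs, fractions strictly increasing."""

    fractions: np.ndarray
    mae: np.ndarray
    confidence_source: str  # "sigma" or "matched_sphere"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fraction": self.fractions, "mae": self.mae})


def confidence_curve(
    pred: pd.DataFrame,
    fractions=DEFAULT_FRACTIONS,
    confidence: str = "sigma",
) -> ConfidenceCurve:
    """MAE over the most-confident fraction of predictions, per fraction.

    ``sigma`` ranks ascending (small predicted uncertainty first),
    ``matched_sphere`` descending (deep sphere match first).  Ties are broken
    by stable input order.
    """
    if len(pred) == 0:
        raise ValueError("empty prediction table")
    if confidence not in pred.columns:
        raise KeyError(f"missing confidence column {confidence!r}")
    fractions = np.asarray(sorted(fractions), dtype=float)
    if np.any(fractions <= 0) or np.any(fractions > 1):
        raise ValueError("fractions must lie in (0, 1]")
    ascending = confidence != "matched_sphere"
    order = pred[confidence].to_numpy()
    idx = np.argsort(order if ascending else -order, kind="stable")
    abs_err = np.abs(pred["y"].to_numpy() - pred["mu"].to_numpy())[idx]
    n = len(abs_err)
    mae = np.array([abs_err[: int(np.ceil(f * n))].mean() for f in fractions])
    return ConfidenceCurve(fractions=fractions, mae=mae, confidence_source=confidence)


@dataclass
class ErrorBreakdown:
    """Global metrics plus an optional per-group table."""

    mae: float
    mol_mae: float
    mol_rmse: float
    n: int
    groups: pd.DataFrame | None = None  # columns: group, mean, sd, max, n, ci_low, ci_high


def error_metrics(
    pred: pd.DataFrame,
    grouping: str | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> ErrorBreakdown:
    """MAE, per-molecule MAE/RMSE, and optionally grouped error statistics.

    ``mol MAE`` / ``mol RMSE`` first average the absolute error within each
    molecule, then take the mean / root-mean-square across molecules.  When
    ``grouping`` names a column, per-group mean/sd/max/n plus a bootstrap 95%
    CI of the group mean error are returned as well.
    """
    if len(pred) == 0:
        raise ValueError("empty prediction table")
    err = np.abs(pred["y"].to_numpy() - pred["mu"].to_numpy())
    per_mol = pd.Series(err).groupby(pred["molecule_id"].to_numpy()).mean()
    out = ErrorBreakdown(
        mae=float(err.mean()),
        mol_mae=float(per_mol.mean()),
        mol_rmse=float(np.sqrt(np.mean(per_mol.to_numpy() ** 2))),
        n=len(pred),
    )
    if grouping is not None:
        rows = []
        rng_seed = seed
        for key, sub in pred.assign(_err=err).groupby(grouping, observed=True):
            vals = sub["_err"].to_numpy()
            if len(vals) >= 2:
                lo, hi = bootstrap_ci(vals, n_boot=n_boot, seed=rng_seed)
            else:
                lo = hi = float(vals.mean())
            rows.append(
                {"group": key, "mean": vals.mean(), "sd": vals.std(ddof=0),
                 "max": vals.max(), "n": len(vals), "ci_low": lo, "ci_high": hi}
            )
            rng_seed += 1
        out.groups = pd.DataFrame(rows)
    return out


def shift_bin_strata(pred: pd.DataFrame, bin_width: float) -> pd.DataFrame:
    """Attach a ``shift_bin`` column: fixed-width bins of the observed shift.

    Conventional widths: 10 ppm for 13C, 0.5 ppm for 1H.
    """
    edges = np.floor(pred["y"].to_numpy() / bin_width) * bin_width
    return pred.assign(shift_bin=edges)


def bonding_partner_strata(
    graphs: dict[str, MolecularGraph], pred: pd.DataFrame
) -> pd.DataFrame:
    """Expand the table so each nucleus appears once per bonded element.

    A nucleus bonded to several distinct partner elements contributes a row
    to each such stratum (documented multi-membership), under the added
    ``partner`` column.
    """
    rows = []
    for _, row in pred.iterrows():
        graph = graphs.get(row["molecule_id"])
        if graph is None:
            raise KeyError(f"prediction row references unknown molecule {row['molecule_id']!r}")
        i = int(row["atom_index"])
        partners = sorted({graph.atoms[j].element for j, _ in graph.neighbors(i)})
        for p in partners:
            rows.append({**row.to_dict(), "partner": p})
    return pd.DataFrame(rows)


def bootstrap_ci(
    values, n_boot: int = 10_000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI of the mean."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values for a bootstrap CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def prediction_table(
    graphs: list[MolecularGraph],
    y: list[np.ndarray],
    predictions,
    nucleus: str | None = None,
) -> pd.DataFrame:
    """Assemble the standard evaluation table from per-molecule arrays.

    ``predictions`` is either a list of :class:`~nmrshift.gnn.ShiftPrediction`
    (columns mu + sigma) or a list of (mu, matched_sphere) pairs from the
    HOSE baseline.  Rows are emitted only for observed atoms (finite y).
    """
    rows = []
    for graph, targets, pred in zip(graphs, y, predictions):
        if hasattr(pred, "mu") and hasattr(pred, "sigma"):
            mu, conf, conf_name = pred.mu, pred.sigma, "sigma"
        else:
            mu, conf = pred
            conf_name = "matched_sphere"
        for i, t in enumerate(np.asarray(targets, dtype=float)):
            if not np.isfinite(t):
                continue
            row = {
                "molecule_id": graph.mol_id,
                "atom_index": i,
                "element": graph.atoms[i].element,
                "y": t,
                "mu": float(mu[i]),
                conf_name: conf[i],
            }
            if nucleus is not None:
                row["nucleus"] = nucleus
            rows.append(row)
    return pd.DataFrame(rows)
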