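"""Serum biomarker preprocessing: MICE/PMM imputation and min-max scaling.

The biomarker channel consumes four serum markers per patient (CEA, CA125,
CA19-9, AFP). Missing cells are completed by chained equations with
predictive mean matching: each marker is regressed on the other three by
ordinary least squares, missing cells receive the observed value of a donor
row whose predicted mean is nearest, and the sweep repeats for a fixed
number of iterations. PMM guarantees every imputed value lies in the
marker's observed support. A single completed table is produced
(single-imputation; no Rubin pooling).

Min-max normalization is fitted on training rows only; at apply time values
outside the training range are clipped to [0, 1] so unseen cohorts cannot
produce out-of-range features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MARKERS = ("CEA", "CA125", "CA19_9", "AFP")

__all__ = [
    "MARKERS",
    "BiomarkerRecord",
    "NormalizationParams",
    "ImputationModel",
    "read_biomarker_table",
    "write_biomarker_table",
    "impute_mice_pmm",
    "fit_minmax",
    "apply_minmax",
]


@dataclass
class BiomarkerRecord:
    patient_id: str
    values: dict  # marker -> float (NaN if missing)
    missing_flags: dict  # marker -> bool

    @staticmethod
    def from_row(row: pd.Series) -> "BiomarkerRecord":
        vals = {m: float(row[m]) if pd.notna(row[m]) else float("nan") for m in MARKERS}
        return BiomarkerRecord(
            patient_id=str(row["patient_id"]),
            values=vals,
            missing_flags={m: bool(np.isnan(vals[m])) for m in MARKERS},
        )


def read_biomarker_table(path: str | Path) -> pd.DataFrame:
    """Read the cohort CSV (patient_id, CEA, CA125, CA19_9, AFP, label).

    Empty cells become NaN and are flagged missing downstream. Non-numeric
    marker cells raise with the offending row id.
    """
    table = pd.read_csv(path, dtype={"patient_id": str})
    missing_cols = [c for c in ("patient_id", *MARKERS) if c not in table.columns]
    if missing_cols:
        raise ValueError(f"biomarker table missing columns: {missing_cols}")
    for m in MARKERS:
        coerced = pd.to_numeric(table[m], errors="coerce")
        bad = coerced.isna() & table[m].notna()
        if bad.any():
            rid = table.loc[bad, "patient_id"].iloc[0]
            raise ValueError(f"non-numeric {m} value in row for patient {rid!r}")
        table[m] = coerced.astype(float)
    return table


def write_biomarker_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def _ols_predict(X: np.ndarray, y: np.ndarray, X_new: np.ndarray) -> tuple:
    """Least-squares fit of y on X (with intercept); returns (coef, predictions)."""
    A = np.column_stack([np.ones(len(X)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    A_new = np.column_stack([np.ones(len(X_new)), X_new])
    return coef, A_new @ coef


@dataclass
class ImputationModel:
    """Frozen state of a fitted MICE/PMM run, applicable to unseen rows.

    Stores, per marker, the final-sweep regression coefficients and the
    training donor pool (observed values with their predicted means), plus
    initialization means. ``seen_ids`` records the training rows used, for
    the leakage audit.
    """

    coefs: dict = field(default_factory=dict)  # marker -> ndarray (4,)
    donors: dict = field(default_factory=dict)  # marker -> (pred_means, values)
    init_means: dict = field(default_factory=dict)
    n_iterations: int = 10
    k_donors: int = 5
    seen_ids: tuple = ()

    def apply(self, table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
        """Complete unseen rows using training regressions and donor pools."""
        rng = np.random.default_rng(seed)
        out = table.copy()
        vals = out[list(MARKERS)].to_numpy(dtype=float)
        miss = np.isnan(vals)
        for j, m in enumerate(MARKERS):
            vals[miss[:, j], j] = self.init_means[m]
        for _ in range(self.n_iterations):
            for j, m in enumerate(MARKERS):
                rows = np.flatnonzero(miss[:, j])
                if len(rows) == 0:
                    continue
                others = [k for k in range(len(MARKERS)) if k != j]
                A = np.column_stack([np.ones(len(rows)), vals[np.ix_(rows, others)]])
                pred = A @ self.coefs[m]
                donor_pred, donor_vals = self.donors[m]
                for r, p in zip(rows, pred):
                    vals[r, j] = _pmm_draw(donor_pred, donor_vals, p, self.k_donors, rng)
        out[list(MARKERS)] = vals
        return out


def _pmm_draw(donor_pred, donor_vals, target_pred, k, rng) -> float:
    """Copy one of the k observed values whose predicted mean is nearest."""
    k = min(k, len(donor_vals))
    order = np.argsort(np.abs(donor_pred - target_pred), kind="stable")[:k]
    return float(donor_vals[order[rng.integers(k)]])


def impute_mice_pmm(
    table: pd.DataFrame,
    n_iterations: int = 10,
    k_donors: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, ImputationModel]:
    """Chained-equation imputation with predictive mean matching.

    Markers are swept in fixed order (CEA, CA125, CA19-9, AFP) for
    determinism; missing cells start at the observed marker mean. Observed
    cells are never altered. Returns the completed table and the frozen
    model for application to held-out rows.
    """
    out = table.copy()
    vals = out[list(MARKERS)].to_numpy(dtype=float)
    miss = np.isnan(vals)
    rng = np.random.default_rng(seed)

    model = ImputationModel(
        n_iterations=n_iterations,
        k_donors=k_donors,
        seen_ids=tuple(table["patient_id"]) if "patient_id" in table else (),
    )
    for j, m in enumerate(MARKERS):
        obs = vals[~miss[:, j], j]
        if len(obs) == 0:
            raise ValueError(f"marker {m} has no observed values; cannot impute")
        model.init_means[m] = float(obs.mean())
        vals[miss[:, j], j] = model.init_means[m]

    if not miss.any():
        # identity case: nothing to do, but still freeze donor pools
        n_iterations_eff = 1
    else:
        n_iterations_eff = n_iterations

    for _ in range(n_iterations_eff):
        for j, m in enumerate(MARKERS):
            others = [k for k in range(len(MARKERS)) if k != j]
            obs_rows = np.flatnonzero(~miss[:, j])
            mis_rows = np.flatnonzero(miss[:, j])
            X_obs = vals[np.ix_(obs_rows, others)]
            y_obs = vals[obs_rows, j]
            coef, pred_obs = _ols_predict(X_obs, y_obs, X_obs)
            model.coefs[m] = coef
            model.donors[m] = (pred_obs, y_obs.copy())
            if len(mis_rows) == 0:
                continue
            A_mis = np.column_stack([np.ones(len(mis_rows)), vals[np.ix_(mis_rows, others)]])
            pred_mis = A_mis @ coef
            for r, p in zip(mis_rows, pred_mis):
                vals[r, j] = _pmm_draw(pred_obs, y_obs, p, k_donors, rng)

    out[list(MARKERS)] = vals
    return out, model


@dataclass
class NormalizationParams:
    """Per-marker training min/max for min-max scaling (fit on training only)."""

    mins: dict
    maxs: dict
    seen_ids: tuple = ()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"mins": self.mins, "maxs": self.maxs}, indent=1)
        )

    @staticmethod
    def from_json(path: str | Path) -> "NormalizationParams":
        d = json.loads(Path(path).read_text())
        return NormalizationParams(mins=d["mins"], maxs=d["maxs"])


def fit_minmax(train_table: pd.DataFrame) -> NormalizationParams:
    mins, maxs = {}, {}
    for m in MARKERS:
        col = train_table[m].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(f"cannot fit min-max with missing values in {m}; impute first")
        mins[m] = float(col.min())
        maxs[m] = float(col.max())
    return NormalizationParams(
        mins=mins,
        maxs=maxs,
        seen_ids=tuple(train_table["patient_id"]) if "patient_id" in train_table else (),
    )


def apply_minmax(table: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """x' = (x - min) / (max - min), clipped to [0, 1]; constant marker -> 0."""
    if not params.mins:
        raise ValueError("normalization params are unfitted")
    out = table.copy()
    for m in MARKERS:
        lo, hi = params.mins[m], params.maxs[m]
        col = out[m].to_numpy(dtype=float)
        if hi > lo:
            out[m] = np.clip((col - lo) / (hi - lo), 0.0, 1.0)
        else:
            out[m] = np.zeros_like(col)
    return out
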