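"""Conformer validation against ¹H NMR via a shielding-to-shift linear map.

Computed isotropic shieldings σ map onto TMS-referenced experimental
shifts δ approximately as δ ≈ σ_ref − σ, so an ordinary least-squares fit
of δ on σ should have slope near −1 for the conformer that generated the
spectrum.  Conformers are ranked by goodness of fit (RMSE primary, R²
reported); the best-fitting conformer is the experimentally supported one.
Symmetry-equivalent protons are averaged on the computed side before
fitting, mirroring experimental equivalence under fast rotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cmp_to_key

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateFitError, InsufficientDataError, InvalidInputError

__all__ = [
    "ShieldingShiftTable",
    "ShiftFitResult",
    "average_equivalent",
    "fit_shift_model",
    "rank_conformers",
]


@dataclass(frozen=True)
class ShieldingShiftTable:
    """Per-proton-group computed shielding vs measured shift for one conformer."""

    conformer_label: str
    records: pd.DataFrame  # columns: proton_group, sigma_calc, delta_exp
    protonation_state: str = "neutral"

    def __post_init__(self) -> None:
        df = self.records
        required = {"proton_group", "sigma_calc", "delta_exp"}
        if not required.issubset(df.columns):
            raise InvalidInputError(f"records must have columns {sorted(required)}")
        if len(df) < 3:
            raise InsufficientDataError(
                f"conformer {self.conformer_label!r}: need >= 3 proton groups, got {len(df)}"
            )
        if df["proton_group"].duplicated().any():
            raise InvalidInputError(
                f"conformer {self.conformer_label!r}: duplicate proton group labels"
            )
        vals = df[["sigma_calc", "delta_exp"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("non-finite shielding/shift values")
        if self.protonation_state not in {"neutral", "protonated"}:
            raise InvalidInputError(
                f"protonation_state must be neutral|protonated, got {self.protonation_state!r}"
            )
        object.__setattr__(self, "records", df.reset_index(drop=True))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> list["ShieldingShiftTable"]:
        """Split a long-format table (one row per conformer × proton group)."""
        out = []
        for (label, state), grp in df.groupby(["conformer_label", "state"], sort=True):
            out.append(
                cls(
                    conformer_label=str(label),
                    records=grp[["proton_group", "sigma_calc", "delta_exp"]].copy(),
                    protonation_state=str(state),
                )
            )
        return out


def average_equivalent(df: pd.DataFrame, groups: dict) -> pd.DataFrame:
    """Average computed shieldings over symmetry-equivalent protons.

    ``groups`` maps a group label to the list of per-proton columns/rows
    (by ``proton`` label in ``df``) that are equivalent under fast
    rotation; the measured shift of the group must be identical across
    members and is carried through.
    """
    rows = []
    for label, members in groups.items():
        sub = df[df["proton"].isin(members)]
        if sub.empty:
            raise InvalidInputError(f"equivalence group {label!r} matches no protons")
        deltas = sub["delta_exp"].unique()
        if len(deltas) != 1:
            raise InvalidInputError(
                f"equivalence group {label!r} mixes different experimental shifts"
            )
        rows.append(
            {
                "proton_group": label,
                "sigma_calc": float(sub["sigma_calc"].mean()),
                "delta_exp": float(deltas[0]),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ShiftFitResult:
    """OLS fit of experimental shift on computed shielding for one conformer."""

    conformer_label: str
    slope: float
    intercept: float
    r_squared: float
    rmse: float
    slope_stderr: float
    n_groups: int

    def summary(self) -> str:
        return (
            f"{self.conformer_label}: delta = {self.intercept:.3f} "
            f"{self.slope:+.3f}*sigma  (R^2 = {self.r_squared:.4f}, "
            f"RMSE = {self.rmse:.4f} ppm, n = {self.n_groups})"
        )


def fit_shift_model(table: ShieldingShiftTable) -> ShiftFitResult:
    """Ordinary least squares of δ_exp on σ_calc for one conformer.

    Slope is expected near −1 for a TMS-referenced mapping; the intercept
    estimates the reference shielding.  R² is defined as 0 when the
    response has no variance (the fit then explains nothing).
    """
    sigma = table.records["sigma_calc"].to_numpy(dtype=float)
    delta = table.records["delta_exp"].to_numpy(dtype=float)
    if np.ptp(sigma) == 0.0:
        raise DegenerateFitError(
            f"conformer {table.conformer_label!r}: zero variance in computed shieldings"
        )
    res = sm.OLS(delta, sm.add_constant(sigma)).fit()
    tss = float(np.sum((delta - delta.mean()) ** 2))
    r2 = float(res.rsquared) if tss > 0 else 0.0
    return ShiftFitResult(
        conformer_label=table.conformer_label,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=r2,
        rmse=float(np.sqrt(np.mean(res.resid**2))),
        slope_stderr=float(res.bse[1]),
        n_groups=len(sigma),
    )


def _fit_cmp(a: ShiftFitResult, b: ShiftFitResult) -> int:
    if abs(a.rmse - b.rmse) >= 1e-9:
        return -1 if a.rmse < b.rmse else 1
    if a.r_squared != b.r_squared:  # tie on RMSE: higher R^2 first
        return -1 if a.r_squared > b.r_squared else 1
    return -1 if a.conformer_label < b.conformer_label else (0 if a.conformer_label == b.conformer_label else 1)


def rank_conformers(tables) -> list[ShiftFitResult]:
    """Fit every conformer and order by fit quality (best first).

    Ascending RMSE; ties (ΔRMSE < 1e−9) broken by higher R², then by
    label order.  The first element is the experimentally supported
    conformer.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise InsufficientDataError("ranking needs at least two conformers")
    fits = [fit_shift_model(t) for t in tables]
    return sorted(fits, key=cmp_to_key(_fit_cmp))
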