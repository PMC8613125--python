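"""Acid/base speciation of a single ionisable group across pH.

For a monoprotic equilibrium HA ⇌ H⁺ + A⁻ the Henderson–Hasselbalch
relation pH = pKa + log₁₀([A⁻]/[HA]) fixes the fraction of each species at
a given pH.  For an amine cue such as 2-phenylethylamine the conjugate
acid HA is the protonated ammonium form, so the "protonated fraction" is

    f_HA(pH) = 1 / (1 + 10^(pH − pKa)),

which decreases monotonically with pH and equals 1/2 at pH = pKa.
Fractions are kept at full floating precision; percentage formatting to
one decimal place is a presentation choice only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "AcidBaseSpec",
    "SpeciationProfile",
    "fraction_protonated",
    "speciation_profile",
    "protonation_delta",
]


@dataclass(frozen=True)
class AcidBaseSpec:
    """A single ionisable group.

    Parameters
    ----------
    label : str
        Free-text name of the compound (e.g. ``"PEA"``).
    pKa : float
        Acid dissociation constant of the conjugate acid HA.  Must be a
        finite scalar; values outside (0, 14) are accepted with a warning
        since they fall outside the aqueous range this package targets.
    is_base : bool
        True for amines: the protonated species HA carries the charge and
        A⁻ maps onto the neutral free base.  False for ordinary acids,
        where HA is the neutral species.  The protonated *fraction* is
        f_HA in either convention; the flag only fixes which species is
        charged.
    """

    label: str
    pKa: float
    is_base: bool = True

    def __post_init__(self) -> None:
        if np.ndim(self.pKa) != 0:
            raise InvalidInputError(
                "single ionisable group only; polyprotic speciation "
                "(a sequence of pKa values) is not supported"
            )
        pka = float(self.pKa)
        if not math.isfinite(pka):
            raise InvalidInputError(f"pKa must be finite, got {self.pKa!r}")
        if not 0.0 < pka < 14.0:
            warnings.warn(
                f"pKa {pka} outside the supported aqueous range (0, 14)",
                stacklevel=3,
            )
        object.__setattr__(self, "pKa", pka)


@dataclass(frozen=True)
class SpeciationProfile:
    """Protonation-state fractions evaluated on an ascending pH grid."""

    pH_values: np.ndarray
    fraction_protonated: np.ndarray
    fraction_neutral: np.ndarray
    spec: AcidBaseSpec = field(repr=False, default=None)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pH": self.pH_values,
                "fraction_protonated": self.fraction_protonated,
                "fraction_neutral": self.fraction_neutral,
            }
        )


def _check_finite_scalar(name: str, x) -> float:
    try:
        val = float(x)
    except (TypeError, ValueError) as exc:
        raise InvalidInputError(f"{name} must be a scalar, got {x!r}") from exc
    if not math.isfinite(val):
        raise InvalidInputError(f"{name} must be finite, got {x!r}")
    return val


def fraction_protonated(pH, spec: AcidBaseSpec) -> float:
    """Fraction of the compound in the protonated (HA) state at ``pH``.

    Returns ``1 / (1 + 10**(pH - pKa))``, strictly inside (0, 1) for
    finite arguments.
    """
    ph = _check_finite_scalar("pH", pH)
    # expm-style guard not needed: 10**x is well behaved over any sane pH
    return 1.0 / (1.0 + 10.0 ** (ph - spec.pKa))


def speciation_profile(pH_grid, spec: AcidBaseSpec) -> SpeciationProfile:
    """Evaluate the protonated/neutral split over an ascending pH grid."""
    grid = np.asarray(pH_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise InvalidInputError("pH grid must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(grid)):
        raise InvalidInputError("pH grid contains non-finite values")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise InvalidInputError("pH grid must be sorted strictly ascending")
    f_prot = 1.0 / (1.0 + 10.0 ** (grid - spec.pKa))
    return SpeciationProfile(
        pH_values=grid,
        fraction_protonated=f_prot,
        fraction_neutral=1.0 - f_prot,
        spec=spec,
    )


def protonation_delta(pH_a, pH_b, spec: AcidBaseSpec) -> float:
    """Signed percentage-point change in protonated fraction from pH_a to pH_b.

    ``100 * (f(pH_b) - f(pH_a))``: positive when pH_b is the more acidic
    (lower) condition, e.g. the end-of-century ocean scenario versus the
    present-day one.
    """
    fa = fraction_protonated(pH_a, spec)
    fb = fraction_protonated(pH_b, spec)
    return 100.0 * (fb - fa)
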