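"""Torsion-scan analysis and Boltzmann conformer thermodynamics.

A torsion scan is a periodic energy profile E(τ) over the side-chain
dihedral τ ∈ (−180°, 180°].  Local minima of the profile are conformers:
for a 2-arylethylamine the extended *anti* well sits near |τ| ≈ 180° and
the two folded *gauche* wells near ∓60°.  Energy differences ΔE between
wells translate into relative populations through Boltzmann weights

    p_i ∝ g_i · exp(−ΔE_i / (R·T)),

with g_i the number of symmetry-equivalent wells sharing that energy.
The extended:folded population ratio 1:n uses n = (g_f/g_a)·exp(ΔE_anti/RT)
with the two mirror-image folded global-minimum wells counting twice by
default (g_f = 2, g_a = 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateScanError, InvalidInputError, MissingConformerError

__all__ = [
    "GAS_CONSTANT_KJ",
    "TorsionScan",
    "Conformer",
    "ConformerEnsemble",
    "RatioResult",
    "celsius_to_kelvin",
    "find_minima",
    "barrier_heights",
    "merge_degenerate",
    "boltzmann_populations",
    "extended_to_folded_ratio",
]

#: Molar gas constant in kJ·mol⁻¹·K⁻¹, fixed to pin numerical reproducibility.
GAS_CONSTANT_KJ = 8.31446e-3

_ENVIRONMENTS = {"gas", "implicit", "hybrid"}


def celsius_to_kelvin(temp_c: float) -> float:
    return float(temp_c) + 273.15


def _wrap_angle(tau):
    """Map angles onto the periodic domain (−180, 180]."""
    tau = np.asarray(tau, dtype=float)
    wrapped = ((tau + 180.0) % 360.0) - 180.0
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return wrapped


@dataclass(frozen=True)
class TorsionScan:
    """Periodic torsion-angle energy profile.

    Angles in degrees on (−180, 180], strictly increasing, at least 8
    points; energies in kJ/mol relative to ``reference_label``.  Inputs
    given on [0, 360) are remapped with a warning.  Periodic continuity
    between the last and first point is assumed.
    """

    tau_deg: np.ndarray
    energy: np.ndarray
    environment: str = "implicit"
    reference_label: str = ""

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau_deg, dtype=float)
        en = np.asarray(self.energy, dtype=float)
        if tau.ndim != 1 or en.shape != tau.shape:
            raise InvalidInputError("tau_deg and energy must be equal-length 1-D arrays")
        if tau.size < 8:
            raise InvalidInputError(f"torsion scan needs at least 8 points, got {tau.size}")
        if not (np.all(np.isfinite(tau)) and np.all(np.isfinite(en))):
            raise InvalidInputError("torsion scan contains non-finite values")
        if np.any(tau > 180.0) or np.any(tau <= -180.0):
            warnings.warn(
                "torsion angles outside (-180, 180]; remapping onto the periodic domain",
                stacklevel=3,
            )
            order = np.argsort(_wrap_angle(tau), kind="stable")
            tau, en = _wrap_angle(tau)[order], en[order]
        if not np.all(np.diff(tau) > 0):
            raise InvalidInputError("torsion angles must be strictly increasing")
        if self.environment not in _ENVIRONMENTS:
            raise InvalidInputError(
                f"environment must be one of {sorted(_ENVIRONMENTS)}, got {self.environment!r}"
            )
        object.__setattr__(self, "tau_deg", tau)
        object.__setattr__(self, "energy", en)

    @classmethod
    def from_csv(cls, path, environment: str | None = None) -> "TorsionScan":
        df = pd.read_csv(path)
        env = environment or (
            str(df["environment"].iloc[0]) if "environment" in df.columns else "implicit"
        )
        return cls(
            tau_deg=df["tau_deg"].to_numpy(),
            energy=df["energy_kj_mol"].to_numpy(),
            environment=env,
            reference_label=str(path),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "tau_deg": self.tau_deg,
                "energy_kj_mol": self.energy,
                "environment": self.environment,
            }
        ).to_csv(path, index=False)


def label_for_angle(tau_deg: float) -> str:
    """Conformer label by angle window: |τ|>120° anti, τ<0 gauche1, τ≥0 gauche2."""
    if abs(tau_deg) > 120.0:
        return "anti"
    return "gauche1" if tau_deg < 0.0 else "gauche2"


@dataclass(frozen=True)
class Conformer:
    """One energy-scan well: label, position, relative energy, degeneracy."""

    label: str
    tau_deg: float
    delta_E: float
    degeneracy: int = 1

    def __post_init__(self) -> None:
        if self.delta_E < 0:
            raise InvalidInputError(f"delta_E must be >= 0, got {self.delta_E}")
        if self.degeneracy < 1 or int(self.degeneracy) != self.degeneracy:
            raise InvalidInputError(f"degeneracy must be a positive integer, got {self.degeneracy}")


@dataclass(frozen=True)
class ConformerEnsemble:
    """Conformers plus a temperature; exactly one conformer at ΔE = 0."""

    conformers: tuple
    temperature_K: float = 290.15  # 17 °C, annually averaged ocean surface

    def __post_init__(self) -> None:
        conf = tuple(self.conformers)
        if not conf:
            raise InvalidInputError("ensemble must contain at least one conformer")
        if self.temperature_K <= 0:
            raise InvalidInputError(f"temperature must be positive, got {self.temperature_K} K")
        if min(c.delta_E for c in conf) != 0.0:
            raise InvalidInputError("ensemble must contain a conformer with delta_E = 0")
        object.__setattr__(self, "conformers", conf)

    @classmethod
    def from_conformers(cls, conformers, temperature_K=None, temperature_C=None):
        if temperature_C is not None:
            if temperature_K is not None:
                raise InvalidInputError("give temperature in K or °C, not both")
            temperature_K = celsius_to_kelvin(temperature_C)
        if temperature_K is None:
            temperature_K = 290.15
        return cls(conformers=tuple(conformers), temperature_K=float(temperature_K))

    @classmethod
    def from_csv(cls, path, **kw) -> "ConformerEnsemble":
        df = pd.read_csv(path)
        confs = [
            Conformer(
                label=str(r["label"]),
                tau_deg=float(r["tau_deg"]),
                delta_E=float(r["delta_E_kj_mol"]),
                degeneracy=int(r.get("degeneracy", 1)) if "degeneracy" in df.columns else 1,
            )
            for _, r in df.iterrows()
        ]
        return cls.from_conformers(confs, **kw)


def find_minima(scan: TorsionScan) -> list[Conformer]:
    """Locate all local minima of a periodic torsion scan.

    A grid point is a minimum when it lies below both periodic
    neighbours; plateaus (runs of equal energy below both flanks)
    collapse to their central point.  ΔE is assigned relative to the
    global minimum of the scan.
    """
    en = scan.energy
    n = en.size
    if np.ptp(en) == 0.0:
        raise DegenerateScanError("all scan energies equal; no conformational information")

    # Compress into runs of (numerically) equal consecutive values, cyclic.
    tol = 1e-9 * max(1.0, float(np.max(np.abs(en))))
    runs = []  # (start, length, value)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and abs(en[j + 1] - en[i]) <= tol:
            j += 1
        runs.append((i, j - i + 1, en[i]))
        i = j + 1
    # merge cyclic wrap if first and last runs are equal-valued
    if len(runs) > 1 and abs(runs[0][2] - runs[-1][2]) <= tol:
        s, ln, v = runs[-1]
        runs[0] = (s, ln + runs[0][1], v)  # start index wraps past n
        runs.pop()

    e_min = float(np.min(en))
    minima = []
    m = len(runs)
    for r in range(m):
        _, _, v = runs[r]
        v_prev = runs[r - 1][2]
        v_next = runs[(r + 1) % m][2]
        if m == 1 or (v < v_prev and v < v_next):
            start, length, _ = runs[r]
            centre = (start + (length - 1) // 2) % n
            tau = float(scan.tau_deg[centre])
            minima.append(
                Conformer(
                    label=label_for_angle(tau),
                    tau_deg=tau,
                    delta_E=float(v - e_min),
                    degeneracy=1,
                )
            )
    minima.sort(key=lambda c: c.tau_deg)
    return minima


def barrier_heights(scan: TorsionScan, minima: list[Conformer]) -> list[tuple]:
    """Barriers between adjacent minima on the periodic circle.

    For each adjacent pair the barrier is the maximum scan energy on the
    connecting arc minus the lower of the two minimum energies; always
    ≥ 0.  Returns ``[((label_i, label_j), barrier_kj_mol), ...]``; empty
    for a single minimum.
    """
    if len(minima) < 2:
        return []
    order = sorted(minima, key=lambda c: c.tau_deg)
    idx = [int(np.argmin(np.abs(scan.tau_deg - c.tau_deg))) for c in order]
    out = []
    n = scan.energy.size
    for k in range(len(order)):
        a, b = order[k], order[(k + 1) % len(order)]
        ia, ib = idx[k], idx[(k + 1) % len(order)]
        if ib > ia:
            seg = scan.energy[ia : ib + 1]
        else:  # wrap-around arc
            seg = np.concatenate([scan.energy[ia:], scan.energy[: ib + 1]])
        barrier = float(np.max(seg) - min(scan.energy[ia], scan.energy[ib]))
        out.append(((a.label, b.label), barrier))
    return out


def merge_degenerate(conformers, tol: float = 1e-6) -> list[Conformer]:
    """Merge conformers tied at the global minimum into one with summed degeneracy.

    Mirror-image wells found separately by the scan then count once with
    the correct multiplicity for population arithmetic.
    """
    confs = sorted(conformers, key=lambda c: (c.delta_E, c.tau_deg))
    if len(confs) < 2:
        return list(confs)
    merged, rest = [confs[0]], []
    for c in confs[1:]:
        if abs(c.delta_E - confs[0].delta_E) <= tol:
            merged.append(c)
        else:
            rest.append(c)
    if len(merged) == 1:
        return confs
    head = replace(merged[0], degeneracy=sum(c.degeneracy for c in merged))
    return [head] + rest


def boltzmann_populations(ensemble: ConformerEnsemble) -> np.ndarray:
    """Degeneracy-weighted Boltzmann population of each conformer.

    p_i = g_i·exp(−ΔE_i/RT) / Σ_j g_j·exp(−ΔE_j/RT); sums to 1.
    """
    rt = GAS_CONSTANT_KJ * ensemble.temperature_K
    w = np.array([c.degeneracy * math.exp(-c.delta_E / rt) for c in ensemble.conformers])
    return w / w.sum()


@dataclass(frozen=True)
class RatioResult:
    """Extended:folded population ratio, reported as 1:n."""

    n_unrounded: float
    n_rounded: int
    text: str
    mode: str = "global-minimum"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.text


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def extended_to_folded_ratio(
    ensemble: ConformerEnsemble, all_minima: bool = False
) -> RatioResult:
    """Population ratio of the extended (anti) to folded (gauche) conformation.

    Default mode uses only the degenerate folded global-minimum well
    against the anti well: n = (g_folded/g_anti)·exp(ΔE_anti/RT).  With
    ``all_minima=True`` every gauche well enters via its full Boltzmann
    population (this gives different numbers and is reported as such).
    """
    anti = [c for c in ensemble.conformers if c.label == "anti"]
    if not anti:
        raise MissingConformerError("ensemble has no anti (extended) conformer")
    folded = [c for c in ensemble.conformers if c.label.startswith("gauche")]
    folded_min = [c for c in folded if c.delta_E <= 1e-6]
    if not folded_min:
        raise MissingConformerError(
            "ensemble has no folded (gauche) conformer at the global minimum"
        )
    rt = GAS_CONSTANT_KJ * ensemble.temperature_K
    if all_minima:
        pops = boltzmann_populations(ensemble)
        p_anti = sum(p for c, p in zip(ensemble.conformers, pops) if c.label == "anti")
        p_fold = sum(
            p for c, p in zip(ensemble.conformers, pops) if c.label.startswith("gauche")
        )
        n = p_fold / p_anti
        mode = "all-minima"
    else:
        a = min(anti, key=lambda c: c.delta_E)
        g_f = sum(c.degeneracy for c in folded_min)
        n = (g_f / a.degeneracy) * math.exp(a.delta_E / rt)
        mode = "global-minimum"
    n_round = _round_half_up(n)
    return RatioResult(n_unrounded=n, n_rounded=n_round, text=f"1:{n_round}", mode=mode)


def pea_table_ensemble(state: str = "neutral", temperature_K: float = 290.15) -> ConformerEnsemble:
    """Reference conformer ensembles of 2-phenylethylamine in water.

    Relative energies and torsion angles of the hybrid-solvation minima
    (anti / gauche1 / gauche2) for the neutral amine and the ammonium
    form, with the folded global minimum carrying degeneracy 2 for its
    mirror-image well.
    """
    tables = {
        "neutral": [
            Conformer("anti", 178.1, 3.5, 1),
            Conformer("gauche1", -60.8, 1.2, 1),
            Conformer("gauche2", 61.8, 0.0, 2),
        ],
        "protonated": [
            Conformer("anti", 179.8, 4.5, 1),
            Conformer("gauche1", -59.0, 3.9, 1),
            Conformer("gauche2", 60.6, 0.0, 2),
        ],
    }
    if state not in tables:
        raise InvalidInputError(f"state must be 'neutral' or 'protonated', got {state!r}")
    return ConformerEnsemble.from_conformers(tables[state], temperature_K=temperature_K)
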