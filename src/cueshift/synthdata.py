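"""Synthetic inputs with the statistical structure each analysis stage assumes.

Every generator plants a known truth (well positions, contact geometry,
linear map, behavioural effect sizes) and echoes it in a metadata dict,
so downstream recovery tests read the truth only from that sidecar.  A
single integer seed governs all generators through independently derived
streams: adding a generator never perturbs existing fixtures, and a
fixed seed reproduces outputs byte-identically.

Default assay parameters emulate the study design this package targets:
20 animals per pH condition, four treatments (control + three cue
concentrations), 120-second trials, and planted near-zone biases that
make attraction dose-dependent and stronger at the lower pH.  Zone times
come from a low-concentration Dirichlet split (total concentration 1.2),
giving the strongly over-dispersed, often all-or-nothing occupancy that
short choice trials show in practice.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .conformers import Conformer, TorsionScan, label_for_angle
from .errors import ConfigError
from .nmr import ShieldingShiftTable
from .structures import StructureModel, combine

__all__ = [
    "ScanConfig",
    "HBondConfig",
    "AssayConfig",
    "NmrConfig",
    "GeneratorConfig",
    "gen_torsion_scan",
    "gen_pocket_complex",
    "gen_assay_trials",
    "gen_shielding_table",
]

_STREAMS = {"scan": 1, "pocket": 2, "assay": 3, "nmr": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[stream])))


@dataclass(frozen=True)
class ScanConfig:
    """Planted wells of a periodic torsion-energy curve.

    ``well_pos_deg``/``well_energy`` give the minima; ``ridge_energy[i]``
    is the barrier-top energy on the arc from well i to well i+1
    (cyclically).  All energies kJ/mol.
    """

    well_pos_deg: tuple = (-60.0, 62.0, 178.0)
    well_energy: tuple = (1.2, 0.0, 3.5)
    ridge_energy: tuple = (8.0, 16.0, 14.0)
    grid_step_deg: float = 5.0


@dataclass(frozen=True)
class HBondConfig:
    """Planted donor–H⋯acceptor contact inside a decorated pocket stub."""

    d_DA: float = 2.5
    angle_DHA_deg: float = 169.8
    d_DH: float = 1.02  # N–H covalent bond length
    n_decoys: int = 12


@dataclass(frozen=True)
class AssayConfig:
    """Choice-assay cohort: n animals × 4 treatments × 2 pH, 120 s trials.

    ``near_bias_pp`` plants the mean near-zone excess over the 33.3 %
    no-preference baseline, in percentage points per (pH, treatment).
    ``dirichlet_total`` is the total concentration of the 3-zone time
    split (1.2 → per-trial near-share SD ≈ 32 pp); ``crab_sd_pp`` is the
    SD of the per-animal random intercept.
    """

    n_crabs: int = 20
    total_s: int = 120
    dirichlet_total: float = 1.2
    crab_sd_pp: float = 5.0
    near_bias_pp: dict = field(
        default_factory=lambda: {
            7.7: {"control": 0.0, "3e-6": 5.0, "3e-5": 12.0, "3e-4": 27.0},
            8.1: {"control": 0.0, "3e-6": 2.0, "3e-5": 4.0, "3e-4": 6.0},
        }
    )


@dataclass(frozen=True)
class NmrConfig:
    """True shielding→shift linear map and measurement noise."""

    true_slope: float = -1.0
    true_intercept: float = 31.0
    noise_ppm: float = 0.05
    sigma_calc: tuple = (24.25, 24.35, 24.45, 28.6, 28.9)
    group_labels: tuple = ("H_meta", "H_ortho", "H_para", "CH2_N", "CH2_Ar")
    true_conformer: str = "gauche2"
    decoy_conformers: tuple = ("gauche1", "anti")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 20181101
    scan: ScanConfig = field(default_factory=ScanConfig)
    hbond: HBondConfig = field(default_factory=HBondConfig)
    assay: AssayConfig = field(default_factory=AssayConfig)
    nmr: NmrConfig = field(default_factory=NmrConfig)

    def metadata(self) -> dict:
        return json.loads(json.dumps(asdict(self), default=str))


# ---------------------------------------------------------------------------
# Torsion scan

def _circ_forward(a: float, b: float) -> float:
    """Forward (counter-clockwise) arc length from a to b in degrees."""
    return (b - a) % 360.0


def gen_torsion_scan(config: GeneratorConfig):
    """Periodic scan built from planted wells joined by cosine half-waves.

    The curve is C¹-smooth and attains exactly the planted well energies
    at the well positions and the planted ridge energies at the arc
    midpoints, so the construction itself is the oracle for minima and
    barrier recovery.  Returns ``(TorsionScan, [Conformer], metadata)``.
    """
    sc = config.scan
    pos = np.asarray(sc.well_pos_deg, dtype=float)
    depth = np.asarray(sc.well_energy, dtype=float)
    ridge = np.asarray(sc.ridge_energy, dtype=float)
    if len(pos) < 1 or len(pos) != len(depth):
        raise ConfigError("well positions and energies must match and be non-empty")
    if np.any(pos <= -180.0) or np.any(pos > 180.0):
        raise ConfigError("well positions must lie in (-180, 180]")
    if np.any(np.diff(pos) <= 0):
        raise ConfigError(
            "well positions must be strictly ascending so each ridge_energy[i] "
            "unambiguously spans the arc from well i to well i+1"
        )
    n_wells = len(pos)
    if n_wells >= 2:
        if len(ridge) != n_wells:
            raise ConfigError("need one ridge energy per adjacent well pair")
        gaps = [_circ_forward(pos[i], pos[(i + 1) % n_wells]) for i in range(n_wells)]
        if min(gaps) < 3.0 * sc.grid_step_deg:
            raise ConfigError("overlapping wells: separation below 3 grid steps")
        for i in range(n_wells):
            if ridge[i] <= max(depth[i], depth[(i + 1) % n_wells]):
                raise ConfigError("ridge energy must exceed both adjacent well energies")

    def energy(tau: np.ndarray) -> np.ndarray:
        if n_wells == 1:
            # single well: one full cosine bump peaking opposite the well
            arc = np.vectorize(_circ_forward)(pos[0], tau)
            top = ridge[0] if len(ridge) else depth[0] + 10.0
            return depth[0] + (top - depth[0]) * (1.0 - np.cos(np.radians(arc))) / 2.0
        out = np.empty_like(tau, dtype=float)
        for idx, t in enumerate(np.atleast_1d(tau)):
            arc = _circ_forward(pos[0], t)
            cum = 0.0
            for i in range(n_wells):
                seg = _circ_forward(pos[i], pos[(i + 1) % n_wells])
                if arc <= cum + seg or i == n_wells - 1:
                    s = (arc - cum) / seg  # in [0, 1] along this well-to-well arc
                    e0, e1, r = depth[i], depth[(i + 1) % n_wells], ridge[i]
                    if s <= 0.5:
                        out[idx] = e0 + (r - e0) * (1.0 - np.cos(2.0 * np.pi * s)) / 2.0
                    else:
                        out[idx] = e1 + (r - e1) * (1.0 - np.cos(2.0 * np.pi * (1.0 - s))) / 2.0
                    break
                cum += seg
        return out

    step = sc.grid_step_deg
    grid = np.arange(-180.0 + step, 180.0 + step / 2.0, step)
    scan = TorsionScan(tau_deg=grid, energy=energy(grid), environment="implicit")
    e_min = float(depth.min())
    planted = [
        Conformer(label=label_for_angle(p), tau_deg=float(p), delta_E=float(d - e_min))
        for p, d in zip(pos, depth)
    ]
    meta = {
        "planted_wells": [(float(p), float(d)) for p, d in zip(pos, depth)],
        "planted_ridges": [float(r) for r in ridge],
        "grid_step_deg": step,
        "seed": config.seed,
    }
    return scan, planted, meta


# ---------------------------------------------------------------------------
# Pocket + ligand with planted hydrogen bond

def gen_pocket_complex(config: GeneratorConfig):
    """Pocket stub and amine ligand realising the planted H-bond exactly.

    The acceptor oxygen sits at the origin and the donor nitrogen on the
    x-axis at the planted d(D⋯A); the bridging hydrogen is placed in the
    xy-plane so the D–H⋯A angle matches the planted value exactly.  The
    remaining atoms are random clash-free decoration (pairwise > 1 Å)
    that never interferes with the planted contact.  Returns
    ``(pocket, ligand, metadata)``; metadata carries atom indices in the
    combined pocket+ligand frame.
    """
    hb = config.hbond
    if hb.d_DA <= 1.5:
        raise ConfigError("planted d_DA must exceed 1.5 Å")
    rng = _rng(config.seed, "pocket")
    theta = np.radians(hb.angle_DHA_deg)
    r, d = hb.d_DH, hb.d_DA
    # |HA| from the triangle D-H-A with the planted angle at H
    q = r * np.cos(theta) + np.sqrt(d**2 - (r * np.sin(theta)) ** 2)
    # angle at the acceptor between A->D and A->H
    cos_alpha = np.clip((d**2 + q**2 - r**2) / (2.0 * d * q), -1.0, 1.0)
    alpha = np.arccos(cos_alpha)

    A = np.zeros(3)
    D = np.array([d, 0.0, 0.0])
    H = q * np.array([np.cos(alpha), np.sin(alpha), 0.0])

    # two remaining amine hydrogens pointing away from the acceptor
    away = []
    for phi in (np.radians(115.0), np.radians(-115.0)):
        u = np.array([np.cos(phi), 0.35, np.sin(phi)])
        away.append(D + r * u / np.linalg.norm(u))
    # short carbon tail on the donor side
    tail = [D + np.array([1.5, -0.4, 0.2]), D + np.array([2.6, 0.3, -0.3])]

    ligand = StructureModel(
        ["N", "H", "H", "H", "C", "C"],
        np.vstack([D, H, away[0], away[1], tail[0], tail[1]]),
        provenance="synthetic ligand (planted H-bond donor)",
    )

    # pocket: acceptor + random carbon decoys in a 4-8 Å shell, clash-free
    decoys, existing = [], [A, D, H, *away, *tail]
    while len(decoys) < hb.n_decoys:
        p = rng.uniform(-8.0, 8.0, size=3)
        rad = np.linalg.norm(p)
        if not 4.0 <= rad <= 8.0:
            continue
        if all(np.linalg.norm(p - e) > 1.8 for e in existing + decoys):
            decoys.append(p)
    pocket = StructureModel(
        ["O"] + ["C"] * hb.n_decoys,
        np.vstack([A] + decoys),
        provenance="synthetic pocket stub (planted H-bond acceptor)",
    )
    meta = {
        "planted_d_DA": float(hb.d_DA),
        "planted_angle_DHA_deg": float(hb.angle_DHA_deg),
        "planted_d_DH": float(hb.d_DH),
        # indices in combine(pocket, ligand)
        "acceptor_idx": 0,
        "donor_idx": 1 + hb.n_decoys,
        "hydrogen_idx": 2 + hb.n_decoys,
        "seed": config.seed,
    }
    return pocket, ligand, meta


# ---------------------------------------------------------------------------
# Assay trials

def _largest_remainder(shares: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative shares summing to 1 into integers summing to total."""
    raw = shares * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base


def gen_assay_trials(config: GeneratorConfig):
    """Simulated choice-assay cohort with planted attraction effects.

    Per trial the (near, middle, far) split of the observation window is
    drawn from a Dirichlet distribution whose mean near-zone share is
    1/3 plus the planted bias for that (pH, treatment) plus the animal's
    random intercept; times are rounded to whole seconds preserving the
    total.  Returns ``(DataFrame, metadata)``.
    """
    ac = config.assay
    if ac.n_crabs < 2:
        raise ConfigError("need at least 2 animals per pH condition")
    rng = _rng(config.seed, "assay")
    rows = []
    for ph, biases in sorted(ac.near_bias_pp.items()):
        intercepts = rng.normal(0.0, ac.crab_sd_pp, size=ac.n_crabs)
        for c in range(ac.n_crabs):
            crab = f"ph{ph}_crab{c + 1:02d}"
            for treatment, bias in biases.items():
                p_near = 1.0 / 3.0 + (bias + intercepts[c]) / 100.0
                p_near = float(np.clip(p_near, 0.02, 0.96))
                p_rest = (1.0 - p_near) / 2.0
                alpha = ac.dirichlet_total * np.array([p_near, p_rest, p_rest])
                shares = rng.dirichlet(alpha)
                t = _largest_remainder(shares, ac.total_s)
                rows.append(
                    {
                        "crab_id": crab,
                        "ph": ph,
                        "treatment": treatment,
                        "t_near_s": int(t[0]),
                        "t_neutral_s": int(t[1]),
                        "t_far_s": int(t[2]),
                        "total_s": ac.total_s,
                    }
                )
    df = pd.DataFrame(rows)
    meta = {
        "planted_near_bias_pp": {str(k): dict(v) for k, v in ac.near_bias_pp.items()},
        "n_crabs": ac.n_crabs,
        "total_s": ac.total_s,
        "dirichlet_total": ac.dirichlet_total,
        "crab_sd_pp": ac.crab_sd_pp,
        "seed": config.seed,
    }
    return df, meta


# ---------------------------------------------------------------------------
# Shielding/shift tables

def gen_shielding_table(config: GeneratorConfig):
    """Shielding/shift tables: one true conformer plus shuffled decoys.

    Experimental shifts are generated once from the true conformer's
    shieldings through the planted linear map plus Gaussian noise; decoy
    conformers pair the same shifts with a permutation of the shieldings
    (re-drawn until it differs from the identity).  Returns
    ``(list[ShieldingShiftTable], metadata)``.
    """
    nc = config.nmr
    rng = _rng(config.seed, "nmr")
    sigma = np.asarray(nc.sigma_calc, dtype=float)
    if len(sigma) < 3 or len(sigma) != len(nc.group_labels):
        raise ConfigError("need >= 3 shielding values, one per group label")
    delta = nc.true_slope * sigma + nc.true_intercept + rng.normal(0.0, nc.noise_ppm, len(sigma))

    def table(label: str, sig: np.ndarray) -> ShieldingShiftTable:
        return ShieldingShiftTable(
            conformer_label=label,
            records=pd.DataFrame(
                {"proton_group": list(nc.group_labels), "sigma_calc": sig, "delta_exp": delta}
            ),
        )

    tables = [table(nc.true_conformer, sigma)]
    for decoy in nc.decoy_conformers:
        perm = rng.permutation(len(sigma))
        while np.array_equal(perm, np.arange(len(sigma))):
            perm = rng.permutation(len(sigma))
        tables.append(table(decoy, sigma[perm]))
    meta = {
        "true_conformer": nc.true_conformer,
        "true_slope": nc.true_slope,
        "true_intercept": nc.true_intercept,
        "noise_ppm": nc.noise_ppm,
        "seed": config.seed,
    }
    return tables, meta
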