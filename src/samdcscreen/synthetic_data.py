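"""Ground-truth-labeled synthetic inputs for every pipeline stage.

Two generator families live here:

* **Docking pose sets** (:func:`make_pose_set`) — multi-pose results whose
  score distribution and spatial cluster structure are *constructed* to pass
  or fail each triage rule (Score / Cluster / Score Density) exactly as
  requested, so the filter cascade can be checked against known truth.

* **Coupled-assay traces** (:func:`simulate_assay`,
  :func:`simulate_standard`, :func:`make_screening_plate`) — A340 progress
  curves from a forward kinetic model of the AdoMetDC / PEPC-MDH assay:
  Michaelis-Menten CO2 production coupled 1:1 to NADH oxidation, with
  competitive inhibition (apparent Km scaling), an optional putrescine
  activity multiplier, linear exogenous-CO2 background drift, per-compound
  constant absorbance offsets, an impaired-coupling factor for
  PEPC/MDH-poisoning compounds, and additive Gaussian read noise.

The PEPC + MDH coupling steps are treated as instantaneous — the assay's own
premise is that A340 tracks CO2 — so no intermediate oxaloacetate pool is
modeled.  Competitive inhibition is a simulator convention, not a mechanistic
claim about any particular compound.

All randomness flows through a single integer seed per generator call; the
same seed reproduces outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assay_kinetics import (
    DEFAULT_EPSILON_L,
    AbsorbanceTrace,
    AssayCondition,
)
from .pose_triage import DockingResult, FilterThresholds, LigandPose

__all__ = [
    "PoseSetSpec",
    "AssaySimConfig",
    "SimulatedProgress",
    "make_pose_set",
    "simulate_progress",
    "simulate_assay",
    "simulate_standard",
    "make_screening_plate",
]

#: Working NADH in the final 200 uL mix: 0.45 mM in reagent R2, of which
#: 47 uL enter the 200 uL reaction -> 450 * 47/200 = 105.75 uM.
DEFAULT_NADH0_UM = 450.0 * 47.0 / 200.0

#: Published catalytic constants used as simulator defaults:
#: Km = 3.1 uM and kcat/Km = 2.0e4 M^-1 s^-1  =>  kcat = 0.062 s^-1.
DEFAULT_KM_UM = 3.1
DEFAULT_KCAT_S = 2.0e4 * DEFAULT_KM_UM * 1e-6


@dataclasses.dataclass(frozen=True)
class PoseSetSpec:
    """Requested truth labels for one synthetic docking result."""

    molecule_id: str
    n_poses: int
    n_heavy_atoms: int
    target_score_rule: bool
    target_cluster_rule: bool
    target_density_rule: bool
    seed: int

    def __post_init__(self) -> None:
        if self.n_poses < 1 or self.n_heavy_atoms < 1:
            raise ValueError("n_poses and n_heavy_atoms must be >= 1")


@dataclasses.dataclass(frozen=True)
class AssaySimConfig:
    """Forward-model parameters for one simulated well.

    Concentrations in uM unless noted; times in minutes; kcat in 1/s.
    """

    Km: float = DEFAULT_KM_UM
    kcat: float = DEFAULT_KCAT_S
    enzyme_uM: float = 1.0
    adomet_uM: float = 1000.0
    inhibitor_Ki_uM: float | None = None
    inhibitor_uM: float = 0.0
    putrescine_factor: float = 1.0  # ~2 models the putrescine stimulation
    nadh0_uM: float = DEFAULT_NADH0_UM
    epsilon_l: float = DEFAULT_EPSILON_L  # AU per uM NADH
    drift_uM_per_min: float = 0.5  # exogenous CO2 background
    compound_a340_offset: float = 0.0  # AU, constant chromophore background
    coupling_factor: float = 1.0  # <1 models an impaired PEPC/MDH readout
    noise_sd: float = 0.0  # AU, additive Gaussian read noise
    dt: float = 0.1
    duration: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("Km", "kcat", "enzyme_uM", "adomet_uM", "inhibitor_uM", "nadh0_uM"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        if self.epsilon_l <= 0:
            raise ValueError("epsilon_l must be positive")
        if self.putrescine_factor < 1.0:
            raise ValueError("putrescine_factor must be >= 1")
        if not (0.0 < self.coupling_factor <= 1.0):
            raise ValueError("coupling_factor must lie in (0, 1]")


@dataclasses.dataclass
class SimulatedProgress:
    """Full state trajectory of one simulated well (noise-free internals)."""

    times: np.ndarray  # minutes
    substrate_uM: np.ndarray
    nadh_uM: np.ndarray
    a340: np.ndarray  # with noise/offset applied
    nadh_exhausted: bool


# ---------------------------------------------------------------------------
# docking pose sets
# ---------------------------------------------------------------------------

def _score_interval(spec: PoseSetSpec, thresholds: FilterThresholds) -> tuple[float, float]:
    # Feasible open/closed interval for the best score, honoring the strict
    # "< cut" semantics of the Score and Score Density rules.
    lo, hi = -np.inf, np.inf
    thr_d = thresholds.density_cut * spec.n_heavy_atoms
    for cut, want_pass in ((thresholds.score_cut, spec.target_score_rule),
                           (thr_d, spec.target_density_rule)):
        if want_pass:
            hi = min(hi, cut)
        else:
            lo = max(lo, cut)
    if lo >= hi:
        raise ValueError(
            f"{spec.molecule_id}: score target {spec.target_score_rule} with density "
            f"target {spec.target_density_rule} is unrealizable at "
            f"{spec.n_heavy_atoms} heavy atoms (cuts {thresholds.score_cut} vs {thr_d:.2f})"
        )
    return lo, hi


def make_pose_set(
    spec: PoseSetSpec, thresholds: FilterThresholds = FilterThresholds()
) -> tuple[DockingResult, dict[str, bool]]:
    """Construct a docking result whose rule outcomes are known by design.

    The best score is placed inside the interval jointly compatible with the
    requested Score and Score Density outcomes (a margin keeps it away from
    the strict-inequality boundaries).  Coordinates form one tight cluster
    around the best pose (RMSD well under the cluster cut) plus outliers
    displaced rigidly by at least twice the cut, with the within-cut count
    chosen to land on the requested side of the cluster fraction.

    Raises ``ValueError`` for unrealizable specs (e.g. a failing Score Rule
    combined with a passing Score Density Rule needs few enough heavy atoms
    that the per-atom cut is the weaker one; a failing Cluster Rule needs at
    least 2 poses).  Returns the result and its ground-truth label dict.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_poses

    lo, hi = _score_interval(spec, thresholds)
    margin = 0.05
    lo_f = lo + margin if np.isfinite(lo) else hi - 3.0
    hi_f = hi - margin if np.isfinite(hi) else lo + 3.0
    if lo_f >= hi_f:
        raise ValueError(f"{spec.molecule_id}: feasible score interval too narrow")
    best = float(rng.uniform(lo_f, hi_f))
    scores = best + np.concatenate([[0.0], np.sort(rng.uniform(0.05, 3.0, n - 1))])

    # within-cut membership (reference pose always counts as within)
    frac, cut = thresholds.cluster_fraction, thresholds.cluster_rmsd_cut
    k_min_pass = int(np.ceil(frac * n - 1e-9))
    if spec.target_cluster_rule:
        k_within = int(rng.integers(k_min_pass, n + 1))
    else:
        if k_min_pass - 1 < 1:
            raise ValueError(
                f"{spec.molecule_id}: cluster failure unrealizable with {n} pose(s)"
            )
        k_within = int(rng.integers(1, k_min_pass))

    ref = rng.normal(0.0, 2.0, size=(spec.n_heavy_atoms, 3))
    coords = [ref]
    members = np.zeros(n, dtype=bool)
    members[0] = True
    others = rng.permutation(np.arange(1, n))
    members[others[: k_within - 1]] = True
    for i in range(1, n):
        if members[i]:
            disp = rng.normal(size=ref.shape)
            disp *= rng.uniform(0.2, 0.8) * cut / np.sqrt(np.mean(np.sum(disp**2, axis=1)))
            coords.append(ref + disp)
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            coords.append(ref + direction * (2.0 * cut + rng.uniform(0.5, 3.0)))
    poses = [
        LigandPose(pose_index=i + 1, score=float(s), coords=c)
        for i, (s, c) in enumerate(zip(scores, coords))
    ]
    labels = {
        "score_rule": spec.target_score_rule,
        "cluster_rule": spec.target_cluster_rule,
        "density_rule": spec.target_density_rule,
    }
    return DockingResult(spec.molecule_id, spec.n_heavy_atoms, poses), labels


# ---------------------------------------------------------------------------
# coupled-assay simulator
# ---------------------------------------------------------------------------

def _apparent_km(config: AssaySimConfig) -> float:
    if config.inhibitor_Ki_uM is None or config.inhibitor_uM == 0:
        return config.Km
    return config.Km * (1.0 + config.inhibitor_uM / config.inhibitor_Ki_uM)


def simulate_progress(config: AssaySimConfig) -> SimulatedProgress:
    """Integrate the forward model and return the full state trajectory.

    Substrate decays by the Michaelis-Menten law with apparent Km under
    competitive inhibition, integrated by fixed-step classical 4th-order
    Runge-Kutta at ``dt``.  Cumulative product P(t) = S(0) - S(t) and the
    linear drift are drawn from the NADH pool through the coupling factor:
    ``NADH(t) = max(0, nadh0 - coupling*(P(t) + drift*t))``.  The absorbance
    is ``epsilon_l * NADH + offset + N(0, noise_sd)``.
    """
    km_app = _apparent_km(config)
    vmax = config.kcat * 60.0 * config.putrescine_factor * config.enzyme_uM  # uM/min

    def dSdt(S: float) -> float:
        return -vmax * S / (km_app + S) if S > 0 else 0.0

    n_steps = int(round(config.duration / config.dt))
    times = np.arange(n_steps + 1) * config.dt
    S = np.empty(n_steps + 1)
    S[0] = config.adomet_uM
    h = config.dt
    for i in range(n_steps):
        s = S[i]
        k1 = dSdt(s)
        k2 = dSdt(s + 0.5 * h * k1)
        k3 = dSdt(s + 0.5 * h * k2)
        k4 = dSdt(s + h * k3)
        S[i + 1] = max(0.0, s + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4))
    produced = S[0] - S
    nadh_raw = config.nadh0_uM - config.coupling_factor * (
        produced + config.drift_uM_per_min * times
    )
    nadh = np.maximum(0.0, nadh_raw)
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, config.noise_sd, size=nadh.shape) if config.noise_sd > 0 else 0.0
    a340 = config.epsilon_l * nadh + config.compound_a340_offset + noise
    return SimulatedProgress(
        times=times,
        substrate_uM=S,
        nadh_uM=nadh,
        a340=a340,
        nadh_exhausted=bool(np.any(nadh_raw < 0)),
    )


def simulate_assay(config: AssaySimConfig, condition: AssayCondition | None = None) -> AbsorbanceTrace:
    """Simulate one enzyme well and return its absorbance trace.

    The trace's metadata records whether the NADH pool was exhausted before
    the end of the read (the trace is still returned; its tail is flat).
    """
    sim = simulate_progress(config)
    cond = condition or AssayCondition(
        adomet_uM=config.adomet_uM,
        enzyme_uM=config.enzyme_uM,
        inhibitor_uM=config.inhibitor_uM,
    )
    return AbsorbanceTrace(
        times=sim.times,
        a340=sim.a340,
        condition=cond,
        metadata={"nadh_exhausted": sim.nadh_exhausted},
    )


def simulate_standard(
    standard_uM: float, config: AssaySimConfig, condition: AssayCondition | None = None
) -> AbsorbanceTrace:
    """Simulate a NaHCO3 calibration-standard well (no enzyme).

    The standard's CO2 is consumed instantaneously just after t = 0, so the
    first reading still shows the full NADH pool; thereafter only the linear
    drift acts.  NADH is floored at zero when the standard exceeds the pool.
    """
    if standard_uM < 0:
        raise ValueError("standard_uM must be non-negative")
    n_steps = int(round(config.duration / config.dt))
    times = np.arange(n_steps + 1) * config.dt
    consumed = config.coupling_factor * (
        standard_uM + config.drift_uM_per_min * times
    )
    consumed[0] = 0.0  # pre-consumption read at t = 0
    nadh = np.maximum(0.0, config.nadh0_uM - consumed)
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, config.noise_sd, size=nadh.shape) if config.noise_sd > 0 else 0.0
    a340 = config.epsilon_l * nadh + config.compound_a340_offset + noise
    cond = condition or AssayCondition(is_standard=True, standard_uM=standard_uM)
    return AbsorbanceTrace(times=times, a340=a340, condition=cond)


# ---------------------------------------------------------------------------
# screening plate
# ---------------------------------------------------------------------------

def _ki_for_inhibition(
    target_fraction: float, concentration_uM: float, km: float, s_uM: float
) -> float:
    # Competitive inhibition: rate ratio (Km+S)/(Km_app+S) = 1 - f
    # => Km_app = (Km+S)/(1-f) - S;  Ki = I*Km/(Km_app - Km).
    km_app = (km + s_uM) / (1.0 - target_fraction) - s_uM
    return concentration_uM * km / (km_app - km)


def make_screening_plate(
    n_compounds: int = 26,
    n_true_inhibitors: int = 1,
    n_coupling_poisons: int = 1,
    n_chromophores: int = 1,
    seed: int = 0,
    base_config: AssaySimConfig | None = None,
    screen_uM: float = 100.0,
    standard_uM: float = 50.0,
    target_inhibition: float = 0.5,
    poison_coupling: float = 0.8,
    chromophore_offset: float = 0.15,
) -> tuple[list[AbsorbanceTrace], list[AbsorbanceTrace], pd.DataFrame]:
    """Build a full single-concentration screening plate with known truth.

    Emits enzyme wells (controls + one per compound at ``screen_uM``),
    no-enzyme blanks, calibration-standard wells, and per-compound
    background-check wells (compound alone, compound + standard), matching
    the published screen layout of 26 purchased candidates read against a
    compound-free control.  Three artifact classes are planted at random
    positions:

    * true inhibitors — Ki chosen so the screen concentration yields
      ``target_inhibition`` (~50 % by default, the positive-control level);
    * coupling poisons — the PEPC/MDH readout responds at only
      ``poison_coupling`` of its normal amplitude (CO2 under-reported);
    * chromophores — a constant ``chromophore_offset`` AU at 340 nm.

    Returns ``(traces, background_traces, truth_table)`` where the truth
    table labels each compound's class and planted Ki.
    """
    if n_true_inhibitors + n_coupling_poisons + n_chromophores > n_compounds:
        raise ValueError("artifact classes exceed the number of compounds")
    base = base_config or AssaySimConfig(noise_sd=0.002)
    rng = np.random.default_rng(seed)

    classes = (
        ["inhibitor"] * n_true_inhibitors
        + ["coupling_poison"] * n_coupling_poisons
        + ["chromophore"] * n_chromophores
        + ["clean"] * (n_compounds - n_true_inhibitors - n_coupling_poisons - n_chromophores)
    )
    rng.shuffle(classes)
    ki = _ki_for_inhibition(target_inhibition, screen_uM, base.Km, base.adomet_uM)

    def cfg(**kw) -> AssaySimConfig:
        return dataclasses.replace(base, seed=int(rng.integers(2**31)), **kw)

    traces: list[AbsorbanceTrace] = []
    background: list[AbsorbanceTrace] = []
    truth_rows = []

    for i in range(3):  # blank replicates: no enzyme, no compound
        c = cfg(enzyme_uM=0.0, adomet_uM=0.0)
        traces.append(
            simulate_assay(c, AssayCondition(well=f"BLK{i+1}", is_blank=True))
        )
    for i in range(3):  # compound-free standards
        c = cfg(enzyme_uM=0.0, adomet_uM=0.0)
        background.append(
            simulate_standard(
                standard_uM, c,
                AssayCondition(well=f"STD{i+1}", is_standard=True, standard_uM=standard_uM),
            )
        )
    for i in range(2):  # positive controls: enzyme, no compound
        c = cfg()
        traces.append(
            simulate_assay(
                c, AssayCondition(well=f"CTL{i+1}", adomet_uM=c.adomet_uM, enzyme_uM=c.enzyme_uM)
            )
        )

    for i, cls in enumerate(classes):
        cid = f"CMP-{i+1:03d}"
        kw: dict = {}
        if cls == "inhibitor":
            kw = {"inhibitor_Ki_uM": ki, "inhibitor_uM": screen_uM}
        elif cls == "coupling_poison":
            kw = {"coupling_factor": poison_coupling}
        elif cls == "chromophore":
            kw = {"compound_a340_offset": chromophore_offset}

        c = cfg(**kw)
        traces.append(
            simulate_assay(
                c,
                AssayCondition(
                    well=f"S{i+1:02d}", adomet_uM=c.adomet_uM, enzyme_uM=c.enzyme_uM,
                    inhibitor_id=cid, inhibitor_uM=screen_uM,
                ),
            )
        )
        # compound alone, no enzyme: absorbance-background check
        cb = cfg(enzyme_uM=0.0, adomet_uM=0.0, **kw)
        background.append(
            simulate_assay(
                cb,
                AssayCondition(well=f"B{i+1:02d}", inhibitor_id=cid, inhibitor_uM=screen_uM),
            )
        )
        # compound + standard, no enzyme: coupling-system check
        cs = cfg(enzyme_uM=0.0, adomet_uM=0.0, **kw)
        background.append(
            simulate_standard(
                standard_uM, cs,
                AssayCondition(
                    well=f"P{i+1:02d}", inhibitor_id=cid, inhibitor_uM=screen_uM,
                    is_standard=True, standard_uM=standard_uM,
                ),
            )
        )
        truth_rows.append(
            {
                "compound_id": cid,
                "class": cls,
                "ki_uM": ki if cls == "inhibitor" else np.nan,
                "expected_flag": {
                    "coupling_poison": "coupling_inhibition",
                    "chromophore": "absorbance_interference",
                }.get(cls, "clean"),
            }
        )
    truth = pd.DataFrame(truth_rows)
    return traces, background, truth


def write_truth_sidecar(truth: pd.DataFrame, path: str | Path) -> None:
    """Write a generator truth table as a JSON sidecar file."""
    Path(path).write_text(json.dumps(truth.to_dict(orient="records"), indent=1))
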