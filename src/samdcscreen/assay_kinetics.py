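"""Analytics for the AdoMetDC / PEPC-MDH coupled spectrophotometric assay.

AdoMetDC decarboxylates S-adenosylmethionine (AdoMet), releasing CO2.  In
mildly basic buffer the CO2 equilibrates to bicarbonate, which PEP
carboxylase condenses with phosphoenolpyruvate; malate dehydrogenase then
reduces the product while oxidizing NADH to NAD+.  NADH absorbs at 340 nm
and NAD+ does not, so enzyme activity appears as a decline in A340 with
1:1 stoichiometry between CO2 released and NADH consumed.

The primary signal is the absorbance drop over a fixed window,
``dAU = A(t0) - A(t1)`` with a default window of 0 to 5 minutes.  This
module extracts dAU values, corrects them against no-enzyme blanks,
converts them to CO2 concentrations via NaHCO3 calibration standards,
estimates initial rates and Michaelis-Menten parameters, computes
inhibition percentages and screening tables with background-artifact
flags, and summarizes replicate variability for assay validation
(CV at 0 %, 50 % and 80 % activity).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AssayCondition",
    "AbsorbanceTrace",
    "DeltaAU",
    "KineticFit",
    "BackgroundFlag",
    "InhibitionResult",
    "LevelStats",
    "ValidationStats",
    "Co2Estimate",
    "delta_au",
    "background_correct",
    "calibrate_co2",
    "linearity_check",
    "initial_rate",
    "fit_michaelis_menten",
    "inhibition_percentage",
    "screen_plate",
    "validation_stats",
    "fit_ic50",
    "read_plate",
    "write_plate",
]

#: Combined NADH molar absorptivity x path length, AU per uM NADH.
#: 6220 M^-1 cm^-1 and a ~0.56 cm liquid depth for 200 uL in a 96-well.
DEFAULT_EPSILON_L = 0.00348


@dataclasses.dataclass(frozen=True)
class AssayCondition:
    """What is in one well: substrate, enzyme, compound, controls."""

    well: str = ""
    adomet_uM: float = 0.0
    enzyme_uM: float = 0.0
    inhibitor_id: str | None = None
    inhibitor_uM: float = 0.0
    putrescine_mM: float = 0.0
    is_blank: bool = False
    is_standard: bool = False
    standard_uM: float = 0.0

    def __post_init__(self) -> None:
        for f in ("adomet_uM", "enzyme_uM", "inhibitor_uM", "putrescine_mM", "standard_uM"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if (self.is_blank or self.is_standard) and self.enzyme_uM > 0:
            raise ValueError("blank/standard wells must not contain enzyme")


@dataclasses.dataclass
class AbsorbanceTrace:
    """A340 readings over time for one well."""

    times: np.ndarray  # minutes, strictly increasing from 0
    a340: np.ndarray  # absorbance units
    condition: AssayCondition = AssayCondition()
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.a340, dtype=float)
        if t.shape != a.shape or t.ndim != 1 or len(t) == 0:
            raise ValueError("times and a340 must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("a340 must be finite")
        self.times, self.a340 = t, a

    def at(self, t: float) -> float:
        """A340 at time ``t`` (minutes), linearly interpolated."""
        if t < self.times[0] or t > self.times[-1]:
            raise ValueError(f"time {t} outside recorded range [{self.times[0]}, {self.times[-1]}]")
        return float(np.interp(t, self.times, self.a340))


@dataclasses.dataclass(frozen=True)
class DeltaAU:
    """Absorbance drop A(t0) - A(t1) over a window (positive = consumption)."""

    value: float
    t0: float = 0.0
    t1: float = 5.0
    background_corrected: bool = False

    def __post_init__(self) -> None:
        if self.t1 <= self.t0:
            raise ValueError("t1 must exceed t0")


class BackgroundFlag(str, enum.Enum):
    CLEAN = "clean"
    ABSORBANCE_INTERFERENCE = "absorbance_interference"
    COUPLING_INHIBITION = "coupling_inhibition"


@dataclasses.dataclass
class InhibitionResult:
    compound_id: str
    concentration_uM: float
    inhibition_pct: float
    background_flag: BackgroundFlag = BackgroundFlag.CLEAN


@dataclasses.dataclass
class KineticFit:
    """Michaelis-Menten parameter estimates with fit uncertainties.

    ``kcat`` assumes fully active enzyme at the stated concentration.
    """

    Km: float  # uM
    Vmax: float  # uM / min
    kcat: float  # 1 / s
    kcat_over_Km: float  # M^-1 s^-1
    se_Km: float
    se_Vmax: float
    r_squared: float
    enzyme_uM: float
    km_identifiable: bool = True


@dataclasses.dataclass
class LevelStats:
    mean: float
    sd: float
    cv_pct: float  # NaN when the mean is zero (CV undefined)
    sem: float
    n: int


@dataclasses.dataclass
class ValidationStats:
    """Replicate variability per activity level (0 / 50 / 80 % activity)."""

    levels: dict[float, LevelStats]

    def cv(self, level: float) -> float:
        return self.levels[level].cv_pct

    @property
    def cv_min(self) -> float:
        return self.cv(0.0)

    @property
    def cv_mid(self) -> float:
        return self.cv(50.0)

    @property
    def cv_max(self) -> float:
        return self.cv(80.0)


@dataclasses.dataclass(frozen=True)
class Co2Estimate:
    """CO2 concentration interpolated from the NaHCO3 calibration line."""

    value_uM: float
    extrapolated: bool
    slope: float  # AU per uM
    intercept: float  # AU

    def __float__(self) -> float:
        return self.value_uM


def delta_au(trace: AbsorbanceTrace, t0: float = 0.0, t1: float = 5.0) -> DeltaAU:
    """Absorbance drop ``A(t0) - A(t1)``, interpolating between samples."""
    return DeltaAU(value=trace.at(t0) - trace.at(t1), t0=t0, t1=t1)


def background_correct(sample: DeltaAU, blank: DeltaAU) -> DeltaAU:
    """Subtract a no-enzyme blank's dAU measured over the same window."""
    if (sample.t0, sample.t1) != (blank.t0, blank.t1):
        raise ValueError(
            f"window mismatch: sample ({sample.t0}, {sample.t1}) vs blank ({blank.t0}, {blank.t1})"
        )
    return DeltaAU(
        value=sample.value - blank.value,
        t0=sample.t0,
        t1=sample.t1,
        background_corrected=True,
    )


def calibrate_co2(
    delta: DeltaAU, standards: Sequence[tuple[float, DeltaAU]]
) -> Co2Estimate:
    """Convert a dAU to uM CO2 via a fitted NaHCO3 standard line.

    An ordinary least-squares line (intercept fitted) through the standards'
    (concentration, dAU) pairs is inverted at the sample's dAU.  Samples
    outside the standards' concentration span are flagged as extrapolated.
    """
    if len(standards) < 2:
        raise ValueError("at least 2 calibration standards required")
    conc = np.array([c for c, _ in standards], dtype=float)
    dau = np.array([d.value for _, d in standards], dtype=float)
    if np.ptp(conc) == 0:
        raise ValueError("calibration standards all at the same concentration")
    fit = stats.linregress(conc, dau)
    value = (delta.value - fit.intercept) / fit.slope
    return Co2Estimate(
        value_uM=float(value),
        extrapolated=not (conc.min() <= value <= conc.max()),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def linearity_check(
    pairs: Sequence[tuple[float, DeltaAU | float]]
) -> tuple[float, float, float]:
    """OLS fit of dAU against concentration: ``(slope, intercept, r_squared)``.

    Used to delimit the assay's linear detection range (product below
    ~250 uM total CO2 in the published characterization).
    """
    if len(pairs) < 3:
        raise ValueError("at least 3 points required")
    x = np.array([c for c, _ in pairs], dtype=float)
    y = np.array([d.value if isinstance(d, DeltaAU) else float(d) for _, d in pairs])
    if np.ptp(x) == 0:
        raise ValueError("degenerate x-variance")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def initial_rate(
    trace: AbsorbanceTrace, window: float = 1.0, epsilon_l: float = DEFAULT_EPSILON_L
) -> float:
    """Initial CO2 production rate in uM/min from the early A340 decline.

    An OLS slope of A340 against time over ``[0, window]`` minutes is
    converted through ``epsilon_l`` (AU per uM NADH).  A short window limits
    the low-substrate bias from depletion during the read.
    """
    mask = trace.times <= window + 1e-12
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 samples within the first {window} min")
    fit = stats.linregress(trace.times[mask], trace.a340[mask])
    return float(-fit.slope / epsilon_l)


def _mm(S: np.ndarray, Vmax: float, Km: float) -> np.ndarray:
    return Vmax * S / (Km + S)


def fit_michaelis_menten(
    points: Sequence[tuple[float, float]], enzyme_uM: float = 1.0
) -> KineticFit:
    """Nonlinear least-squares fit of ``v = Vmax S / (Km + S)``.

    Parameters are constrained positive.  ``kcat`` (s^-1) and ``kcat/Km``
    (M^-1 s^-1) are derived from ``Vmax`` using the enzyme concentration,
    assuming fully active enzyme.  When the data carry no curvature (all
    points far above Km) the Km estimate collapses against its lower bound
    and the fit is flagged ``km_identifiable=False``.
    """
    S = np.array([s for s, _ in points], dtype=float)
    v = np.array([r for _, r in points], dtype=float)
    if len(np.unique(S)) < 4:
        raise ValueError("at least 4 distinct substrate concentrations required")
    if enzyme_uM <= 0:
        raise ValueError("enzyme concentration must be positive")
    vmax0 = max(v.max(), 1e-9)
    half = vmax0 / 2.0
    above = S[v >= half]
    km0 = float(above.min()) if len(above) and above.min() > 0 else max(S[S > 0].min(), 1.0)
    try:
        popt, pcov = optimize.curve_fit(
            _mm,
            S,
            v,
            p0=[vmax0, km0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    Vmax, Km = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov))
    se_Vmax, se_Km = float(perr[0]), float(perr[1])
    resid = v - _mm(S, *popt)
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    kcat = Vmax / enzyme_uM / 60.0  # uM/min / uM -> 1/min -> 1/s
    # Km far below the smallest measured [S] means the curvature was never
    # sampled: the estimate is an artifact of near-flat data
    s_min = float(S[S > 0].min()) if np.any(S > 0) else 0.0
    identifiable = (
        Km > 1e-6
        and Km >= 0.1 * s_min
        and math.isfinite(se_Km)
        and se_Km < 10.0 * max(Km, 1e-12)
    )
    return KineticFit(
        Km=Km,
        Vmax=Vmax,
        kcat=kcat,
        kcat_over_Km=kcat / (Km * 1e-6),
        se_Km=se_Km,
        se_Vmax=se_Vmax,
        r_squared=r2,
        enzyme_uM=enzyme_uM,
        km_identifiable=identifiable,
    )


def inhibition_percentage(with_inh: DeltaAU, without_inh: DeltaAU) -> float:
    """Percent inhibition, ``(1 - dAU_with / dAU_without) x 100``.

    Both dAU values should be background-corrected.  Values below 0
    (apparent activation) or above 100 (over-suppression plus noise) are
    passed through unclamped.
    """
    if without_inh.value <= 0:
        raise ValueError("uninhibited dAU must be positive")
    return (1.0 - with_inh.value / without_inh.value) * 100.0


def validation_stats(replicates: Mapping[float, Sequence[float]]) -> ValidationStats:
    """Replicate summary per activity level: mean, sample SD (n-1),
    CV = 100 SD / mean, SEM = SD / sqrt(n).

    A zero mean leaves the CV undefined; it is reported as NaN.
    """
    levels = {}
    for level, values in replicates.items():
        x = np.asarray(list(values), dtype=float)
        if len(x) < 2:
            raise ValueError(f"level {level}: at least 2 replicates required")
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        cv = 100.0 * sd / mean if mean != 0 else float("nan")
        levels[float(level)] = LevelStats(
            mean=mean, sd=sd, cv_pct=cv, sem=sd / math.sqrt(len(x)), n=len(x)
        )
    return ValidationStats(levels=levels)


# ---------------------------------------------------------------------------
# plate-level screening
# ---------------------------------------------------------------------------

#: Minimum meaningful absorbance deviation; guards the 3-sigma blank rule
#: against tiny blank SDs so that read noise alone cannot trip a flag.
ABS_TOLERANCE_FLOOR = 0.01


def _mean_level(trace: AbsorbanceTrace, t0: float, t1: float) -> float:
    mask = (trace.times >= t0) & (trace.times <= t1)
    return float(trace.a340[mask].mean())


def screen_plate(
    traces: Sequence[AbsorbanceTrace],
    background_traces: Sequence[AbsorbanceTrace] = (),
    t0: float = 0.0,
    t1: float = 5.0,
) -> list[InhibitionResult]:
    """Score a single-concentration screening plate.

    ``traces`` holds the enzyme wells (a no-compound positive control plus
    one well per compound) and the no-enzyme blanks.  ``background_traces``
    holds the per-compound artifact-check wells: compound without enzyme
    (absorbance background) and compound plus NaHCO3 standard without enzyme
    (coupling-system check), along with compound-free standard wells.

    Per compound the inhibition percentage is computed against the control
    after blank correction.  Background flags:

    * ``absorbance_interference`` — the compound's no-enzyme trace deviates
      in mean A340 level from the blanks by more than the tolerance (a
      compound absorbing at 340 nm shifts the whole trace; the dAU window
      would cancel a constant offset, so the level is compared).
    * ``coupling_inhibition`` — the compound + standard well under-reports
      the standard's dAU by more than the tolerance (the compound poisons
      the PEPC/MDH readout itself).  This flag takes precedence.

    The tolerance is ``max(3 x SD of blank-replicate dAU, 0.01 AU)``.
    Results are sorted by inhibition percentage, descending.
    """
    blanks = [tr for tr in traces if tr.condition.is_blank and tr.condition.inhibitor_id is None]
    controls = [
        tr
        for tr in traces
        if tr.condition.enzyme_uM > 0 and tr.condition.inhibitor_id is None
    ]
    compounds = [tr for tr in traces if tr.condition.enzyme_uM > 0 and tr.condition.inhibitor_id]
    if not controls:
        raise ValueError("no positive-control (enzyme, no compound) well found")
    if not blanks:
        raise ValueError("no blank (no enzyme, no compound) well found")

    blank_daus = [delta_au(tr, t0, t1).value for tr in blanks]
    blank_dau = DeltaAU(float(np.mean(blank_daus)), t0, t1)
    blank_level = float(np.mean([_mean_level(tr, t0, t1) for tr in blanks]))
    sd_blank = float(np.std(blank_daus, ddof=1)) if len(blank_daus) > 1 else 0.0
    tol = max(3.0 * sd_blank, ABS_TOLERANCE_FLOOR)

    ctrl = background_correct(
        DeltaAU(float(np.mean([delta_au(tr, t0, t1).value for tr in controls])), t0, t1),
        blank_dau,
    )

    # artifact-check wells, keyed by compound
    bg_plain: dict[str, AbsorbanceTrace] = {}
    bg_standard: dict[str, AbsorbanceTrace] = {}
    std_refs: list[AbsorbanceTrace] = []
    for tr in background_traces:
        cid = tr.condition.inhibitor_id
        if tr.condition.is_standard:
            if cid:
                bg_standard[cid] = tr
            else:
                std_refs.append(tr)
        elif cid:
            bg_plain[cid] = tr
    std_dau = (
        float(np.mean([delta_au(tr, t0, t1).value for tr in std_refs])) if std_refs else None
    )

    results = []
    for tr in compounds:
        cond = tr.condition
        corrected = background_correct(delta_au(tr, t0, t1), blank_dau)
        pct = inhibition_percentage(corrected, ctrl)
        flag = BackgroundFlag.CLEAN
        plain = bg_plain.get(cond.inhibitor_id)
        if plain is not None and abs(_mean_level(plain, t0, t1) - blank_level) > tol:
            flag = BackgroundFlag.ABSORBANCE_INTERFERENCE
        std = bg_standard.get(cond.inhibitor_id)
        if std is not None and std_dau is not None:
            if std_dau - delta_au(std, t0, t1).value > tol:
                flag = BackgroundFlag.COUPLING_INHIBITION
        results.append(
            InhibitionResult(
                compound_id=cond.inhibitor_id,
                concentration_uM=cond.inhibitor_uM,
                inhibition_pct=pct,
                background_flag=flag,
            )
        )
    results.sort(key=lambda r: r.inhibition_pct, reverse=True)
    return results


def fit_ic50(
    points: Sequence[tuple[float, float]]
) -> tuple[float, float, float, float]:
    """Optional 4-parameter logistic fit of inhibition (%) vs concentration.

    Returns ``(ic50, hill, bottom, top)``.  Provided as a convenience for
    dose-response follow-up; single-concentration screens do not use it.
    """
    c = np.array([x for x, _ in points], dtype=float)
    y = np.array([x for _, x in points], dtype=float)

    def logistic(x, ic50, hill, bottom, top):
        return bottom + (top - bottom) / (1.0 + (ic50 / np.maximum(x, 1e-12)) ** hill)

    popt, _ = optimize.curve_fit(
        logistic,
        c,
        y,
        p0=[np.median(c[c > 0]), 1.0, 0.0, 100.0],
        bounds=([1e-9, 0.1, -50.0, 0.0], [1e9, 10.0, 50.0, 200.0]),
        maxfev=20000,
    )
    return tuple(float(p) for p in popt)


# ---------------------------------------------------------------------------
# plate table I/O (long-format delimited tables)
# ---------------------------------------------------------------------------

_COND_COLS = [
    "well",
    "adomet_uM",
    "enzyme_uM",
    "inhibitor_id",
    "inhibitor_uM",
    "putrescine_mM",
    "is_blank",
    "is_standard",
    "standard_uM",
]


def write_plate(
    traces: Sequence[AbsorbanceTrace], plate_path: str | Path, conditions_path: str | Path
) -> None:
    """Write traces as a long-format readings table (well, time_min, a340)
    plus a per-well conditions table."""
    rows, conds = [], []
    for tr in traces:
        c = tr.condition
        for t, a in zip(tr.times, tr.a340):
            rows.append((c.well, t, a))
        conds.append(
            (
                c.well,
                c.adomet_uM,
                c.enzyme_uM,
                c.inhibitor_id or "",
                c.inhibitor_uM,
                c.putrescine_mM,
                c.is_blank,
                c.is_standard,
                c.standard_uM,
            )
        )
    pd.DataFrame(rows, columns=["well", "time_min", "a340"]).to_csv(
        plate_path, sep="\t", index=False, float_format="%.6f"
    )
    pd.DataFrame(conds, columns=_COND_COLS).to_csv(conditions_path, sep="\t", index=False)


def read_plate(plate_path: str | Path, conditions_path: str | Path) -> list[AbsorbanceTrace]:
    """Read the long-format plate dialect written by :func:`write_plate`."""
    plate = pd.read_csv(plate_path, sep="\t", dtype={"well": str})
    conds = pd.read_csv(
        conditions_path, sep="\t", dtype={"well": str}, keep_default_na=False
    )
    traces = []
    cond_map = {}
    for row in conds.itertuples(index=False):
        cond_map[row.well] = AssayCondition(
            well=row.well,
            adomet_uM=float(row.adomet_uM),
            enzyme_uM=float(row.enzyme_uM),
            inhibitor_id=str(row.inhibitor_id) or None,
            inhibitor_uM=float(row.inhibitor_uM),
            putrescine_mM=float(row.putrescine_mM),
            is_blank=str(row.is_blank) in ("True", "true", "1"),
            is_standard=str(row.is_standard) in ("True", "true", "1"),
            standard_uM=float(row.standard_uM),
        )
    for well, g in plate.groupby("well", sort=False):
        g = g.sort_values("time_min")
        if well not in cond_map:
            raise ValueError(f"well {well} has readings but no conditions row")
        traces.append(
            AbsorbanceTrace(
                times=g["time_min"].to_numpy(),
                a340=g["a340"].to_numpy(),
                condition=cond_map[well],
            )
        )
    return traces
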