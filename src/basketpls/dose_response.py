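"""Viability-plate processing, Hill fitting, inhibition AUC and Loewe synergy.

Plate signals (e.g. CellTiter-Glo luminescence) are blank-corrected, the
vehicle mean defines the 0%-inhibition anchor A_min, and percent
inhibition of a treated well reading x is

    y = (A_min - x) / A_min * 100

Dose-response curves are summarised by a two-parameter Hill fit

    y = 100 / (1 + (IC50 / x)^Hill)

with fixed 0-100% asymptotes, and by the normalized inhibition AUC: the
trapezoidal integral of fractional inhibition (clipped to [0, 1]) over
log10 dose, divided by the log10 dose range, so that 0 = fully inactive
and 1 = fully inhibiting across the tested range.

Loewe additivity scores a fixed-ratio combination: with X1, X2 the
monotherapy IC50s and x1, x2 the per-drug concentrations at the
combination's IC50, the index x1/X1 + x2/X2 is 1 under dose additivity
and below 1 for synergy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class PlateError(ValueError):
    """Raised for uninterpretable plate tables or unreliable fits."""


REQUIRED_PLATE_COLUMNS = ("arm", "well_type", "dose_uM", "signal")


def read_plate_table(path, sep="\t") -> pd.DataFrame:
    plate = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise PlateError(f"plate table missing columns: {missing}")
    return plate


def percent_inhibition(plate: pd.DataFrame) -> pd.DataFrame:
    """Blank-correct a plate arm and convert treated wells to % inhibition.

    Returns a DataFrame with columns ``dose_uM`` and ``inhibition`` (one
    row per distinct dose; replicate wells averaged). Negative values
    mean growth stimulation and are reported as-is.
    """
    missing = [c for c in REQUIRED_PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise PlateError(f"plate table missing columns: {missing}")
    blanks = plate.loc[plate["well_type"] == "blank", "signal"]
    vehicles = plate.loc[plate["well_type"] == "vehicle", "signal"]
    if blanks.empty or vehicles.empty:
        raise PlateError("plate needs at least one blank and one vehicle well")
    blank = float(blanks.mean())
    a_min = float(vehicles.mean()) - blank
    if a_min <= 0:
        raise PlateError("vehicle signal does not exceed blank: uninterpretable plate")
    treated = plate.loc[plate["well_type"] == "treated"].copy()
    if (treated["dose_uM"] <= 0).any():
        raise PlateError("treated wells must have positive dose")
    treated["inhibition"] = (a_min - (treated["signal"] - blank)) / a_min * 100.0
    out = (
        treated.groupby("dose_uM", as_index=False)["inhibition"].mean()
        .sort_values("dose_uM", ignore_index=True)
    )
    return out


@dataclass
class HillFit:
    """Two-parameter Hill fit of an inhibition profile."""

    ic50: float
    hill: float
    doses: np.ndarray
    inhibition: np.ndarray
    sse: float
    converged: bool
    reliable: bool
    message: str = ""

    def curve(self, dose) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        return 100.0 / (1.0 + (self.ic50 / dose) ** self.hill)


def fit_hill(doses, inhibition) -> HillFit:
    """Least-squares Hill fit with bounded parameters.

    Initialization: IC50 at the measured dose whose inhibition is nearest
    50% (geometric mean of the dose range as fallback), Hill slope 1.
    Bounds IC50 in [min dose / 100, 100 * max dose], Hill in [0.1, 10].
    Fits whose IC50 lands on a bound, or that fail to converge, are
    flagged unreliable rather than raising — extrapolated IC50s beyond
    the tested range are not trustworthy.
    """
    doses = np.asarray(doses, dtype=float)
    inhibition = np.asarray(inhibition, dtype=float)
    if doses.shape != inhibition.shape:
        raise PlateError("doses and inhibition must have equal length")
    if len(np.unique(doses[doses > 0])) < 4:
        raise PlateError("need at least 4 distinct nonzero doses")
    if (doses <= 0).any():
        raise PlateError("doses must be positive")
    # measurement noise can push near-complete kills slightly past 100%;
    # the model itself saturates at 100 so such points just add residual

    lo, hi = doses.min() / 100.0, doses.max() * 100.0
    near50 = np.abs(inhibition - 50.0)
    if near50.min() < 40.0:
        ic50_0 = float(doses[near50.argmin()])
    else:
        ic50_0 = float(np.sqrt(doses.min() * doses.max()))
    ic50_0 = min(max(ic50_0, lo), hi)

    def residuals(theta):
        ic50, hill = theta
        return 100.0 / (1.0 + (ic50 / doses) ** hill) - inhibition

    sol = least_squares(
        residuals, x0=[ic50_0, 1.0], bounds=([lo, 0.1], [hi, 10.0]), method="trf"
    )
    ic50, hill = map(float, sol.x)
    sse = float(np.sum(sol.fun ** 2))
    on_bound = ic50 <= lo * (1 + 1e-6) or ic50 >= hi * (1 - 1e-6)
    # a flat profile gives a degenerate fit: inhibition never crosses ~50%
    informative = inhibition.max() - inhibition.min() > 5.0
    reliable = bool(sol.success and not on_bound and informative)
    return HillFit(
        ic50=ic50,
        hill=hill,
        doses=doses,
        inhibition=inhibition,
        sse=sse,
        converged=bool(sol.success),
        reliable=reliable,
        message="" if reliable else "fit unreliable: flat profile or IC50 at bound",
    )


def auc_from_curve(profile, dose_range=None, n_grid: int = 256) -> float:
    """Normalized inhibition AUC over log10 dose, in [0, 1].

    ``profile`` is either a :class:`HillFit` (evaluated on a log-spaced
    grid over ``dose_range``) or a (doses, inhibition) pair integrated
    directly. Fractional inhibition is clipped to [0, 1] before
    integration; the integral is divided by the log10 dose span.
    """
    if isinstance(profile, HillFit):
        if dose_range is None:
            dose_range = (float(profile.doses.min()), float(profile.doses.max()))
        lo, hi = dose_range
        if not (0 < lo < hi):
            raise PlateError("dose range must satisfy 0 < min < max")
        grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
        inh = profile.curve(grid)
    else:
        grid, inh = (np.asarray(v, dtype=float) for v in profile)
        if dose_range is not None:
            lo, hi = dose_range
            keep = (grid >= lo) & (grid <= hi)
            grid, inh = grid[keep], inh[keep]
        if len(grid) < 2:
            raise PlateError("need at least two doses to integrate")
        order = np.argsort(grid)
        grid, inh = grid[order], inh[order]
        if grid[0] <= 0:
            raise PlateError("doses must be positive for log integration")
    frac = np.clip(inh / 100.0, 0.0, 1.0)
    logd = np.log10(grid)
    return float(np.trapezoid(frac, logd) / (logd[-1] - logd[0]))


@dataclass
class SynergyResult:
    """Loewe additivity index of a fixed-ratio combination."""

    mono_ic50_1: float
    mono_ic50_2: float
    combo_ic50_1: float
    combo_ic50_2: float
    loewe_index: float
    synergistic: bool
    ratio: tuple[float, float] = (1, 2)
    fits: dict = field(default_factory=dict)


def loewe_index(mono1: HillFit, mono2: HillFit, combo: HillFit,
                ratio: tuple[float, float] = (1, 2)) -> SynergyResult:
    """Loewe index from mono and combination Hill fits.

    The combination curve must be fitted against the drug-1 concentration
    axis; at the combination IC50 c the per-drug exposures are x1 = c and
    x2 = (ratio2/ratio1) * c. Index below 1 flags synergy.
    """
    for name, fit in (("mono1", mono1), ("mono2", mono2), ("combo", combo)):
        if not fit.reliable:
            raise PlateError(f"{name} fit is unreliable; cannot score synergy")
    r = ratio[1] / ratio[0]
    x1 = combo.ic50
    x2 = r * combo.ic50
    index = x1 / mono1.ic50 + x2 / mono2.ic50
    return SynergyResult(
        mono_ic50_1=mono1.ic50,
        mono_ic50_2=mono2.ic50,
        combo_ic50_1=x1,
        combo_ic50_2=x2,
        loewe_index=float(index),
        synergistic=bool(index < 1.0),
        ratio=tuple(ratio),
        fits={"mono1": mono1, "mono2": mono2, "combo": combo},
    )


def analyze_combination(plates: pd.DataFrame, ratio=(1, 2)) -> SynergyResult:
    """End-to-end synergy analysis from a stacked plate table.

    The table must contain arms ``drug1``, ``drug2`` and ``combo``; each
    arm is converted to percent inhibition, Hill-fitted, and scored with
    the Loewe index.
    """
    fits = {}
    for arm in ("drug1", "drug2", "combo"):
        sub = plates.loc[plates["arm"] == arm]
        if sub.empty:
            raise PlateError(f"plate table has no '{arm}' arm")
        prof = percent_inhibition(sub)
        fits[arm] = fit_hill(prof["dose_uM"], prof["inhibition"])
    return loewe_index(fits["drug1"], fits["drug2"], fits["combo"], ratio=ratio)
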