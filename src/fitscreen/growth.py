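"""Plate-reader growth-curve analysis.

Turns raw optical-density time series into background-corrected growth
curves, area-under-the-curve (AUC) growth measures, dose-response
inhibition profiles, ICx estimates and two-group comparisons.

Conventions
-----------
Time is stored in hours; plate files carry a ``time_min`` column that is
converted on read.  Growth is summarised as the trapezoidal AUC of OD
over the full recording window (units OD*h).  Inhibition at dose ``d``
is ``1 - mean_AUC(d) / mean_AUC(0)``; the ICx is the concentration at
which inhibition reaches ``x`` percent, interpolated piecewise-linearly
in (log10 dose, inhibition) space between the two bracketing doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthCurveSet",
    "DoseResponse",
    "ICxEstimate",
    "correct_blanks",
    "correct_and_average",
    "auc",
    "auc_table",
    "inhibition_profile",
    "estimate_icx",
    "compare_groups",
    "convert_concentration",
]

#: roles a well can play on a growth plate
WELL_ROLES = ("sample", "blank", "vehicle-control")


@dataclass
class GrowthCurveSet:
    """A plate of OD time series plus per-well metadata.

    Parameters
    ----------
    times
        Time grid in hours, strictly increasing.
    od
        Optical density, one row per well, columns aligned with ``times``.
    wells
        Per-well metadata with columns ``well, strain, dose_uM,
        replicate, role``; one row per row of ``od``.
    floored
        Boolean mask marking values clipped to zero during background
        correction (empty before correction).
    """

    times: np.ndarray
    od: np.ndarray
    wells: pd.DataFrame
    floored: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.atleast_2d(np.asarray(self.od, dtype=float))
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.od.shape[1] != self.times.size:
            raise ValueError(
                f"od has {self.od.shape[1]} columns but {self.times.size} times"
            )
        if len(self.wells) != self.od.shape[0]:
            raise ValueError("wells metadata does not match od row count")
        bad = set(self.wells["role"]) - set(WELL_ROLES)
        if bad:
            raise ValueError(f"unknown well roles: {sorted(bad)}")

    @property
    def n_wells(self) -> int:
        return self.od.shape[0]


@dataclass
class DoseResponse:
    """AUC summary across doses with inhibition relative to dose 0."""

    doses: np.ndarray        # uM, ascending, dose 0 first
    mean_auc: np.ndarray     # OD*h
    se_auc: np.ndarray       # OD*h, standard error over replicates
    inhibition: np.ndarray   # fraction in [0, 1] relative to dose 0
    n_replicates: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.doses)
        for name in ("mean_auc", "se_auc", "inhibition"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != doses length")
        if self.doses[0] != 0.0:
            raise ValueError("dose 0 must be present and first")
        if self.inhibition[0] != 0.0:
            raise ValueError("inhibition at dose 0 must be exactly 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose_uM": self.doses,
                "mean_auc": self.mean_auc,
                "se_auc": self.se_auc,
                "inhibition": self.inhibition,
            }
        )


@dataclass
class ICxEstimate:
    """Concentration producing x percent growth inhibition."""

    x: float                      # percent inhibition target
    concentration: float          # uM
    bracketing_doses: tuple       # (lo, hi) uM
    extrapolated: bool = False


def correct_blanks(raw: GrowthCurveSet) -> GrowthCurveSet:
    """Subtract the per-time blank mean from every non-blank well.

    Keeps replicate wells separate (replicate-level AUC statistics are
    computed from these); negative values are floored at 0 and flagged.
    """
    blank_mask = (raw.wells["role"] == "blank").to_numpy()
    if not blank_mask.any():
        raise ValueError("plate has no blank wells; cannot background-correct")
    blank_curve = raw.od[blank_mask].mean(axis=0)
    corrected = raw.od[~blank_mask] - blank_curve
    floored = corrected < 0
    return GrowthCurveSet(
        times=raw.times,
        od=np.where(floored, 0.0, corrected),
        wells=raw.wells.loc[~blank_mask].reset_index(drop=True),
        floored=floored,
    )


def correct_and_average(raw: GrowthCurveSet) -> GrowthCurveSet:
    """Background-correct and replicate-average a plate.

    The per-time-point mean of all blank wells is subtracted from every
    non-blank well; negative corrected values are floored at 0 and
    flagged.  Replicate wells sharing (strain, dose) are then averaged
    into a single curve.

    Raises
    ------
    ValueError
        If the plate has no blank wells.
    """
    per_well = correct_blanks(raw)
    corrected, floored, meta = per_well.od, per_well.floored, per_well.wells

    rows, out_meta, out_floor = [], [], []
    for (strain, dose), grp in meta.groupby(["strain", "dose_uM"], sort=True):
        idx = grp.index.to_numpy()
        rows.append(corrected[idx].mean(axis=0))
        out_floor.append(floored[idx].any(axis=0))
        role = grp["role"].iloc[0]
        out_meta.append(
            {
                "well": ",".join(map(str, grp["well"])),
                "strain": strain,
                "dose_uM": dose,
                "replicate": "avg",
                "role": role,
            }
        )
    return GrowthCurveSet(
        times=raw.times,
        od=np.vstack(rows),
        wells=pd.DataFrame(out_meta),
        floored=np.vstack(out_floor),
    )


def auc(times: np.ndarray, od: np.ndarray) -> float:
    """Trapezoidal area under an OD-versus-time curve (OD*h)."""
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    if times.size < 2:
        raise ValueError("AUC needs at least two time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if od.shape[-1] != times.size:
        raise ValueError("od and times length mismatch")
    return float(np.trapezoid(od, times))


def auc_table(curves: GrowthCurveSet) -> pd.DataFrame:
    """Per-well AUC with metadata, for replicate-level statistics."""
    vals = [auc(curves.times, row) for row in curves.od]
    out = curves.wells.copy()
    out["auc"] = vals
    return out


def inhibition_profile(aucs_by_dose: dict) -> DoseResponse:
    """Summarise per-replicate AUC values into a dose-response profile.

    Parameters
    ----------
    aucs_by_dose
        Mapping ``dose_uM -> sequence of replicate AUC values``; must
        include dose 0 (the untreated / vehicle baseline).
    """
    if 0 not in aucs_by_dose and 0.0 not in aucs_by_dose:
        raise ValueError("dose 0 (untreated baseline) is required")
    doses = np.array(sorted(aucs_by_dose), dtype=float)
    means, ses, ns = [], [], []
    for d in doses:
        vals = np.asarray(aucs_by_dose[d if d in aucs_by_dose else int(d)], dtype=float)
        means.append(vals.mean())
        ses.append(vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0)
        ns.append(vals.size)
    means = np.array(means)
    if means[0] <= 0:
        raise ValueError("mean AUC at dose 0 must be positive")
    inhibition = 1.0 - means / means[0]
    inhibition[0] = 0.0
    return DoseResponse(
        doses=doses,
        mean_auc=means,
        se_auc=np.array(ses),
        inhibition=inhibition,
        n_replicates=np.array(ns),
    )


def estimate_icx(
    profile: DoseResponse, x: float, allow_extrapolation: bool = True
) -> ICxEstimate:
    """Interpolate the concentration producing ``x`` percent inhibition.

    Interpolation is piecewise-linear in (log10 dose, inhibition) over
    the non-zero doses; the zero dose enters only as the inhibition
    baseline.  If the target is not bracketed the nearest measured dose
    is returned with ``extrapolated=True`` (or an error is raised when
    extrapolation is disabled).
    """
    if not 0 < x < 100:
        raise ValueError("x must be in (0, 100) percent")
    target = x / 100.0
    pos = profile.doses > 0
    doses = profile.doses[pos]
    inh = profile.inhibition[pos]
    if doses.size < 1 or len(profile.doses) < 2:
        raise ValueError("need at least two doses including dose 0")

    # exact hits first (covers the dose-0 -> first-dose bracket too)
    exact = np.isclose(inh, target)
    if exact.any():
        d = float(doses[np.argmax(exact)])
        return ICxEstimate(x=x, concentration=d, bracketing_doses=(d, d))

    above = inh >= target
    if not above.any() or above.all():
        # target outside the measured range
        if not allow_extrapolation:
            raise ValueError(f"inhibition {target:.3f} not bracketed by profile")
        idx = int(np.argmax(inh)) if not above.any() else int(np.argmin(inh))
        d = float(doses[idx])
        return ICxEstimate(
            x=x, concentration=d, bracketing_doses=(d, d), extrapolated=True
        )

    hi_idx = int(np.argmax(above))  # first dose at/above target
    if hi_idx == 0:
        # bracketed between dose 0 (inhibition 0) and the first dose:
        # no log-axis point for dose 0, so interpolate linearly in dose
        lo_d, lo_i = 0.0, 0.0
        hi_d, hi_i = float(doses[0]), float(inh[0])
        frac = (target - lo_i) / (hi_i - lo_i)
        conc = lo_d + frac * (hi_d - lo_d)
        return ICxEstimate(x=x, concentration=float(conc), bracketing_doses=(lo_d, hi_d))

    lo_d, hi_d = float(doses[hi_idx - 1]), float(doses[hi_idx])
    lo_i, hi_i = float(inh[hi_idx - 1]), float(inh[hi_idx])
    frac = (target - lo_i) / (hi_i - lo_i)
    log_conc = np.log10(lo_d) + frac * (np.log10(hi_d) - np.log10(lo_d))
    return ICxEstimate(
        x=x, concentration=float(10 ** log_conc), bracketing_doses=(lo_d, hi_d)
    )


def compare_groups(auc_a, auc_b) -> dict:
    """Two-sided pooled-variance (Student) t-test on replicate AUCs.

    Degenerate zero-variance groups are resolved deterministically:
    equal means give ``p = 1``, unequal means ``p = 0``.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two replicate values")
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "p": 1.0}
        return {"t": np.inf if a.mean() > b.mean() else -np.inf, "p": 0.0}
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "p": float(p)}


def convert_concentration(c_uM: float, molar_mass: float) -> float:
    """Convert a molar concentration (uM) to a mass concentration (mg/L).

    mg/L = uM * (g/mol) / 1000.
    """
    if c_uM < 0:
        raise ValueError("concentration must be non-negative")
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    return c_uM * molar_mass / 1000.0
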