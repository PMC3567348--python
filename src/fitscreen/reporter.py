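"""Real-time GFP stress-reporter quantification (PELI analysis).

A plate of GFP-fusion reporter strains is read for OD (growth) and GFP
(expression) every few minutes during a short chemical exposure.  The
per-cell expression ``P = GFP_corrected / OD_corrected`` is compared
against the matched vehicle control to give the induction factor
``I(t) = P_experiment(t) / P_vehicle(t)``, and the Protein Expression
Level Index (PELI) is the time-average of I over the exposure window:

    PELI = (1 / T) * integral_0^T I(t) dt

so an unperturbed reporter has PELI = 1 by construction.  A reporter is
called *activated* when its mean PELI over replicates exceeds a
signal-to-noise cutoff (default 1.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReporterPlate",
    "PELIRecord",
    "correct_signals",
    "expression_level",
    "plate_normalize",
    "induction_series",
    "peli",
    "aggregate_and_call",
    "heatmap_export",
    "rank_profile",
    "analyze_plate",
]

log = logging.getLogger(__name__)

REPORTER_ROLES = ("experiment", "vehicle-control", "medium-control", "internal-control")


@dataclass
class ReporterPlate:
    """Paired OD/GFP time courses plus per-well metadata.

    ``times`` are minutes; ``od`` and ``gfp`` are well x time matrices
    sharing the grid; ``wells`` has columns ``well, orf,
    stress_category, dose_mgL, role, replicate``.
    """

    times: np.ndarray
    od: np.ndarray
    gfp: np.ndarray
    wells: pd.DataFrame
    floored: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.atleast_2d(np.asarray(self.od, dtype=float))
        self.gfp = np.atleast_2d(np.asarray(self.gfp, dtype=float))
        if self.od.shape != self.gfp.shape:
            raise ValueError("od and gfp must share shape")
        if self.od.shape[1] != self.times.size:
            raise ValueError("time grid does not match signal columns")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.wells) != self.od.shape[0]:
            raise ValueError("wells metadata does not match signal rows")
        bad = set(self.wells["role"]) - set(REPORTER_ROLES)
        if bad:
            raise ValueError(f"unknown reporter well roles: {sorted(bad)}")


@dataclass
class PELIRecord:
    """Replicate-aggregated PELI for one reporter ORF at one dose."""

    orf: str
    dose_mgL: float
    replicates: np.ndarray
    mean: float
    sd: float
    activated: bool
    category: str = ""
    n_rep: int = 0


def correct_signals(plate: ReporterPlate, epsilon_frac: float = 1e-4) -> ReporterPlate:
    """Subtract the matched medium-control background from OD and GFP.

    Medium-control wells (growth medium, no cells) are matched by dose
    so chemical autofluorescence is removed with the chemical present.
    Per time point their mean OD and GFP are subtracted from every
    non-medium well at the same dose; corrected values are floored at a
    small positive epsilon (``epsilon_frac`` of each channel's dynamic
    range) and flagged where flooring occurred.
    """
    wells = plate.wells
    med = wells["role"] == "medium-control"
    if not med.any():
        raise ValueError("no medium-control wells on plate")
    med_doses = set(wells.loc[med, "dose_mgL"])
    have_global = len(med_doses) == 1

    od_c = plate.od.astype(float).copy()
    gfp_c = plate.gfp.astype(float).copy()
    eps_od = epsilon_frac * max(np.ptp(plate.od), 1e-12)
    eps_gfp = epsilon_frac * max(np.ptp(plate.gfp), 1e-12)

    for dose, grp in wells.groupby("dose_mgL"):
        target = grp.index[grp["role"] != "medium-control"].to_numpy()
        if target.size == 0:
            continue
        ctrl = wells.index[(wells["role"] == "medium-control")
                           & (wells["dose_mgL"] == dose)].to_numpy()
        if ctrl.size == 0:
            if have_global:
                ctrl = wells.index[med].to_numpy()  # single shared medium blank
            else:
                raise ValueError(f"no medium control for dose {dose} mg/L")
        od_c[target] -= plate.od[ctrl].mean(axis=0)
        gfp_c[target] -= plate.gfp[ctrl].mean(axis=0)

    floored = (od_c < eps_od) | (gfp_c < eps_gfp)
    od_c = np.maximum(od_c, eps_od)
    gfp_c = np.maximum(gfp_c, eps_gfp)
    return ReporterPlate(
        times=plate.times, od=od_c, gfp=gfp_c, wells=wells.copy(), floored=floored
    )


def expression_level(gfp_c: np.ndarray, od_c: np.ndarray) -> np.ndarray:
    """Per-cell expression P = GFP_corrected / OD_corrected, pointwise."""
    gfp_c = np.asarray(gfp_c, dtype=float)
    od_c = np.asarray(od_c, dtype=float)
    if np.any(od_c <= 0):
        raise ValueError("corrected OD must be positive (apply correct_signals first)")
    return gfp_c / od_c


def plate_normalize(p: np.ndarray, internal_control_p: np.ndarray | None) -> np.ndarray:
    """Divide P by the per-time-point plate median of internal controls.

    Removes plate-wide multiplicative factors (lamp gain, plate batch).
    Skipped with a warning when no internal-control wells exist.
    """
    p = np.asarray(p, dtype=float)
    if internal_control_p is None or np.size(internal_control_p) == 0:
        log.warning("no internal-control wells; plate normalization skipped")
        return p
    ref = np.median(np.atleast_2d(internal_control_p), axis=0)
    if np.any(ref <= 0):
        raise ValueError("internal-control P must be positive at every time point")
    return p / ref


def induction_series(p_experiment: np.ndarray, p_vehicle: np.ndarray) -> np.ndarray:
    """Induction factor I(t) = P_experiment(t) / P_vehicle(t)."""
    pe = np.asarray(p_experiment, dtype=float)
    pv = np.asarray(p_vehicle, dtype=float)
    if pe.shape != pv.shape:
        raise ValueError("experiment and vehicle series must share the time grid")
    if np.any(pv <= 0):
        raise ValueError("vehicle P must be positive")
    return pe / pv


def peli(i_series: np.ndarray, times: np.ndarray) -> float:
    """Time-averaged induction: trapezoidal integral of I over the
    window divided by the window length.  Dimensionless; I == 1 gives
    exactly 1."""
    t = np.asarray(times, dtype=float)
    i = np.asarray(i_series, dtype=float)
    if t.size < 2:
        raise ValueError("PELI needs at least two time points")
    if i.shape[-1] != t.size:
        raise ValueError("series and times length mismatch")
    span = t[-1] - t[0]
    return float(np.trapezoid(i, t) / span)


def aggregate_and_call(
    replicate_pelis, cutoff: float = 1.5, orf: str = "", dose_mgL: float = np.nan,
    category: str = "",
) -> PELIRecord:
    """Mean +/- sample SD over replicate PELIs and the activation call.

    Activation uses the replicate mean against the signal-to-noise
    cutoff (default 1.5).  A single replicate gets SD = 0.
    """
    vals = np.asarray(list(replicate_pelis), dtype=float)
    if vals.size < 1:
        raise ValueError("need at least one replicate PELI")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return PELIRecord(
        orf=orf,
        dose_mgL=dose_mgL,
        replicates=vals,
        mean=mean,
        sd=sd,
        activated=mean > cutoff,
        category=category,
        n_rep=int(vals.size),
    )


def heatmap_export(i_by_dose: dict, times: np.ndarray,
                   category_order: list | None = None) -> pd.DataFrame:
    """ln(I) matrix for heat-map rendering.

    ``i_by_dose`` maps dose -> DataFrame (rows = ORFs, columns = time
    points) of induction factors.  Rows are grouped by stress category
    when an ordering is given; columns are blocked by dose.  Rendering
    is left to the plotting layer — this emits the numeric TSV payload.
    """
    blocks = []
    for dose in sorted(i_by_dose):
        mat = i_by_dose[dose]
        cols = [f"dose{dose}_t{int(t)}" for t in times]
        blk = pd.DataFrame(np.log(mat.to_numpy(dtype=float)),
                           index=mat.index, columns=cols)
        blocks.append(blk)
    out = pd.concat(blocks, axis=1)
    if category_order is not None:
        order = [o for o in category_order if o in out.index]
        order += [o for o in out.index if o not in order]
        out = out.loc[order]
    return out


def rank_profile(records: list) -> pd.DataFrame:
    """Per dose, ORFs ranked by mean PELI descending (ties: ORF id).

    Returns ``dose_mgL, rank, orf, peli_mean, peli_sd, activated,
    category`` — the tabular analogue of a rank-profile figure.
    """
    rows = [
        {
            "dose_mgL": r.dose_mgL,
            "orf": r.orf,
            "peli_mean": r.mean,
            "peli_sd": r.sd,
            "activated": r.activated,
            "category": r.category,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    out = []
    for dose, grp in df.groupby("dose_mgL", sort=True):
        grp = grp.sort_values(["peli_mean", "orf"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
        grp.insert(1, "rank", np.arange(1, len(grp) + 1))
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def analyze_plate(
    plate: ReporterPlate, cutoff: float = 1.5, use_internal_control: bool = True
) -> dict:
    """Full reporter pipeline on one plate.

    Corrects signals, computes P per well, optionally plate-normalizes
    by internal controls, forms I(t) per (orf, dose, replicate) against
    the matched vehicle replicate, and aggregates PELIs into activation
    calls.  Returns ``records`` (list of PELIRecord), ``peli_table``,
    ``induction`` (dict dose -> ORF x time mean-I DataFrame) and
    ``rank_table``.
    """
    corrected = correct_signals(plate)
    wells = corrected.wells
    p = expression_level(corrected.gfp, corrected.od)

    ic_rows = wells.index[wells["role"] == "internal-control"].to_numpy()
    if use_internal_control and ic_rows.size:
        p = plate_normalize(p, p[ic_rows])

    records: list[PELIRecord] = []
    i_by_dose: dict = {}
    exp_wells = wells[wells["role"] == "experiment"]
    for (orf, dose), grp in exp_wells.groupby(["orf", "dose_mgL"], sort=True):
        cat = grp["stress_category"].iloc[0]
        pelis, i_mats = [], []
        for _, wrow in grp.iterrows():
            veh = wells.index[
                (wells["role"] == "vehicle-control")
                & (wells["orf"] == orf)
                & (wells["replicate"] == wrow["replicate"])
            ].to_numpy()
            if veh.size == 0:  # fall back to any vehicle replicate of the ORF
                veh = wells.index[
                    (wells["role"] == "vehicle-control") & (wells["orf"] == orf)
                ].to_numpy()
            if veh.size == 0:
                raise ValueError(f"no vehicle-control wells for ORF {orf!r}")
            i_t = induction_series(p[wrow.name], np.mean(p[veh], axis=0))
            pelis.append(peli(i_t, corrected.times))
            i_mats.append(i_t)
        records.append(
            aggregate_and_call(pelis, cutoff=cutoff, orf=orf, dose_mgL=dose,
                               category=cat)
        )
        i_by_dose.setdefault(dose, {})[orf] = np.mean(i_mats, axis=0)

    induction = {
        d: pd.DataFrame.from_dict(mats, orient="index",
                                  columns=[f"t{int(t)}" for t in corrected.times])
        for d, mats in i_by_dose.items()
    }
    peli_table = pd.DataFrame(
        {
            "orf": [r.orf for r in records],
            "dose_mgL": [r.dose_mgL for r in records],
            "peli_mean": [r.mean for r in records],
            "peli_sd": [r.sd for r in records],
            "n_rep": [r.n_rep for r in records],
            "activated": [r.activated for r in records],
            "category": [r.category for r in records],
        }
    )
    return {
        "records": records,
        "peli_table": peli_table,
        "induction": induction,
        "rank_table": rank_profile(records),
    }
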