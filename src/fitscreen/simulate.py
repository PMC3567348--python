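"""Seeded synthetic-data generators with ground truth.

Three generators emulate the data shapes the analysis modules consume,
each a deterministic function of (config, seed):

* pooled deletion-strain barcode screens — competitive pool growth over
  5 or 15 generations with planted per-strain selection coefficients,
  saturating hybridization with null features and lognormal noise,
  3 treated replicates and 12 controls per generation arm;
* GFP reporter plates — logistic growth, ORF-specific induction
  profiles, triplicate experiment/vehicle wells plus medium controls;
* dose-response growth plates — Hill-type dose-dependent inhibition of
  a logistic growth curve read every 15 min for 24 h, with the true
  ICx available in closed form.

Default sizes are scaled-down but structure-preserving stand-ins for a
genome-scale screen (4000 strains / 2000 null features versus the full
4757 / 18000); full scale is reachable through the configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dssa import ArrayExperiment
from .growth import GrowthCurveSet
from .reporter import ReporterPlate

__all__ = [
    "PoolSimConfig",
    "ReporterSimConfig",
    "simulate_pool_screen",
    "simulate_reporter_plate",
    "simulate_growth_doseresponse",
    "hill_inhibition",
    "hill_icx",
]


@dataclass
class PoolSimConfig:
    """Configuration of the pooled barcode-screen generator.

    Selection coefficients ``s`` are per-generation fitness deficits:
    a strain with coefficient s grows as ``2^(g * (1 - s))`` over g
    generations, so s > 0 depletes the strain under treatment
    (sensitive) and s < 0 enriches it (resistant).  By default the
    effective coefficient scales linearly with dose relative to the
    highest dose; ``dose_scaling="threshold"`` instead applies the full
    coefficient at every non-zero dose (a sharp threshold response).
    """

    n_strains: int = 4000
    n_null_features: int = 2000
    generations: tuple = (5,)
    doses: tuple = (330.0,)
    selection: dict = field(default_factory=dict)   # gene id -> s
    replicates: int = 3
    controls: int = 12
    dose_scaling: str = "linear"                    # "linear" | "threshold"
    # hybridization model
    saturation_ceiling: float = 60000.0
    signal_max: float = 65000.0
    half_saturation: float = 4e-3                   # on relative-abundance scale
    noise_sigma: float = 0.15                       # lognormal sigma (ln units)
    background_mean: float = 120.0
    background_sd: float = 40.0
    abundance_sigma: float = 0.5                    # strain-to-strain spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.n_null_features < 1:
            raise ValueError("counts must be >= 1")
        if self.replicates < 1 or self.controls < 1:
            raise ValueError("replicates and controls must be >= 1")
        if any(abs(s) >= 1 for s in self.selection.values()):
            raise ValueError("|selection coefficient| must be < 1")
        if self.dose_scaling not in ("linear", "threshold"):
            raise ValueError("dose_scaling must be 'linear' or 'threshold'")


def _hybridize(rng, abundance: np.ndarray, cfg: PoolSimConfig) -> np.ndarray:
    """Saturating (Michaelis-type) abundance -> signal map with noise."""
    sat = cfg.signal_max * abundance / (abundance + cfg.half_saturation)
    noise = np.exp(rng.normal(0.0, cfg.noise_sigma, size=abundance.shape))
    return sat * noise


def simulate_pool_screen(cfg: PoolSimConfig) -> tuple[ArrayExperiment, pd.DataFrame]:
    """Generate a pooled screen and its ground-truth table.

    Relative strain abundance after g generations is
    ``a_i0 * 2^(g * (1 - s_eff_i))`` renormalized to sum to one;
    control pools use s == 0.  Per-array barcode signal follows the
    saturating hybridization map with lognormal noise; null features
    are drawn from the background distribution.  Returns the experiment
    plus a truth table ``gene, s, expected_label``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = np.array([f"GENE{i:05d}" for i in range(cfg.n_strains)])
    base = np.exp(rng.normal(0.0, cfg.abundance_sigma, cfg.n_strains))
    base /= base.sum()
    s = np.zeros(cfg.n_strains)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, coef in cfg.selection.items():
        s[gene_pos[g]] = coef

    max_dose = max(cfg.doses) if cfg.doses else 1.0
    probes = pd.DataFrame(
        {
            "gene_id": np.concatenate([genes, [""] * cfg.n_null_features]),
            "is_null_feature": np.concatenate(
                [np.zeros(cfg.n_strains, bool), np.ones(cfg.n_null_features, bool)]
            ),
        },
        index=[f"P{i:05d}" for i in range(cfg.n_strains)]
        + [f"NULL{i:05d}" for i in range(cfg.n_null_features)],
    )

    columns, meta_rows = {}, []

    def make_array(array_id, s_eff, gens, dose, arm, rep):
        growth = np.power(2.0, gens * (1.0 - s_eff))
        ab = base * growth
        ab = ab / ab.sum()  # relative abundance sums to 1 before hybridization
        sig = _hybridize(rng, ab, cfg)
        bg = np.maximum(
            rng.normal(cfg.background_mean, cfg.background_sd, cfg.n_null_features),
            0.0,
        )
        # gene probes also sit on background
        sig = sig + np.maximum(
            rng.normal(cfg.background_mean, cfg.background_sd, cfg.n_strains), 0.0
        )
        columns[array_id] = np.concatenate([sig, bg])
        meta_rows.append(
            {"array_id": array_id, "dose_uM": dose, "generations": gens,
             "arm": arm, "replicate": rep}
        )

    for gens in cfg.generations:
        for dose in cfg.doses:
            if cfg.dose_scaling == "linear":
                s_eff = s * (dose / max_dose)
            else:
                s_eff = s if dose > 0 else np.zeros_like(s)
            for rep in range(1, cfg.replicates + 1):
                make_array(f"T_g{gens}_d{dose:g}_r{rep}", s_eff, gens, dose,
                           "treatment", rep)
        for rep in range(1, cfg.controls + 1):
            make_array(f"C_g{gens}_r{rep}", np.zeros_like(s), gens, 0.0,
                       "control", rep)

    intensities = pd.DataFrame(columns, index=probes.index)
    arrays = pd.DataFrame(meta_rows).set_index("array_id")
    exp = ArrayExperiment(
        intensities=intensities,
        probes=probes,
        arrays=arrays,
        saturation_ceiling=cfg.saturation_ceiling,
    )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "s": s,
            "expected_label": np.where(
                s > 0, "sensitive", np.where(s < 0, "resistant", "none")
            ),
        }
    )
    return exp, truth


@dataclass
class ReporterSimConfig:
    """Configuration of the GFP reporter-plate generator.

    ``induction`` maps ORF id -> true induction factor I* (constant
    over the window, so the true PELI equals I*); unlisted ORFs default
    to 1 (no response).  Growth is logistic with rate ``r`` (1/min),
    carrying capacity ``od_max`` and inoculum ``od0``.
    """

    orfs: tuple = ("ORF01", "ORF02", "ORF03")
    categories: dict = field(default_factory=dict)   # orf -> stress category
    induction: dict = field(default_factory=dict)    # orf -> I*
    doses: tuple = (10.0,)
    replicates: int = 3
    time_step_min: float = 5.0
    duration_min: float = 120.0
    od0: float = 0.2
    od_max: float = 1.0
    growth_rate: float = 0.01        # 1/min
    p_base: float = 1000.0           # vehicle GFP per OD unit
    od_background: float = 0.04
    gfp_background: float = 50.0
    noise_od: float = 0.0            # multiplicative (fractional) noise
    noise_gfp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(i <= 0 for i in self.induction.values()):
            raise ValueError("true induction factors must be positive")
        if self.od0 <= 0 or self.od_max <= self.od0 / 2:
            raise ValueError("invalid logistic growth parameters")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_min + 1e-9, self.time_step_min)


def simulate_reporter_plate(cfg: ReporterSimConfig) -> tuple[ReporterPlate, pd.DataFrame]:
    """Generate a reporter plate and its truth PELI table.

    Vehicle wells express GFP = p_base * OD; experiment wells express
    GFP = I* * p_base * OD.  Both channels gain the medium background
    plus multiplicative Gaussian noise; medium-control wells carry the
    background alone.  Truth PELI = I* (constant induction).
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.times
    # logistic growth from od0 toward od_max
    k, r, od0 = cfg.od_max, cfg.growth_rate, cfg.od0
    od_true = k / (1.0 + (k / od0 - 1.0) * np.exp(-r * t))

    rows_od, rows_gfp, meta = [], [], []

    def noisy(base, frac):
        if frac == 0:
            return base.copy()
        return base * (1.0 + rng.normal(0.0, frac, size=base.shape))

    def add_well(well, orf, cat, dose, role, rep, i_star):
        od = noisy(od_true, cfg.noise_od) + cfg.od_background
        gfp = noisy(i_star * cfg.p_base * od_true, cfg.noise_gfp) + cfg.gfp_background
        rows_od.append(od)
        rows_gfp.append(gfp)
        meta.append({"well": well, "orf": orf, "stress_category": cat,
                     "dose_mgL": dose, "role": role, "replicate": rep})

    w = 0
    for dose in cfg.doses:
        for orf in cfg.orfs:
            cat = cfg.categories.get(orf, "general")
            i_star = cfg.induction.get(orf, 1.0)
            for rep in range(1, cfg.replicates + 1):
                add_well(f"W{w:03d}", orf, cat, dose, "experiment", rep, i_star); w += 1
                add_well(f"W{w:03d}", orf, cat, dose, "vehicle-control", rep, 1.0); w += 1
        # medium control for this dose (no cells)
        rows_od.append(np.full_like(t, cfg.od_background))
        rows_gfp.append(np.full_like(t, cfg.gfp_background))
        meta.append({"well": f"W{w:03d}", "orf": "", "stress_category": "",
                     "dose_mgL": dose, "role": "medium-control", "replicate": 1})
        w += 1

    plate = ReporterPlate(
        times=t,
        od=np.vstack(rows_od),
        gfp=np.vstack(rows_gfp),
        wells=pd.DataFrame(meta),
    )
    truth = pd.DataFrame(
        {
            "orf": list(cfg.orfs),
            "true_peli": [cfg.induction.get(o, 1.0) for o in cfg.orfs],
        }
    )
    return plate, truth


def hill_inhibition(dose: float, ic50: float, slope: float) -> float:
    """Fractional growth inhibition of a Hill dose-response curve."""
    if dose <= 0:
        return 0.0
    return dose ** slope / (dose ** slope + ic50 ** slope)


def hill_icx(x: float, ic50: float, slope: float) -> float:
    """Closed-form ICx of a Hill curve: ic50 * (f/(1-f))^(1/slope), f = x/100."""
    f = x / 100.0
    return float(ic50 * (f / (1.0 - f)) ** (1.0 / slope))


def simulate_growth_doseresponse(
    ic50: float,
    slope: float,
    doses,
    seed: int,
    od_max: float = 1.2,
    rate: float = 0.5,          # 1/h
    od0: float = 0.0165,
    replicates: int = 3,
    noise_sd: float = 0.005,
    blank_od: float = 0.05,
    duration_h: float = 24.0,
    step_min: float = 15.0,
) -> tuple[GrowthCurveSet, float]:
    """Hill-inhibited logistic growth plate with known true IC20.

    Each dose scales a shared logistic growth curve by
    ``1 - inhibition(dose)``, so the AUC-based inhibition equals the
    Hill inhibition exactly in the noiseless limit.  Additive Gaussian
    read noise and a constant blank offset emulate the plate reader.
    Returns the raw plate (blank wells included) and the closed-form
    true IC20.
    """
    if ic50 <= 0 or slope <= 0:
        raise ValueError("ic50 and slope must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_h + 1e-9, step_min / 60.0)
    base = od_max / (1.0 + (od_max / od0 - 1.0) * np.exp(-rate * t))

    rows, meta = [], []
    w = 0
    for dose in doses:
        scale = 1.0 - hill_inhibition(dose, ic50, slope)
        for rep in range(1, replicates + 1):
            od = blank_od + scale * base + rng.normal(0.0, noise_sd, t.size)
            rows.append(od)
            meta.append({"well": f"W{w:03d}", "strain": "WT", "dose_uM": float(dose),
                         "replicate": rep, "role": "sample"})
            w += 1
    for rep in range(1, 3):
        rows.append(blank_od + rng.normal(0.0, noise_sd, t.size))
        meta.append({"well": f"W{w:03d}", "strain": "", "dose_uM": 0.0,
                     "replicate": rep, "role": "blank"})
        w += 1

    plate = GrowthCurveSet(times=t, od=np.vstack(rows), wells=pd.DataFrame(meta))
    return plate, hill_icx(20.0, ic50, slope)
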