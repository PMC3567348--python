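"""End-to-end recovery experiments on synthetic screens.

Each function generates a synthetic data set under the study's design
(3 treated replicates x 12 controls for the pooled screen, triplicate
reporter wells, 15-min / 24-h growth reads), runs the full analysis
pipeline on it, and scores the result against the generator's ground
truth.  These are the quantitative benchmarks the test suite and the
acceptance script both run; all randomness is controlled by the seed.
"""

from __future__ import annotations

import numpy as np

from .dssa import run_dssa
from .growth import auc_table, correct_blanks, estimate_icx, inhibition_profile
from .reporter import analyze_plate
from .simulate import (
    PoolSimConfig,
    ReporterSimConfig,
    simulate_growth_doseresponse,
    simulate_pool_screen,
    simulate_reporter_plate,
)

__all__ = [
    "dssa_recovery",
    "dssa_null_calls",
    "ic20_recovery",
    "reporter_recovery",
    "reporter_null_activations",
]

N_PLANTED = 30
PLANTED_S = 0.3


def dssa_recovery(
    seed: int,
    n_strains: int = 4000,
    n_planted: int = N_PLANTED,
    s: float = PLANTED_S,
    strict: bool = False,
) -> dict:
    """Plant ``n_planted`` depleted strains, run DSSA, score the calls.

    Returns sensitivity (planted strains recovered as sensitive), the
    empirical false-discovery rate among sensitive calls, and the call
    count.
    """
    rng = np.random.default_rng(seed)
    planted = rng.choice(n_strains, size=n_planted, replace=False)
    selection = {f"GENE{i:05d}": s for i in planted}
    cfg = PoolSimConfig(n_strains=n_strains, selection=selection, seed=seed)
    exp, truth = simulate_pool_screen(cfg)
    res = run_dssa(exp, strict=strict)
    calls = res["calls"]
    called = set(calls.loc[calls["label"] == "sensitive", "gene"])
    truth_set = set(truth.loc[truth["s"] > 0, "gene"])
    tp = len(called & truth_set)
    return {
        "sensitivity": tp / len(truth_set),
        "fdr": (len(called) - tp) / len(called) if called else 0.0,
        "n_called": len(called),
    }


def dssa_null_calls(seed: int, n_strains: int = 4000, strict: bool = False) -> dict:
    """Run DSSA on a screen with no planted effects; count calls."""
    cfg = PoolSimConfig(n_strains=n_strains, selection={}, seed=seed)
    exp, _ = simulate_pool_screen(cfg)
    calls = run_dssa(exp, strict=strict)["calls"]
    n_called = int((calls["label"] != "none").sum())
    return {"n_called": n_called, "call_rate": n_called / len(calls)}


def ic20_recovery(
    seed: int,
    ic50: float = 500.0,
    slope: float = 1.5,
    doses=(0.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1600.0),
) -> dict:
    """Simulate a Hill dose-response plate and re-estimate the IC20."""
    plate, true_ic20 = simulate_growth_doseresponse(
        ic50, slope, list(doses), seed=seed
    )
    per_well = auc_table(correct_blanks(plate))
    profile = inhibition_profile(
        {d: grp["auc"].to_list() for d, grp in per_well.groupby("dose_uM")}
    )
    est = estimate_icx(profile, 20)
    return {
        "true_ic20": true_ic20,
        "estimated_ic20": est.concentration,
        "rel_error": abs(est.concentration - true_ic20) / true_ic20,
    }


def reporter_recovery(
    seed: int,
    n_orfs: int = 24,
    n_quiet: int = 24,
    induction: float = 1.8,
    noise: float = 0.02,
    cutoff: float = 1.5,
) -> dict:
    """Plant activated reporters among quiet ones and score the calls.

    ``n_orfs`` reporters get true induction ``induction`` (> cutoff);
    ``n_quiet`` stay at 1.  Scores mean relative PELI error on the
    planted reporters and whether the activation calls are exactly the
    planted set.
    """
    orfs = tuple(f"ORF{i:03d}" for i in range(n_orfs + n_quiet))
    cfg = ReporterSimConfig(
        orfs=orfs,
        induction={o: induction for o in orfs[:n_orfs]},
        noise_od=noise,
        noise_gfp=noise,
        seed=seed,
    )
    plate, truth = simulate_reporter_plate(cfg)
    res = analyze_plate(plate, cutoff=cutoff)
    table = res["peli_table"].set_index("orf")
    planted = set(orfs[:n_orfs])
    activated = set(table.index[table["activated"]])
    rel_err = (
        (table.loc[list(planted), "peli_mean"] - induction).abs() / induction
    )
    return {
        "max_rel_peli_error": float(rel_err.max()),
        "mean_rel_peli_error": float(rel_err.mean()),
        "calls_exact": activated == planted,
        "n_activated": len(activated),
    }


def reporter_null_activations(seed: int, n_orfs: int = 24,
                              noise: float = 0.02) -> dict:
    """Vehicle-level plate (all true induction 1): count activations."""
    orfs = tuple(f"ORF{i:03d}" for i in range(n_orfs))
    cfg = ReporterSimConfig(orfs=orfs, induction={}, noise_od=noise,
                            noise_gfp=noise, seed=seed)
    plate, _ = simulate_reporter_plate(cfg)
    res = analyze_plate(plate)
    return {"n_activated": int(res["peli_table"]["activated"].sum()),
            "n_orfs": n_orfs}
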