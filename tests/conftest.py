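import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture()
def tiny_array_experiment():
    """2 treatment + 3 control arrays, 6 gene probes + 4 null features."""
    from fitscreen.dssa import ArrayExperiment

    rng = np.random.default_rng(7)
    genes = [f"G{i}" for i in range(6)]
    probes = pd.DataFrame(
        {
            "gene_id": genes + [""] * 4,
            "is_null_feature": [False] * 6 + [True] * 4,
        },
        index=[f"P{i}" for i in range(6)] + [f"N{i}" for i in range(4)],
    )
    cols = {}
    meta = []
    for aid, arm, rep in [
        ("T1", "treatment", 1),
        ("T2", "treatment", 2),
        ("C1", "control", 1),
        ("C2", "control", 2),
        ("C3", "control", 3),
    ]:
        cols[aid] = rng.lognormal(8, 0.3, 10)
        meta.append(
            {"array_id": aid, "dose_uM": 330.0 if arm == "treatment" else 0.0,
             "generations": 5, "arm": arm, "replicate": rep}
        )
    return ArrayExperiment(
        intensities=pd.DataFrame(cols, index=probes.index),
        probes=probes,
        arrays=pd.DataFrame(meta).set_index("array_id"),
        saturation_ceiling=60000.0,
    )


@pytest.fixture(scope="session")
def growth_plate():
    """Constant-blank plate: 2 strains x 2 doses x 2 replicates + blanks."""
    from fitscreen.growth import GrowthCurveSet

    times = np.arange(0, 24.01, 0.25)
    rows, meta = [], []
    w = 0
    for strain in ("WT",):
        for dose, level in [(0.0, 0.6), (100.0, 0.45)]:
            for rep, offset in [(1, -0.02), (2, 0.02)]:
                rows.append(np.full_like(times, 0.05 + level + offset))
                meta.append({"well": f"W{w}", "strain": strain, "dose_uM": dose,
                             "replicate": rep, "role": "sample"})
                w += 1
    for rep in (1, 2):
        rows.append(np.full_like(times, 0.05))
        meta.append({"well": f"W{w}", "strain": "", "dose_uM": 0.0,
                     "replicate": rep, "role": "blank"})
        w += 1
    return GrowthCurveSet(times=times, od=np.vstack(rows),
                          wells=pd.DataFrame(meta))
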