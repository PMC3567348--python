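"""fitscreen: chemical-genetic fitness-screen analysis.

Analysis of pooled yeast deletion-strain barcode screens (differential
strain sensitivity analysis), plate-reader growth curves (AUC, ICx),
hypergeometric gene-set enrichment with custom reference sets, and
real-time GFP stress-reporter quantification (PELI), together with
seeded synthetic-data generators that provide ground truth for every
stage.
"""

from importlib import resources

from . import dssa, enrichment, growth, io, reporter, simulate
from .dssa import ArrayExperiment, gene_binomial_calls, run_dssa
from .enrichment import AnnotationDB, enrich, hypergeom_tail, read_gmt
from .growth import (
    GrowthCurveSet,
    auc,
    compare_groups,
    convert_concentration,
    correct_and_average,
    estimate_icx,
    inhibition_profile,
)
from .reporter import ReporterPlate, analyze_plate, peli
from .simulate import (
    PoolSimConfig,
    ReporterSimConfig,
    simulate_growth_doseresponse,
    simulate_pool_screen,
    simulate_reporter_plate,
)

__version__ = "0.1.0"


def stress_library_path() -> str:
    """Path to the bundled stress-response reporter library GMT.

    Five stress-pathway categories (general, oxidative, chemical,
    protein, DNA stress) whose union is the reporter library used as a
    custom enrichment reference.
    """
    return str(resources.files("fitscreen.data") / "stress_library.gmt")


def go_stress_subsets_path() -> str:
    """Path to the bundled GMT of small GO categories within the
    stress library (fully-membered categories only)."""
    return str(resources.files("fitscreen.data") / "go_stress_subsets.gmt")
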