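import numpy as np
import pytest

import cinscore as cs
from cinscore import synthetic
from cinscore.peak_io import NORMAL, TUMOUR, GenotypeCall, PeakRecord


@pytest.fixture(scope="session")
def panel():
    return cs.load_default_panel()


@pytest.fixture(scope="session")
def arm_model():
    return cs.load_default_arm_model()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """Small matched cohort: 20 normals for calibration, 40 tumour cases."""
    cfg = synthetic.GeneratorConfig(seed=42, n_normals=20, n_tumours=40)
    return synthetic.generate_cohort(cfg, panel)


def het_call(tissue: str, marker: str, area_short: float, area_long: float,
             sizes=(150.0, 158.0), sample_id: str = "S1") -> GenotypeCall:
    return GenotypeCall(
        sample_id, tissue, marker,
        ((sizes[0], area_short), (sizes[1], area_long)), "heterozygous",
    )


@pytest.fixture
def make_het_call():
    return het_call


def peaks_for_pair(marker: str, n_areas, t_areas, sizes=(150.0, 158.0), case="GC1"):
    """Peak records for one matched normal/tumour heterozygous marker."""
    recs = []
    for tissue, (a_s, a_l) in ((NORMAL, n_areas), (TUMOUR, t_areas)):
        recs.append(PeakRecord(case, tissue, marker, sizes[0], a_s))
        recs.append(PeakRecord(case, tissue, marker, sizes[1], a_l))
    return recs


@pytest.fixture
def make_pair_peaks():
    return peaks_for_pair
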