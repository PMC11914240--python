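import numpy as np
import pytest

from plaquekit.data_model import Frame, Modality, SegmentRecord


def make_frame(position, lumen, vessel, modality=Modality.NIRS_IVUS,
               subject="S0", vessel_id="V0", bins=None, tissue_areas=None,
               n_bins=360):
    tb = np.zeros(n_bins, dtype=np.uint8) if bins is None else bins
    return Frame(
        subject_id=subject, vessel_id=vessel_id, modality=modality,
        position=float(position), lumen_area=float(lumen),
        vessel_area=float(vessel), tissue_bins=tb, tissue_areas=tissue_areas,
    )


def make_segment(positions, lumens, vessels, **kw):
    return SegmentRecord(
        [make_frame(p, l, v, **kw) for p, l, v in zip(positions, lumens, vessels)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_cohort():
    from plaquekit.synthetic import SyntheticCohortSpec, generate_cohort

    spec = SyntheticCohortSpec(
        n_subjects=6, vessels_per_subject=2, frames_per_segment=40, seed=7
    )
    return generate_cohort(spec)
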