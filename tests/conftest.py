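import numpy as np
import pytest

from tbiqmri.protocol import AcquisitionProtocol
from tbiqmri.phantom import PhantomSpec, build_phantom, default_effect_table


@pytest.fixture(scope="session")
def small_protocol():
    """Reduced 64x64 grid keeping the full condition lists."""
    return AcquisitionProtocol(matrix=64)


@pytest.fixture(scope="session")
def severe_phantom(small_protocol):
    spec = PhantomSpec(protocol=small_protocol, severity="severe", timepoint="3d")
    return build_phantom(spec, default_effect_table())


@pytest.fixture(scope="session")
def sham_phantom(small_protocol):
    spec = PhantomSpec(protocol=small_protocol, severity="sham", timepoint="1d")
    return build_phantom(spec, default_effect_table())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def cohort_table():
    """Long-format cohort table built from per-subject truth ROI values
    (plus measurement jitter), bypassing image reconstruction for speed."""
    import pandas as pd
    from tbiqmri.cohort import CohortSpec, draw_cohort_outcomes
    from tbiqmri.phantom import PhantomSpec, build_phantom
    from tbiqmri.roi import build_cohort_table

    spec = CohortSpec(group_sizes={"sham": 4, "mild": 4, "moderate": 4, "severe": 4},
                      early_sacrifice={"sham": 1, "mild": 1, "moderate": 1, "severe": 1},
                      protocol=AcquisitionProtocol(matrix=48))
    gen = np.random.default_rng(2024)
    subjects, manifest, outcomes, _, _ = draw_cohort_outcomes(spec, gen)
    rows = []
    for subj in subjects:
        for tp in spec.timepoints:
            pspec = PhantomSpec(protocol=spec.protocol, severity=subj.group,
                                timepoint=tp, effect_scale=subj.effect_scale)
            truth, _ = build_phantom(pspec, spec.effects)
            for roi, params in truth.roi_truth.items():
                if roi == "other_brain":
                    continue
                for metric, val in params.items():
                    jitter = gen.normal(0, 0.02 * (abs(val) + 1e-3))
                    rows.append({"subject_id": subj.subject_id, "timepoint": tp,
                                 "roi_name": roi, "metric_name": metric,
                                 "mean": val + jitter, "sd": 0.0,
                                 "n_valid_voxels": 10})
    stats = pd.DataFrame(rows)
    return build_cohort_table(stats, manifest, outcomes)
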