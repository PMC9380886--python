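"""Simulate one subject's raw stacks and reconstruct all six maps.

Prints reconstructed ROI means against ground truth. With protocol noise
at SNR 40, ROI means land within a few percent of truth.
"""

import numpy as np

from tbiqmri import AcquisitionProtocol, PhantomSpec, build_phantom, roi_mean
from tbiqmri.phantom import simulate_subject_stacks
from tbiqmri.cohort import SubjectImageSet
from tbiqmri.pipeline import fit_subject_maps

protocol = AcquisitionProtocol(matrix=96)  # reduced grid for a quick demo
spec = PhantomSpec(protocol=protocol, severity="moderate", timepoint="1d")
truth, rois = build_phantom(spec)
stacks = simulate_subject_stacks(truth, np.random.default_rng(7))
subject = SubjectImageSet("MO01", "1d", protocol, stacks)

maps = fit_subject_maps(subject)
print(f"failed maps: {maps['failed'] or 'none'}")
print(f"{'metric':<7}{'ROI':<20}{'fitted':>10}{'truth':>10}")
for metric in ("t1", "t2", "adc", "cbf", "aptw", "mtr"):
    for roi in ("core", "ipsi_cortex", "contra_cortex"):
        fitted = roi_mean(maps[metric], rois, roi).mean
        tru = truth.roi_truth[roi][metric]
        print(f"{metric:<7}{roi:<20}{fitted:>10.3g}{tru:>10.3g}")

# Core CBF is depressed (moderate injury, day 1: 100 - 45 = 55) and core
# APTw reads ~ -3.5% versus -2.0% contralaterally, the acute deficit the
# protocol is designed to detect.
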