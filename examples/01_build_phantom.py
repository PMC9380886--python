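"""Build a digital phantom and inspect its ground-truth regional values.

A severe contusion at 3 days: the perilesion cortex shows elevated APTw
(+2.5% over the contralateral side), T1 is up and MTR down across
ipsilateral regions, and the core retains a perfusion deficit.
"""

from tbiqmri import PhantomSpec, build_phantom

spec = PhantomSpec(severity="severe", timepoint="3d")
truth, rois = build_phantom(spec)

print(f"grid: {truth.label_map.shape}, brain voxels: {truth.brain.sum()}")
print(f"{'region':<20}{'T1 (s)':>8}{'T2 (ms)':>9}{'ADC':>10}{'CBF':>7}"
      f"{'APTw %':>8}{'MTR %':>7}")
for name in rois.names:
    t = truth.roi_truth[name]
    print(f"{name:<20}{t['t1']:>8.2f}{t['t2']:>9.1f}{t['adc']:>10.2e}"
          f"{t['cbf']:>7.0f}{t['aptw']:>8.2f}{t['mtr']:>7.1f}")

# The printed table is the ground truth the reconstruction pipeline is
# judged against: e.g. ipsi_cortex APTw (-2.0 + 2.5 = +0.5%) exceeds
# contra_cortex (-2.0%) by the configured 3-day perilesion shift.
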