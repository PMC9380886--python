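"""End-to-end run: simulate a small cohort, fit every map, extract ROI
statistics, and produce the statistical report - all from one config.

Writes CSV outputs under scratch/example_run/ and prints the
pre-registered correlation table. Rerunning with the same seed
reproduces identical files (checksums in run_manifest.json).
"""

import pandas as pd

from tbiqmri import run_all

config = {
    "seed": 7,
    "protocol": {"matrix": 64},
    "cohort": {
        "group_sizes": {"sham": 3, "mild": 3, "moderate": 3, "severe": 3},
        "early_sacrifice": {"sham": 0, "mild": 1, "moderate": 1, "severe": 1},
        "timepoints": ["1h", "1d", "3d"],
    },
}

manifest = run_all(config, "scratch/example_run")
print(f"pipeline finished in {manifest['runtime_s']}s; "
      f"{manifest['n_image_sets']} image sets reconstructed")

corr = pd.read_csv("scratch/example_run/stats_correlations.csv")
print(corr[["metric_name", "roi_name", "timepoint", "outcome", "r", "p_value"]]
      .to_string(index=False))
# At this demo scale (12 subjects, behavior n = 9, histology n = 3) the
# correlations are noisy and individual signs can flip; the configured
# pattern - core APTw@1d negative vs mNSS/escape time, positive vs
# sucrose preference, perilesion APTw@3d positive vs Iba1 - emerges
# reliably at the full 56-subject design (see examples/04).
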