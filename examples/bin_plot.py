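"""Render a bin plot: the gridded SSC/FcεRIα plane with CD63 statistics.

Generates a stimulated synthetic sample, calibrates on the matching
unstimulated tube, computes per-bin and quadrant statistics and writes an
SVG with the black quadrant frequencies and the red CD63+ percentage in
the basophil (upper-left) quadrant.
"""

from binbat import (
    BinStatistic,
    Condition,
    SyntheticProfile,
    WorkflowConfig,
    bin_statistics,
    calibrate,
    generate_sample,
    quadrant_statistics,
    render_bin_plot,
)
from binbat.workflow import prepare_sample

cfg = WorkflowConfig()
profile = SyntheticProfile(allergic=True, responder=True)
unstim, _ = generate_sample(profile, Condition.UNSTIM, 50_000, seed=11)
stim, _ = generate_sample(profile, Condition.POS_CTRL, 50_000, seed=12)

gated_unstim = prepare_sample(unstim, cfg)
thresholds, _ = calibrate(gated_unstim, "unstim", cfg.calibration)
gated_stim = prepare_sample(stim, cfg)

grid = thresholds.grid()
stats = bin_statistics(gated_stim, grid, "CD63", thresholds.thr_cd63)
quad = quadrant_statistics(gated_stim, grid, "CD63", thresholds.thr_cd63,
                           thresholds.target_quadrant)
out = render_bin_plot(stats, quad, "scratch/binplot_posctrl.svg",
                      statistic=BinStatistic.FREQ,
                      title="positive control, CD63+ frequency per bin")

print(f"wrote {out}")
print(f"quadrant frequencies (% of gated events): {dict(quad.q_freq)}")
print(f"red percentage (CD63+ of basophil quadrant): {quad.zpos_pct_target:.2f}%")
print()
print("Bins are coloured blue (sample minimum) to red (sample maximum) by the")
print("CD63+ frequency; bins with fewer than 10 events are grey.")
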