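"""Measure the hypercapnic ventilatory response (HCVR).

The animal breathes room air for 5 min, then 8% CO2 for 5 min; minute
ventilation is averaged over each plateau (excluding the first 60 s after
the gas switch, wake epochs only) and the HCVR is the least-squares slope
of VE on inspired CO2 %.
"""

from somnoresp import run_hcvr
from somnoresp.synth import HypnogramParams, SynthConfig, generate_recording

cfg = SynthConfig(seed=7, duration_s=600.0)
cfg.hypnogram = HypnogramParams(
    bout_mean_s={"W": 1e9, "NREM": 100.0, "REM": 60.0},
    transition_weights={"W": {}, "NREM": {"W": 1.0}, "REM": {"W": 1.0}},
    initial_stage="W",
)
cfg.co2_protocol = [(0.0, 300.0), (8.0, 300.0)]
cfg.hcvr_gain = 7.5  # mL/min of extra VE per % inspired CO2
rec, truth = generate_recording(cfg)

res = run_hcvr(rec, cfg.co2_protocol, hypnogram=truth.hypnogram_true)
for pct, ve in zip(res.levels_pct, res.ve_ml_min):
    print(f"VE at {pct:.0f}% CO2: {ve:.1f} mL/min")
print(f"HCVR slope: {res.slope:.2f} mL/min per %CO2 (configured {cfg.hcvr_gain})")
print(f"intercept:  {res.intercept:.1f} mL/min, R^2 = {res.r_squared:.4f}")
# The slope is the chemoreflex sensitivity; a blunted slope is the hallmark
# of hypoventilation phenotypes.
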