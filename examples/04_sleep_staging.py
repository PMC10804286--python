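"""Score sleep stages from EEG/EMG and summarize sleep architecture.

5-s epochs are staged from EEG band powers (2-5 Hz NREM, 5-10 Hz REM,
10-20 Hz wake) and EMG tone; thresholds self-calibrate per recording.
"""

from somnoresp import SynthConfig, architecture_summary, generate_recording, stage_recording
from somnoresp.staging import staging_accuracy

rec, truth = generate_recording(SynthConfig(seed=11, duration_s=600.0))
hyp, _features = stage_recording(rec)

acc = staging_accuracy(hyp, truth.hypnogram_true)
arch = architecture_summary(hyp)
print(f"epoch accuracy vs generator truth: {acc:.3f} over {len(hyp)} epochs")
print(f"total sleep time: {arch.total_sleep_s:.0f} s")
for stage in ("W", "NREM", "REM"):
    print(
        f"  {stage:5s} {arch.stage_seconds[stage]:6.0f} s in "
        f"{arch.bout_counts[stage]:3d} bouts (mean {arch.bout_mean_s[stage]:.0f} s)"
    )
# The stager is an automated rendering of the standard visual criteria; an
# externally scored hypnogram can replace it anywhere in the pipeline.
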