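"""Open-circuit indirect calorimetry: VO2, VCO2, RER and coupling ratios.

Gas fractions sampled every 11 min are converted to oxygen consumption and
CO2 production with the Haldane transformation; the respiratory exchange
ratio RER = VCO2/VO2 indexes substrate utilization, and VE/VO2, VE/VCO2
quantify how breathing scales with metabolism.
"""

from somnoresp import Recording, coupling_ratios
from somnoresp.metabolism import summarize_recording
from somnoresp.synth import SynthConfig, generate_metabolic_traces

cfg = SynthConfig(seed=9, duration_s=6 * 660.0)  # six 11-min bins
cfg.metabolism.vo2_ml_h = 60.0
cfg.metabolism.rer = 0.85

rec = Recording()
for ch in generate_metabolic_traces(cfg).values():
    rec.add(ch)
ms = summarize_recording(rec, cfg.metabolism.chamber_flow_ml_h)

print(f"VO2  = {ms.vo2_ml_h:.2f} mL/h (configured {cfg.metabolism.vo2_ml_h})")
print(f"VCO2 = {ms.vco2_ml_h:.2f} mL/h")
print(f"RER  = {ms.rer:.3f} (configured {cfg.metabolism.rer})")
print(f"beam breaks: {ms.activity_total:.0f}")

ve_ml_min = 22.5  # minute ventilation from the matched sleep study
r_o2, r_co2 = coupling_ratios(ve_ml_min, ms.vo2_ml_h, ms.vco2_ml_h)
print(f"VE/VO2 = {r_o2:.1f}, VE/VCO2 = {r_co2:.1f}")
# A rise in VE/VCO2 means breathing is stimulated out of proportion to
# metabolic CO2 production.
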