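"""Convert a chamber-pressure trace to tidal volume (barometric method).

Whole-body plethysmography measures breathing as pressure fluctuations in a
sealed chamber.  The conversion to volume needs rectal/chamber/room
temperatures, humidity, barometric pressure, and the deflection of a
known-volume calibration injection.
"""

import numpy as np

from somnoresp import (
    CalibrationContext,
    differentiate_volume,
    drorbaugh_fenn_factor,
    pressure_to_volume,
)

ctx = CalibrationContext(
    v_k=0.05,            # 50 uL calibration injection
    p_k=1.0,             # produced 1.0 units of pressure deflection
    t_body_k=310.15,     # rectal 37.0 degC
    t_chamber_k=302.15,  # chamber 29.0 degC
    t_room_k=296.15,
    humidity=0.9,
    p_baro_mmhg=760.0,
)
factor = drorbaugh_fenn_factor(ctx)
print(f"barometric conversion factor F = {factor:.3f}")

fs = 1000.0
t = np.arange(int(2 * fs)) / fs
pressure = 0.02 * np.sin(2 * np.pi * 2.5 * t)  # breathing at 150/min
volume = pressure_to_volume(pressure, ctx)
flow = differentiate_volume(volume, fs)
print(f"pressure amplitude {pressure.max():.3f} -> VT amplitude {volume.max():.4f} mL")
print(f"peak inspiratory flow {flow.max():.3f} mL/s")
# F > 1 amplifies the tiny pressure signal into physiological volumes; flow
# is the time derivative of volume and is what breath scoring operates on.
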