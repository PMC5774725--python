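"""The 10 depolarization predictors of a constructed beat.

Builds a beat with known ground truth - fiducials at -36 / +48 ms, source
depth 7.5 cm, moment along (0.6, 0.8) - and checks that the extracted
predictor vector recovers each construction parameter: intervals from the
fiducials, pole distance sqrt(2)*depth, unit MMR, and a map angle
perpendicular to the moment.
"""

import numpy as np

import mcgkit as m

geometry = m.planar_grid()
direction = np.array([0.6, 0.8, 0.0])
source = m.DipoleSource(position=[0.005, -0.01, -0.075], moment_direction=direction)
template = m.BeatTemplate(tq_ms=-36.0, ts_ms=48.0)
beat = m.synthesize_beat(template, source, geometry)

vec = m.extract_predictors(beat)
expected_angle = np.degrees(np.arctan2(direction[0], -direction[1]))

print(f"{'predictor':<12} {'value':>8}   expected")
print(f"{'QR_interval':<12} {vec.QR_interval:8.1f}   36 ms (construction)")
print(f"{'RS_interval':<12} {vec.RS_interval:8.1f}   48 ms (construction)")
print(f"{'QR_pd':<12} {vec.QR_pd:8.2f}   sqrt(2)*7.5 = {np.sqrt(2) * 7.5:.2f} cm")
print(f"{'QR_MMR':<12} {vec.QR_MMR:8.3f}   1 (symmetric source)")
print(f"{'QR_angle':<12} {vec.QR_angle:8.1f}   {expected_angle:.1f} deg (perpendicular to moment)")
print(f"{'QR_peak':<12} {vec.QR_peak:8.1f}   pT (field scale at the QR-section instant)")
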