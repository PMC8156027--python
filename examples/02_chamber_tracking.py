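"""Classify a swim path into chamber zones via the synthetic camera.

The baseline Skinner-tank chamber (12 x 16 cm) is divided into a starting
area, a corridor, a V-shaped decision funnel, and two choice areas; a
below-tank camera tracks the fish. Here a straight crossing is rendered
frame by frame, positions are recovered by centroid detection, and the
debounced zone-entry events are printed.
"""

from skinnertank.chamber import (chamber_geometry, detect_centroid,
                                 synthesize_frame, trace_to_events, zone_of)

geom = chamber_geometry("B")
print(f"variant B: {geom.width} x {geom.length} cm, start->choice distance "
      f"{geom.measured_start_choice_distance():.1f} cm")

# a fish swimming from the start area into the left choice area
trace = []
for i in range(1, 150):
    t = 0.1 * i
    true_pos = (5.0, 0.8 + 0.1 * i)
    frame = synthesize_frame(true_pos, geom, noise_sigma=4.0, noise_seed=i)
    trace.append((t, detect_centroid(frame)))

events = trace_to_events(trace, geom, min_dwell=0.2)
for e in events:
    print(f"t = {e.timestamp:5.1f} s  entered {e.zone}")
final = trace[-1][1]
print(f"final tracked position ({final[0]:.2f}, {final[1]:.2f}) cm -> zone "
      f"{zone_of(final, geom)}")
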