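"""Build the default pen geometry and query it.

The pen is 1.80 x 2.61 m, covered by 30 subfloor RFID antennas (32 x 41 cm)
labelled A1..F5; feeders sit on E1/F1/E5/F5, the drinker on D1, and antenna
A2 is defective. Image pixels convert to centimeters with a single global
scale factor (0.2199 cm/px).
"""

from pentrack import (
    antenna_center_distance_m,
    build_default_geometry,
    locate_antenna,
    px_to_cm,
)
from pentrack.pen_model import PointPx

geom = build_default_geometry()

print(f"antennas: {len(geom.antennas)}, defective: {sorted(geom.defective_labels)}")
print(f"100 px = {px_to_cm(100, geom):.2f} cm, 128 px = {px_to_cm(128, geom):.2f} cm")

d3 = geom.antennas["D3"]
print(f"center of D3 lies on antenna: {locate_antenna(d3.center_px, geom)}")
print(f"a point in the wall margin lies on: {locate_antenna(PointPx(1, 1), geom)}")
print(f"D3 -> D4 center distance: {antenna_center_distance_m('D3', 'D4', geom):.3f} m")
print(f"mean enclosing-circle radius: {geom.mean_enclosing_radius_px():.1f} px")
# The center distance is the step the RFID system records for one antenna
# switch; the enclosing radius is the natural 'same location' scale.
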