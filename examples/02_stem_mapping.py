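"""Locate a tree in the plot from four UWB anchor ranges plus altitudes.

Corner anchors A-D are surveyed once (altitudes + slope distances); each
tree observation is four tag-to-anchor slope ranges and the device
altitude.  Slope distances are projected into the horizontal plot plane,
every anchor triple gives a trilateration point (the radical centre of its
three range circles), and the four points are fused with inverse-total-
range weights — triples with shorter ranges (stronger signal) count more.
"""

import math

from stemsurvey import AnchorSurvey, TagRanges, build_frame, locate

# survey of a 10 x 10 m plot on a ~17-degree slope rising along +x
# (terrain z = 0.3 x; distances are true 3-D corner-to-corner values)
survey = AnchorSurvey(
    H_A=0.0, H_B=300.0, H_C=300.0, H_D=0.0,             # altitudes, cm
    Dis_AB=1044.0307, Dis_AC=1445.6832, Dis_AD=1000.0,  # slope distances, cm
    Dis_BC=1000.0, Dis_BD=1445.6832, Dis_CD=1044.0307,
)
frame = build_frame(survey)
print("planar anchor frame (cm):")
for k in "ABCD":
    x, y = frame.coords(k)
    print(f"  {k}: ({x:8.2f}, {y:8.2f})")

# a tree at (420, 640) cm, device resting at its base (z = 126 cm)
tag = TagRanges(A_n=775.81, B_n=881.07, C_n=704.47, D_n=567.34, H_n=126.0)
pos = locate(frame, survey, tag)
print(f"\ntrilateration points: " + ", ".join(f"({q[0]:.0f}, {q[1]:.0f})" for q in pos.Q))
print(f"fused position: ({pos.X_n:.1f}, {pos.Y_n:.1f}) cm from anchor A")
print("(each point comes from one anchor triple; the fused point is their "
      "range-weighted mean and lies inside their convex hull)")
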