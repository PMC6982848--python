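"""Estimate a tree's DBH from the two angle-sensor readings.

The caliper frame is pressed against the stem: the vertex touches the bark
at the beam middle and each arm swings until its face rests on the trunk,
giving contact angles alpha1 and alpha2.  Each angle fixes one tangent arc;
DBH is the sum of the two arc radii, so an eccentric stem (different arcs
on the two sides) is handled without assuming a circular cross-section.
"""

from stemsurvey import AnglePair, DeviceGeometry, average_dbh, dbh_from_angles

geom = DeviceGeometry()  # production constants: s=15, w=2.5, h=3.5 cm

# a symmetric stem touching both arms at right angles
est = dbh_from_angles(geom, AnglePair(alpha1=90.0, alpha2=90.0))
print(f"symmetric 90/90 contact: r1={est.r1:.2f} cm, r2={est.r2:.2f} cm, "
      f"DBH={est.dbh_mm:.1f} mm")

# an eccentric stem: the two sides subtend different angles
m1 = dbh_from_angles(geom, AnglePair(alpha1=95.0, alpha2=82.0))  # major axis
m2 = dbh_from_angles(geom, AnglePair(alpha1=88.0, alpha2=89.5))  # minor axis
print(f"direction 1 (major): r1={m1.r1:.2f}, r2={m1.r2:.2f} -> {m1.dbh_mm:.1f} mm")
print(f"direction 2 (minor): r1={m2.r1:.2f}, r2={m2.r2:.2f} -> {m2.dbh_mm:.1f} mm")

# the field protocol measures twice (major/minor) and averages
print(f"recorded DBH (mean of the two directions): {10 * average_dbh(m1, m2):.1f} mm")
# The per-direction values differ because the stem is eccentric; their mean
# is the conventional caliper-style DBH entered in the inventory record.
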