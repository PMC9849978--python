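"""The full three-wave study analogue on the bundled demo city.

A 7 x 7 km synthetic metropolis of 250,000 people with clustered
deprivation receives nested facility waves of 29, 33 and 78 health
centres (1996 / 2006 / 2016).  The pipeline scores poverty, runs the
pattern statistics per wave and tabulates walking-time access.
Runtime: roughly ten seconds.
"""

from spatialaccess import demo_study_config, run_pipeline

report = run_pipeline(demo_study_config(seed=7))

print(f"walking cutoff: {report.walk['cutoff_min']} min "
      f"({report.walk['radius_m']} m at {report.walk['speed_m_s']} m/s)")
pm = report.poverty_moran
print(f"poverty Moran's I: {pm['i']:.3f} (z = {pm['z']:.1f}) -> clustered\n")

print(f"{'year':>4s} {'facilities':>10s} {'ANN':>6s} {'ANN z':>6s} {'no access %':>12s}")
for w in report.waves:
    print(f"{w['year']:4d} {w['n_facilities']:10d} {w['ann']['ann']:6.2f} "
          f"{w['ann']['z']:6.2f} {w['access']['no_access_pct']:12.2f}")

print()
print("Facilities are placed at random (ANN ~ 1, |z| < 1.96) while poverty is")
print("strongly clustered (Moran z >> 1.96); as nested waves add facilities,")
print("the share of residents beyond a 12.5-minute walk falls monotonically.")
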