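"""Scan patterns, exact timing and line-synchronised command waveforms.

Builds the activity-scan rasters with their printed frame rates, a
two-region random-access pattern (with blanked transition lines), a bent
"halfpipe" plane, and shows the tunable-lens settling transient.
"""

import numpy as np

from ntcsim import scan
from ntcsim.scan import ScanRegion, ZProfile

print("Raster frame rates (line period includes the turnaround):")
for n, per in [(256, 1.0), (128, 1.0), (170, 1.0), (64, 1.0), (1024, 2.0)]:
    r = scan.timing_report(scan.build_raster(n, n, per))
    print(f"  {n:5d} lines @ {per} ms  ->  {r.frame_rate_hz:7.4f} Hz")

planes = ZProfile.multiplane([15.0 * i for i in range(6)])
vol = scan.timing_report(scan.build_raster(6 * 170, 340, 1.0, z_profile=planes))
print(f"  six 170-line planes 15 um apart -> {vol.per_plane_rate_hz:.4f} Hz volume rate")

ra = scan.build_random_access(
    [ScanRegion(128, 128, 1.0, origin_um=(-500, 0)), ScanRegion(128, 128, 1.0, origin_um=(500, 0))],
    transition_lines=2,
)
t = scan.timing_report(ra)
print(f"\nRandom access, two 128-line regions 1 mm apart, 2 blanked lines per jump:")
print(f"  cycle {t.cycle_duration_ms:.0f} ms -> {t.frame_rate_hz:.2f} Hz "
      f"({t.active_rate_hz:.2f} Hz counting active lines only)")

wf = scan.emit_waveforms(ra, sample_rate_hz=100_000.0, turnaround_fraction=0.1)
blanked = 1.0 - wf.active_mask.mean()
print(f"  {wf.x_galvo.size} samples; Pockels blanked on {blanked:.1%} of them "
      "(turnarounds, retrace and transitions)")

hp = scan.build_raster(257, 256, 1.0, z_profile=ZProfile.halfpipe(100.0))
z = scan.apply_z_profile(hp.regions[0])
print(f"\nHalfpipe plane, 100 um peak: command 0 um at the first/last line, "
      f"{z.max():.0f} um at line {int(np.argmax(z))} (sqrt-cosine of the slow axis).")

settle, _ = scan.etl_transient(150.0, threshold_um=5.0)
print(f"\nETL 150 um step settles to within 5 um in {settle:.2f} ms "
      "(second-order transient; jumps are paid once per z-step, not per pixel).")
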