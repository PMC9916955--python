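"""Round-tripping tracker exports and binning activity.

Writes a simulated cohort to the self-describing tracking CSV dialect,
reads it back, bins one trajectory into 1-s windows and computes a metric
from the file-loaded data — the same path real Zebrabox-style exports take.
"""

import tempfile
from pathlib import Path

from swimmetrics.arena import assign_zones, make_equal_area_well
from swimmetrics.io import bin_activity, read_tracking, write_tracking
from swimmetrics.metrics import center_distance_ratio, velocity
from swimmetrics.protocol import larval_light_dark
from swimmetrics.simulate import SimulationSpec, larval_ld_presets, simulate

arena = make_equal_area_well(8.0)
protocol = larval_light_dark(habituation=60)
ds = simulate(SimulationSpec(arena=arena, protocol=protocol, n_per_genotype=2,
                             seed=1, presets=larval_ld_presets(), speed_scale=0.1))

path = Path(tempfile.mkdtemp()) / "larvae.csv"
write_tracking(ds, path)
loaded = read_tracking(path)
print(f"wrote and re-read {path.name}: {len(loaded.subjects)} subjects, "
      f"{len(loaded.tracks)} samples")

sid = loaded.subject_ids[0]
traj = loaded.track_for(sid)
bins = bin_activity(traj, dt=1.0)
za = assign_zones(traj, arena)
print(f"{sid}: velocity {velocity(traj=traj):.2f} mm/s, "
      f"total distance {bins['distance'].sum():.1f} mm, "
      f"center distance ratio (D1) "
      f"{center_distance_ratio(za, window=protocol.phase_window('D1')):.3f}")

# The center distance ratio is the fraction of swim distance inside the
# inner, equal-area circle of the well during the dark phase; low values
# mean wall-hugging (larval thigmotaxis = 1 - ratio).
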