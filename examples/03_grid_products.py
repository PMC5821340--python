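"""Dense prediction products: horizontal slice and 2 mg/L iso-depth surface.

Fits the hybrid model on a synthetic survey, predicts DO on a 50 x 50
horizontal grid at mid-window and 1 m depth, and extracts the surface of
shallowest depth at which DO falls to 2 mg/L — the hypoxia line a farm
manager watches.
"""

import numpy as np

import oxypond as op

survey = op.sample_sensors(op.default_field_spec(seed=5), layout="random", n=100)
model, _ = op.fit(survey, target_k=21, bias=True)

slice_ = op.horizontal_slice(model, t=20.0, z=1.0, nx=50, ny=50)
print(f"DO slice at t=20 min, z=1.0 m: "
      f"{slice_.values.min():.3f}..{slice_.values.max():.3f} mg/L "
      f"(mean {slice_.values.mean():.3f})")

iso = op.iso_depth_surface(model, t=20.0, threshold=2.0, nx=50, ny=50, nz=33)
reached = iso.values[iso.values != op.NOT_REACHED]
print(f"2 mg/L line reached on {100 * reached.size / iso.values.size:.1f}% "
      f"of the pond columns")
if reached.size:
    print(f"crossing depth range {reached.min():.2f}..{reached.max():.2f} m "
          f"(median {np.median(reached):.2f} m)")

from pathlib import Path

out_dir = Path("scratch")
out_dir.mkdir(exist_ok=True)
op.export_grid(slice_, out_dir / "slice.csv")
op.export_grid(iso, out_dir / "iso_depth.csv")
print("grids written as long CSV (one row per node, y-outer/x-inner order)")
print("Shallow crossing depths mark where low-oxygen water sits close to")
print("the surface; deep or never-reached columns are well oxygenated.")
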