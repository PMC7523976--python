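#!/usr/bin/env python
"""Build the synthetic plaque phantom and document its geometry.

Generates the master contour stack of the idealized carotid segment
(eccentric plaque, large lipid core, fibrous cap with a local thin-cap dip,
0.5 mm offset outer wall), exports the contours and a legacy-VTK mesh of the
dip cross-section for inspection, and tabulates how slice-thickness
resampling degrades the minimum cap thickness.

Outputs under results/phantom/:
  cap_profile.csv           per-station minimum cap thickness
  st_degradation.csv        reconstructed minimum cap thickness vs ST
  dip_section.vtk           region-labelled mesh of the dip station
  contours/                 per-station contour tables + manifest
"""

import pathlib
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from plaquestress import phantom as ph
from plaquestress.vtk_io import write_vtk

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "phantom"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    spec = ph.PhantomSpec()
    stack = ph.build_phantom(spec)
    stack.save(OUT / "contours")

    prof = stack.cap_thickness_profile()
    pd.DataFrame({"z_mm": stack.z, "min_cap_thickness_mm": prof}).to_csv(
        OUT / "cap_profile.csv", index=False)
    print(f"phantom: {stack.n_stations} stations at {spec.axial_resolution} mm")
    print(f"  nominal cap {spec.cap_thickness} mm, "
          f"realized minimum {np.nanmin(prof):.4f} mm at z = "
          f"{stack.z[int(np.nanargmin(prof))]:.2f} mm")

    rows = []
    for st in (0.25, 0.5, 0.75, 1.0, 1.25, 1.5):
        rec = ph.resample_slices(stack, st)
        rows.append({"slice_thickness_mm": st,
                     "reconstructed_min_cap_mm": float(np.nanmin(rec.cap_thickness_profile()))})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "st_degradation.csv", index=False)
    print("\nslice-thickness degradation of the cap minimum:")
    print(df.to_string(index=False))
    print("-> a 1.5 mm axial resolution misses the local thin cap entirely")

    k = int(np.nanargmin(prof))
    mesh = ph.mesh_section(stack, k, ph.partition_wall(stack, 0.25))
    write_vtk(OUT / "dip_section.vtk", mesh)
    print(f"\ndip cross-section mesh: {mesh.n_elems} quads, "
          f"{mesh.wall_rings} rings across the wall -> {OUT / 'dip_section.vtk'}")


if __name__ == "__main__":
    main()
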