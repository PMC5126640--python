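"""State-history export: VTU time series, HDF5 container, CSV summary."""
from __future__ import annotations

import pathlib

import numpy as np

from ..vtkio import write_vtu
from .strain import state_fields


def write_state_history(out_dir, mesh, states, prefix: str = "state",
                        vtu_every: int = 1) -> dict:
    """Write a solved protocol history to ``out_dir``.

    Produces ``<prefix>_####.vtu`` snapshots (displacement and pore
    pressure point data, element-averaged parameter cell data),
    ``<prefix>.h5`` with ``/states/<index>/u``, ``/p``, per-parameter
    cell arrays and time metadata, and ``<prefix>_summary.csv`` with the
    scalar time series. Units: mm, MPa, N, s.
    """
    import h5py
    import pandas as pd

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"vtu": [], "h5": str(out / f"{prefix}.h5"),
             "csv": str(out / f"{prefix}_summary.csv")}
    rows = []
    ne = mesh.n_cells
    with h5py.File(paths["h5"], "w") as h5:
        h5.attrs["units"] = "mm, MPa, N, s"
        for k, s in enumerate(states):
            fields = state_fields(s)
            cell_data = {name: arr.reshape(ne, 8).mean(axis=1)
                         for name, arr in fields.items()}
            if k % vtu_every == 0:
                p = out / f"{prefix}_{k:04d}.vtu"
                write_vtu(p, mesh,
                          point_data={"displacement_mm": s.u, "pore_pressure_MPa": s.p},
                          cell_data=cell_data)
                paths["vtu"].append(str(p))
            g = h5.create_group(f"states/{k}")
            g.attrs["time_s"] = s.time_s
            g.attrs["stance_pct"] = s.stance_pct
            g.create_dataset("u", data=s.u)
            g.create_dataset("p", data=s.p)
            for name, arr in cell_data.items():
                g.create_dataset(name, data=arr)
            rows.append({
                "time_s": s.time_s, "stance_pct": s.stance_pct,
                "applied_force_N": s.applied_force_N,
                "indenter_dz_mm": s.indenter_dz_mm,
                "min_principal_strain": float(cell_data["min_principal_strain"].min()),
                "shear_strain": float(cell_data["shear_strain"].max()),
                "max_principal_stress_MPa": float(cell_data["max_principal_stress"].max()),
                "fibril_strain": float(cell_data["fibril_strain"].max()),
                "peak_pore_pressure_MPa": float(s.p.max()),
            })
    pd.DataFrame(rows).to_csv(paths["csv"], index=False)
    return paths
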