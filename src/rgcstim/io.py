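"""HDF5 and CSV export for traces, threshold maps and population maps."""

from __future__ import annotations

import h5py
import numpy as np

from .cable import SimulationTrace

__all__ = ["write_trace", "write_threshold_map", "trace_to_csv",
           "write_population_maps"]


def write_trace(trace: SimulationTrace, path) -> None:
    """Datasets: time, Vm[site], snapshots[t, compartment]."""
    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=trace.t)
        f.create_dataset("vm_mv", data=trace.vm)
        f.create_dataset("sites", data=trace.sites)
        if trace.first_cross_ms is not None:
            f.create_dataset("first_cross_ms", data=trace.first_cross_ms)
        if trace.snapshots:
            times = sorted(trace.snapshots)
            snap = np.stack([trace.snapshots[t] for t in times])
            f.create_dataset("snapshot_times_ms", data=np.asarray(times))
            f.create_dataset("snapshots_mv", data=snap)
        f.attrs["dt_ms"] = trace.dt


def trace_to_csv(trace: SimulationTrace, path, site: int | None = None) -> None:
    v = trace.soma if site is None else trace.at(site)
    np.savetxt(path, np.column_stack([trace.t, v]), delimiter=",",
               header="time_ms,vm_mv", comments="")


def write_threshold_map(tmap, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("positions_um", data=tmap.positions)
        f.create_dataset("threshold_ua", data=tmap.threshold)
        f.create_dataset("latency_ms", data=tmap.latency)
        f.create_dataset("initiation_comp", data=tmap.initiation_comp)
        f.attrs["electrode_radius_um"] = tmap.electrode_radius
        f.attrs["grid_step_um"] = tmap.grid.step
        f.attrs["grid_z_um"] = tmap.grid.z


def write_population_maps(pmaps, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("positions_um", data=pmaps.positions)
        f.create_dataset("threshold_ua", data=pmaps.threshold)
        f.create_dataset("n_active", data=pmaps.counts)
        ids = ["|".join(map(str, t)) for t in pmaps.identities]
        f.create_dataset("identities", data=np.array(ids, dtype="S"))
        f.attrs["electrode_radius_um"] = pmaps.electrode_radius


def field_grid_to_csv(electrode, path, *, extent=(-150.0, 150.0, -150.0, 150.0),
                      step=10.0, z=0.0, i_ua=1.0, profile=None):
    """Sample the electrode potential on an x-y grid and write x,y,ve_mv CSV.

    Useful for contour plots of the field at a given retinal depth ``z``.
    """
    from .field import transfer_vector

    x0, x1, y0, y1 = extent
    xs = np.arange(x0, x1 + step / 2, step)
    ys = np.arange(y0, y1 + step / 2, step)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
    ve = transfer_vector(pts, electrode, profile) * i_ua
    np.savetxt(path, np.column_stack([pts[:, 0], pts[:, 1], ve]),
               delimiter=",", header="x_um,y_um,ve_mv", comments="")
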