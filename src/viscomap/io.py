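"""Persistence: HDF5 strain histories, CSV curve sets, CSV/PNG maps, report CSV."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .curves import CreepCurve
from .exceptions import StructuralError
from .fem import (BoundaryConditionSpec, BottomFix, Coverage, LoadingProtocol,
                  SideFix, StrainFieldHistory, build_mesh)
from .maps import PropertyMap
from .sls import MaterialSpec

__all__ = [
    "save_history", "load_history",
    "curves_to_csv", "curves_from_csv",
    "map_to_csv", "map_to_png", "report_to_csv",
]


def save_history(path: str | Path, hist: StrainFieldHistory) -> None:
    """Write a StrainFieldHistory to an HDF5 container (config echoed as attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=hist.times)
        f.create_dataset("strains", data=hist.strains, compression="gzip", compression_opts=4)
        f.create_dataset("pressure", data=hist.pressure)
        f.create_dataset("reaction_residuals", data=hist.reaction_residuals)
        g = f.create_group("config")
        g.attrs.update({
            "radius": hist.mesh.radius, "thickness": hist.mesh.thickness, "h": hist.mesh.h,
            "E": hist.material.E, "nu": hist.material.nu,
            "g": hist.material.g, "tau_R": hist.material.tau_R,
            "p_max": hist.load.p_max, "ramp_time": hist.load.ramp_time,
            "hold_time": hist.load.hold_time, "coverage": hist.load.coverage.value,
            "bottom_fix": hist.bc.bottom_fix.value, "side_fix": hist.bc.side_fix.value,
        })


def load_history(path: str | Path) -> StrainFieldHistory:
    with h5py.File(path, "r") as f:
        a = dict(f["config"].attrs)
        mesh = build_mesh(float(a["radius"]), float(a["thickness"]), float(a["h"]))
        material = MaterialSpec(E=float(a["E"]), nu=float(a["nu"]),
                                g=float(a["g"]), tau_R=float(a["tau_R"]))
        load = LoadingProtocol(p_max=float(a["p_max"]), ramp_time=float(a["ramp_time"]),
                               hold_time=float(a["hold_time"]),
                               coverage=Coverage(str(a["coverage"])))
        bc = BoundaryConditionSpec(bottom_fix=BottomFix(str(a["bottom_fix"])),
                                   side_fix=SideFix(str(a["side_fix"])))
        return StrainFieldHistory(times=f["times"][...], strains=f["strains"][...],
                                  pressure=f["pressure"][...], mesh=mesh,
                                  material=material, load=load, bc=bc,
                                  reaction_residuals=f["reaction_residuals"][...])


def curves_to_csv(path: str | Path, curves: list[CreepCurve]) -> None:
    """Long-format CSV: element_i, element_j, t, eps_zz (one row per sample)."""
    frames = []
    for c in curves:
        if c.element is None:
            raise StructuralError("curves need element indices for CSV round-trip")
        frames.append(pd.DataFrame({
            "element_i": c.element[0], "element_j": c.element[1],
            "t": c.times, "eps_zz": c.eps_zz,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def curves_from_csv(path: str | Path, sigma0: float,
                    ramp_time: float = 0.0) -> list[CreepCurve]:
    """Read curves written by :func:`curves_to_csv`.

    The CSV stores only the sampled strains; the applied pressure and the
    preceding ramp duration are metadata supplied by the caller.
    """
    df = pd.read_csv(path)
    curves = []
    for (i, j), sub in df.groupby(["element_i", "element_j"], sort=True):
        sub = sub.sort_values("t")
        curves.append(CreepCurve(times=sub["t"].to_numpy(),
                                 eps_zz=sub["eps_zz"].to_numpy(),
                                 sigma0=sigma0, element=(int(i), int(j)),
                                 ramp_time=ramp_time))
    return curves


def map_to_csv(path: str | Path, pmap: PropertyMap) -> None:
    """Grid CSV with rows = depth from the top, columns = horizontal position."""
    # values[i, j] has j from the bottom; transpose and flip for image layout
    np.savetxt(path, pmap.values.T[::-1, :], delimiter=",")


def map_to_png(path: str | Path, pmap: PropertyMap, cmap: str = "viridis",
               title: str | None = None) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = pmap.values.T[::-1, :]
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(img, cmap=cmap, aspect="equal")
    ax.set_xlabel("horizontal [elements]")
    ax.set_ylabel("depth [elements]")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def report_to_csv(path: str | Path, report: pd.DataFrame) -> None:
    """Accuracy table: rows = simulation test, columns = E, tauR, g."""
    report.to_csv(path, index_label="test")
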