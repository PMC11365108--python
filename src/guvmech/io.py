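"""File I/O: TIFF image series, CSV tables, PDB bilayer frames."""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .bilayer import BilayerFrame
from .imaging import VesicleGeometry
from .mechanics import ElasticityFitResults, PressureStep, TensionAreaPoint
from .pipeline import AnalysisConfig
from .synthetic import (
    CHAIN_PSEUDOATOM_MASS,
    OCTANE_MASS,
    PHOSPHORUS_MASS,
    AspirationSeries,
)

__all__ = [
    "write_series",
    "read_images",
    "read_pressures",
    "write_pressures",
    "read_config",
    "write_config",
    "write_geometries",
    "read_geometries",
    "write_points",
    "write_fit",
    "write_bilayer_pdb",
    "read_bilayer_pdb",
    "write_bilayer_csv",
    "read_bilayer_csv",
]

_CHAIN_TO_LEAFLET = {"A": "upper", "B": "lower", "O": "none"}
_LEAFLET_TO_CHAIN = {v: k for k, v in _CHAIN_TO_LEAFLET.items()}
_RES_TO_SPECIES = {"LIP": "lipid", "OCT": "octane", "HOH": "water", "ION": "ion"}
_SPECIES_TO_RES = {v: k for k, v in _RES_TO_SPECIES.items()}


def write_series(series: AspirationSeries, outdir: str) -> None:
    """Write an aspiration series: TIFF stack, pressure/truth CSV, config."""
    os.makedirs(outdir, exist_ok=True)
    if series.steps:
        tifffile.imwrite(
            os.path.join(outdir, "images.tif"),
            np.stack(series.images),
        )
    write_pressures(series.pressures, os.path.join(outdir, "pressures.csv"))
    series.truth_frame().to_csv(os.path.join(outdir, "truth.csv"), index=False)
    write_config(series.config, os.path.join(outdir, "config.yaml"))


def read_images(path: str) -> list[np.ndarray]:
    data = tifffile.imread(path)
    if data.ndim == 2:
        return [data]
    return [frame for frame in data]


def write_pressures(pressures: Sequence[PressureStep], path: str) -> None:
    pd.DataFrame(
        {
            "step": [p.step for p in pressures],
            "pressure_pa": [p.dp for p in pressures],
            "pressure_err_pa": [p.dp_err for p in pressures],
        }
    ).to_csv(path, index=False)


def read_pressures(path: str) -> list[PressureStep]:
    df = pd.read_csv(path)
    return [
        PressureStep(dp=float(r.pressure_pa), dp_err=float(r.pressure_err_pa), step=int(r.step))
        for r in df.itertuples(index=False)
    ]


def write_config(config: AnalysisConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)


def read_config(path: str) -> AnalysisConfig:
    with open(path) as fh:
        return AnalysisConfig.from_dict(yaml.safe_load(fh))


def write_geometries(geoms: Sequence[VesicleGeometry], path: str) -> None:
    pd.DataFrame(
        {
            "step": range(len(geoms)),
            "rv_um": [g.rv for g in geoms],
            "rv_err_um": [g.rv_err for g in geoms],
            "lp_um": [g.lp for g in geoms],
            "lp_err_um": [g.lp_err for g in geoms],
        }
    ).to_csv(path, index=False)


def read_geometries(path: str, rp_um: float, rp_err_um: float = 0.0) -> list[VesicleGeometry]:
    df = pd.read_csv(path)
    return [
        VesicleGeometry(
            rp=rp_um, rp_err=rp_err_um,
            rv=float(r.rv_um), rv_err=float(r.rv_err_um),
            lp=float(r.lp_um), lp_err=float(r.lp_err_um),
        )
        for r in df.itertuples(index=False)
    ]


def write_points(points: Sequence[TensionAreaPoint], path: str) -> None:
    pd.DataFrame(
        {
            "step": [p.step for p in points],
            "tau_mn_per_m": [p.tau for p in points],
            "tau_err": [p.tau_err for p in points],
            "alpha": [p.alpha for p in points],
            "alpha_err": [p.alpha_err for p in points],
        }
    ).to_csv(path, index=False)


def write_fit(fit: ElasticityFitResults, path: str) -> None:
    pd.DataFrame(
        [
            {
                "ka_mn_per_m": fit.ka,
                "ka_err": fit.ka_err,
                "intercept": fit.intercept,
                "n_points": fit.n_points,
                "r_squared": fit.r_squared,
                "tau_min": fit.tau_min,
            }
        ]
    ).to_csv(path, index=False)


def _mass_for(species: str, element: str) -> float:
    if species == "lipid":
        return PHOSPHORUS_MASS if element == "P" else CHAIN_PSEUDOATOM_MASS
    if species == "octane":
        return OCTANE_MASS
    if species == "water":
        return 18.015
    return 22.99


def write_bilayer_pdb(frames: Sequence[BilayerFrame], path: str) -> None:
    """Write frames as a multi-model PDB (chain A/B/O, residue = species)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    frames = list(frames)
    n = len(frames[0].mass)
    stack = struc.AtomArrayStack(len(frames), n)
    first = frames[0]
    stack.chain_id = np.array([_LEAFLET_TO_CHAIN.get(l, "O") for l in first.leaflet])
    stack.res_name = np.array([_SPECIES_TO_RES.get(s, "UNK") for s in first.species])
    stack.res_id = np.arange(1, n + 1)
    stack.atom_name = np.asarray(first.element).astype("U4")
    stack.element = np.asarray(first.element).astype("U2")
    stack.hetero = np.zeros(n, dtype=bool)
    for i, frame in enumerate(frames):
        stack.coord[i] = frame.coords * 10.0  # nm -> Angstrom
    lx, ly, lz = first.box
    stack.box = np.repeat(np.diag([lx, ly, lz])[np.newaxis] * 10.0, len(frames), axis=0)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


def read_bilayer_pdb(path: str) -> list[BilayerFrame]:
    """Read PDB frames back to BilayerFrame objects (masses from tagging)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(path)
    stack = pdb.get_structure(model=None)
    box = pdb.get_structure(model=1).box
    if box is None:
        raise ValueError("PDB lacks CRYST1 box information")
    lx, ly, lz = np.diag(box) / 10.0
    species = np.array([_RES_TO_SPECIES.get(r, "lipid") for r in stack.res_name])
    leaflet = np.array([_CHAIN_TO_LEAFLET.get(c, "none") for c in stack.chain_id])
    element = np.asarray(stack.element).astype("U2")
    mass = np.array([_mass_for(s, e) for s, e in zip(species, element)])
    frames = []
    for i in range(stack.stack_depth()):
        frames.append(
            BilayerFrame(
                coords=stack.coord[i] / 10.0,
                mass=mass.copy(),
                species=species.copy(),
                leaflet=leaflet.copy(),
                element=element.copy(),
                box=(float(lx), float(ly), float(lz)),
            )
        )
    return frames


def write_bilayer_csv(frames: Sequence[BilayerFrame], path: str) -> None:
    """CSV fallback: one row per atom with a frame index column."""
    rows = []
    for i, frame in enumerate(frames):
        for j in range(len(frame.mass)):
            rows.append(
                {
                    "frame": i,
                    "x": frame.coords[j, 0],
                    "y": frame.coords[j, 1],
                    "z": frame.coords[j, 2],
                    "mass": frame.mass[j],
                    "species": frame.species[j],
                    "leaflet": frame.leaflet[j],
                    "element": frame.element[j],
                }
            )
    df = pd.DataFrame(rows)
    lx, ly, lz = frames[0].box
    with open(path, "w") as fh:
        fh.write(f"# box {lx} {ly} {lz}\n")
        df.to_csv(fh, index=False)


def read_bilayer_csv(path: str) -> list[BilayerFrame]:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# box"):
            raise ValueError("bilayer CSV must start with a '# box Lx Ly Lz' line")
        box = tuple(float(v) for v in header.split()[2:5])
        df = pd.read_csv(fh)
    frames = []
    for _, sub in df.groupby("frame", sort=True):
        frames.append(
            BilayerFrame(
                coords=sub[["x", "y", "z"]].to_numpy(dtype=float),
                mass=sub["mass"].to_numpy(dtype=float),
                species=sub["species"].to_numpy(dtype=str),
                leaflet=sub["leaflet"].to_numpy(dtype=str),
                element=sub["element"].to_numpy(dtype=str),
                box=box,
            )
        )
    return frames
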