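"""Readers and writers for the pipeline's on-disk formats.

* minimal Abaqus-deck subset (``*NODE``, ``*ELEMENT`` with C3D4/C3D10,
  ``*NSET``, ``*ELSET``) for tetrahedral meshes (quadratic decks are
  subdivided into linear tetrahedra on import);
* legacy ASCII VTK unstructured grids for field inspection;
* NIfTI attenuation volumes (axis-aligned affines only) via nibabel;
* CSV joint trajectories and load histories (pandas);
* HDF5 containers for superelements, material fields and load histories.
"""

from __future__ import annotations

import logging

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .chain import TrajectorySet
from .fem import LoadHistory
from .materials import HUVolume, MaterialField, MaterialLaw
from .mesh import TetMesh, subdivide_quadratic_tets
from .reduction import SuperElement

log = logging.getLogger("bonedyn")


class ParseError(ValueError):
    """Malformed input file, with line context."""


# ---------------------------------------------------------------------------
# Abaqus deck subset


def write_abaqus(mesh: TetMesh, path):
    with open(path, "w") as fh:
        fh.write("*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i}, {x:.10e}, {y:.10e}, {z:.10e}\n")
        fh.write("*ELEMENT, TYPE=C3D4\n")
        for e, conn in enumerate(mesh.elements, start=1):
            fh.write(f"{e}, " + ", ".join(str(c + 1) for c in conn) + "\n")
        for name, idx in mesh.node_sets.items():
            fh.write(f"*NSET, NSET={name}\n")
            _write_id_lines(fh, np.asarray(idx) + 1)
        for name, idx in mesh.element_sets.items():
            fh.write(f"*ELSET, ELSET={name}\n")
            _write_id_lines(fh, np.asarray(idx) + 1)


def _write_id_lines(fh, ids, per_line=8):
    ids = list(int(i) for i in ids)
    for i in range(0, len(ids), per_line):
        fh.write(", ".join(str(j) for j in ids[i:i + per_line]) + "\n")


def read_abaqus(path) -> TetMesh:
    nodes = {}
    elems = []
    elem_order = None
    node_sets, elem_sets = {}, {}
    section = None
    set_name = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                head = [p.strip() for p in line.split(",")]
                kw = head[0].upper()
                opts = {}
                for p in head[1:]:
                    if "=" in p:
                        k, v = p.split("=", 1)
                        opts[k.strip().upper()] = v.strip()
                if kw == "*NODE":
                    section = "node"
                elif kw == "*ELEMENT":
                    etype = opts.get("TYPE", "").upper()
                    if etype == "C3D4":
                        elem_order = 4
                    elif etype == "C3D10":
                        elem_order = 10
                    else:
                        raise ParseError(
                            f"{path}:{lineno}: unsupported element type "
                            f"{etype!r} (C3D4/C3D10 only)")
                    section = "element"
                elif kw == "*NSET":
                    section = "nset"
                    set_name = opts.get("NSET")
                    node_sets.setdefault(set_name, [])
                elif kw == "*ELSET":
                    section = "elset"
                    set_name = opts.get("ELSET")
                    elem_sets.setdefault(set_name, [])
                else:
                    section = None  # ignore unknown keywords
                continue
            parts = [p for p in (x.strip() for x in line.split(",")) if p]
            try:
                if section == "node":
                    nid = int(parts[0])
                    nodes[nid] = [float(v) for v in parts[1:4]]
                elif section == "element":
                    ids = [int(v) for v in parts]
                    if len(ids) != elem_order + 1:
                        raise ValueError("wrong connectivity length")
                    elems.append(ids[1:])
                elif section in ("nset", "elset"):
                    target = node_sets if section == "nset" else elem_sets
                    target[set_name].extend(int(v) for v in parts)
            except (ValueError, IndexError) as err:
                raise ParseError(f"{path}:{lineno}: {err} in line {line!r}")
    if not nodes or not elems:
        raise ParseError(f"{path}: no nodes or elements found")
    ids = sorted(nodes)
    remap = {nid: i for i, nid in enumerate(ids)}
    coords = np.array([nodes[i] for i in ids])
    conn = np.array([[remap[c] for c in e] for e in elems], dtype=np.intp)
    if elem_order == 10:
        log.info("quadratic C3D10 deck: subdividing each element into 8 "
                 "linear tetrahedra")
        conn = subdivide_quadratic_tets(coords, conn)
    mesh = TetMesh(
        coords, conn,
        node_sets={k: np.array([remap[i] for i in v], dtype=np.intp)
                   for k, v in node_sets.items()},
        element_sets={k: np.asarray(v, dtype=np.intp) - 1
                      for k, v in elem_sets.items()},
    )
    if elem_order == 10:
        # element ids changed under subdivision; element sets cannot be mapped
        mesh.element_sets = {}
    return mesh.orient()


# ---------------------------------------------------------------------------
# legacy VTK


def write_vtk(mesh: TetMesh, path, point_data=None, cell_data=None):
    """Legacy ASCII VTK unstructured grid with optional fields."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbonedyn export\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
        fh.write(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}\n")
        for conn in mesh.elements:
            fh.write("4 " + " ".join(str(c) for c in conn) + "\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        fh.write("\n".join(["10"] * mesh.n_elements) + "\n")
        for label, data in (("POINT_DATA", point_data),
                            ("CELL_DATA", cell_data)):
            if not data:
                continue
            n = mesh.n_nodes if label == "POINT_DATA" else mesh.n_elements
            fh.write(f"{label} {n}\n")
            for name, arr in data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.9e}" for v in arr) + "\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for v in arr:
                        fh.write(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")


# ---------------------------------------------------------------------------
# NIfTI


def read_nifti(path) -> HUVolume:
    img = nib.load(str(path))
    aff = img.affine
    rot = aff[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.abs(off_diag).max() > 1e-6 * max(np.abs(np.diag(rot)).max(), 1.0):
        raise ValueError("only axis-aligned NIfTI affines are supported")
    spacing = np.abs(np.diag(rot))
    data = np.asarray(img.get_fdata(), dtype=float)
    # flip axes with negative direction so spacing is positive-increasing
    for ax in range(3):
        if rot[ax, ax] < 0:
            data = np.flip(data, axis=ax)
    origin = aff[:3, 3].copy()
    for ax in range(3):
        if rot[ax, ax] < 0:
            origin[ax] = aff[ax, 3] + rot[ax, ax] * (data.shape[ax] - 1)
    return HUVolume(data, spacing, origin)


def write_nifti(volume: HUVolume, path):
    aff = np.eye(4)
    aff[:3, :3] = np.diag(volume.spacing)
    aff[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), aff), str(path))


# ---------------------------------------------------------------------------
# CSV


def write_trajectory_csv(traj: TrajectorySet, path, joint_names=None):
    f = traj.beta.shape[1]
    names = joint_names or [f"q{j}" for j in range(f)]
    cols = {"time": traj.times}
    for j, nm in enumerate(names):
        cols[f"{nm}"] = traj.beta[:, j]
        cols[f"{nm}_dot"] = traj.beta_dot[:, j]
        cols[f"{nm}_ddot"] = traj.beta_ddot[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_trajectory_csv(path) -> TrajectorySet:
    df = pd.read_csv(path, float_precision="round_trip")
    base = [c for c in df.columns
            if c != "time" and not c.endswith(("_dot", "_ddot"))]
    beta = df[base].to_numpy()
    bdot = df[[f"{c}_dot" for c in base]].to_numpy()
    bddot = df[[f"{c}_ddot" for c in base]].to_numpy()
    return TrajectorySet(df["time"].to_numpy(), beta, bdot, bddot)


def write_material_csv(field: MaterialField, path):
    pd.DataFrame({
        "node_id": np.arange(len(field.node_modulus)),
        "ash_density_g_cm3": field.node_ash_density,
        "youngs_modulus_Pa": field.node_modulus,
    }).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# HDF5 containers


def _write_dict(group, d):
    for k, v in d.items():
        group.create_dataset(k, data=np.asarray(v))


def save_material_field(field: MaterialField, path):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("ash_density", data=field.node_ash_density)
        fh.create_dataset("modulus", data=field.node_modulus)
        law = fh.create_group("law")
        for k in ("e0", "a", "b_coef", "e_floor", "poisson", "mass_density"):
            law.attrs[k] = getattr(field.law, k)


def load_material_field(path) -> MaterialField:
    with h5py.File(path, "r") as fh:
        law = MaterialLaw(**{k: float(v) for k, v in fh["law"].attrs.items()})
        return MaterialField(fh["ash_density"][...], fh["modulus"][...], law)


def save_superelement(sem: SuperElement, path):
    with h5py.File(path, "w") as fh:
        for name in ("M_red", "K_red", "mode_frequencies", "phi_full",
                     "stress_ops", "strain_ops", "element_volumes"):
            fh.create_dataset(name, data=getattr(sem, name))
        fh.attrs["n_modes"] = sem.n_modes
        fh.attrs["zeta"] = sem.zeta
        bm = fh.create_group("boundary_map")
        _write_dict(bm, sem.boundary_map)
        _write_dict(fh.create_group("element_sets"), sem.element_sets)
        _write_dict(fh.create_group("landmarks"), sem.landmarks)
        meta = fh.create_group("metadata")
        for k, v in sem.metadata.items():
            meta.attrs[k] = str(v)


def load_superelement(path) -> SuperElement:
    with h5py.File(path, "r") as fh:
        return SuperElement(
            M_red=fh["M_red"][...],
            K_red=fh["K_red"][...],
            boundary_map={k: v[...].astype(int)
                          for k, v in fh["boundary_map"].items()},
            n_modes=int(fh.attrs["n_modes"]),
            zeta=float(fh.attrs["zeta"]),
            mode_frequencies=fh["mode_frequencies"][...],
            phi_full=fh["phi_full"][...],
            stress_ops=fh["stress_ops"][...],
            strain_ops=fh["strain_ops"][...],
            element_volumes=fh["element_volumes"][...],
            element_sets={k: v[...].astype(int)
                          for k, v in fh["element_sets"].items()},
            landmarks={k: v[...] for k, v in fh["landmarks"].items()},
            metadata={k: v for k, v in fh["metadata"].attrs.items()},
        )


def save_load_history(history: LoadHistory, path):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=history.times)
        _write_dict(fh.create_group("wrenches"), history.wrenches)


def load_load_history(path) -> LoadHistory:
    with h5py.File(path, "r") as fh:
        return LoadHistory(fh["times"][...],
                           {k: v[...] for k, v in fh["wrenches"].items()})
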