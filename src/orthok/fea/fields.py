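"""Barometer field extraction from converged simulations.

Five fields ("barometers") are read off the anterior eye surface:
four stress components — contact pressure, Mises stress, pressure
(-tr(sigma)/3, positive in compression), maximum principal stress — and
the maximum principal logarithmic strain; displacement magnitude is also
available.  Quadrature stresses are volume-averaged per element and then
averaged onto the anterior surface nodes; stresses are reported in kPa.

``fea_rpc`` rebuilds anterior surface height maps before (IOP-inflated)
and after lens wear from the simulation displacements and runs them
through the clinical power-map pipeline, giving the FEA-predicted RPC.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import griddata

from ..maps import PolarMap
from ..power_maps import (PowerMapConfig, rpc_map, smooth_map,
                          tangential_curvature_map, tangential_power_map)
from ..topography import TopographyRecord
from . import elements
from .program import ProgramResult

FIELD_COMPONENTS = ("contact_pressure", "mises", "pressure",
                    "max_principal_stress", "max_principal_log_strain",
                    "displacement_mag")


def _nodal_average(mesh, elem_slice, gp_vals, w, node_ids):
    """Volume-weighted element-mean values averaged onto nodes.

    gp_vals: (m, 8, ...) quadrature values for the elements in elem_slice.
    """
    elems = mesh.elems[elem_slice]
    vol = w[elem_slice].sum(axis=1)
    emean = np.einsum("mg...,mg->m...", gp_vals[elem_slice], w[elem_slice]) \
        / vol.reshape((-1,) + (1,) * (gp_vals.ndim - 2))
    acc = np.zeros((mesh.n_nodes,) + emean.shape[1:])
    wacc = np.zeros(mesh.n_nodes)
    for a in range(8):
        np.add.at(acc, elems[:, a], emean * vol.reshape((-1,) + (1,) * (emean.ndim - 1)))
        np.add.at(wacc, elems[:, a], vol)
    sel = node_ids
    return acc[sel] / wacc[sel].reshape((-1,) + (1,) * (emean.ndim - 1))


def extract_field(prog: ProgramResult, component: str,
                  step_name: str | None = None):
    """(xy positions (n, 2) mm, values (n,)) on the anterior surface nodes.

    Stresses in kPa, strain unitless, displacement in mm.
    """
    if component not in FIELD_COMPONENTS:
        raise ValueError(f"unknown field component {component!r}; "
                         f"choose from {FIELD_COMPONENTS}")
    step = prog.result.steps[-1] if step_name is None else prog.result.step(step_name)
    mesh = prog.mesh
    ids = prog.anterior_node_ids
    xy = mesh.nodes[ids][:, :2] + step.u.reshape(-1, 3)[ids][:, :2] * 0.0
    e0, e1 = prog.elem_ranges["cornea"]
    esl = slice(e0, e1)

    if component == "displacement_mag":
        u = step.u.reshape(-1, 3)[ids]
        return xy, np.linalg.norm(u, axis=1)

    if component == "contact_pressure":
        vals = contact_pressure_field(prog, step.contact_states)
        return xy, vals

    if component == "max_principal_log_strain":
        F = elements.deformation_gradients(prog.model.dNdX, mesh.elems,
                                           step.u.reshape(-1, 3))
        lnV = elements.log_strain_tensors(F)
        T = _nodal_average(mesh, esl, lnV, prog.model.w, ids)
        return xy, np.linalg.eigvalsh(T)[:, -1]

    sig = elements.voigt_to_tensor(step.gp_stress) * 1e3    # MPa -> kPa
    T = _nodal_average(mesh, esl, sig, prog.model.w, ids)
    if component == "mises":
        dev = T - np.trace(T, axis1=1, axis2=2)[:, None, None] / 3 * np.eye(3)
        return xy, np.sqrt(1.5 * np.einsum("nij,nij->n", dev, dev))
    if component == "pressure":
        return xy, -np.trace(T, axis1=1, axis2=2) / 3
    if component == "max_principal_stress":
        return xy, np.linalg.eigvalsh(T)[:, -1]
    raise AssertionError


def contact_pressure_field(prog: ProgramResult, contact_states: dict) -> np.ndarray:
    """Normal contact traction (kPa) on the cornea anterior nodes.

    Penalty normal forces of every pair whose master is the cornea
    anterior surface are binned onto the paired facets, divided by facet
    area, and area-averaged onto facet nodes; zero outside contact.
    """
    mesh = prog.mesh
    quads = prog.anterior_quads
    areas = _areas(mesh.nodes, quads)
    force = np.zeros(len(quads))
    for pair in prog.contacts:
        if pair.master_quads is not quads:
            continue
        st = contact_states.get(pair.name)
        if st is None:
            continue
        np.add.at(force, st.facet_idx[st.active], st.normal_force[st.active])
    pressure = force / areas * 1e3          # N/mm^2 = MPa -> kPa
    acc = np.zeros(mesh.n_nodes)
    wacc = np.zeros(mesh.n_nodes)
    for a in range(4):
        np.add.at(acc, quads[:, a], pressure * areas)
        np.add.at(wacc, quads[:, a], areas)
    ids = prog.anterior_node_ids
    out = np.zeros(len(ids))
    has = wacc[ids] > 0
    out[has] = acc[ids][has] / wacc[ids][has]
    return out


def _areas(nodes, quads):
    P = nodes[quads]
    return 0.5 * np.linalg.norm(np.cross(P[:, 2] - P[:, 0], P[:, 3] - P[:, 1]), axis=1)


def surface_to_polar_record(points: np.ndarray, n_az: int = 180, n_r: int = 180,
                            r_max: float | None = None) -> TopographyRecord:
    """Resample a scattered anterior surface onto a polar elevation grid."""
    if r_max is None:
        r_max = 0.98 * np.hypot(points[:, 0], points[:, 1]).max()
    az = np.arange(n_az) * (360.0 / n_az)
    r = np.linspace(0.0, r_max, n_r)
    th = np.deg2rad(az)[:, None]
    X = r[None, :] * np.cos(th)
    Y = r[None, :] * np.sin(th)
    Z = griddata(points[:, :2], points[:, 2], (X, Y), method="cubic")
    cov = np.isfinite(Z)
    return TopographyRecord(np.where(cov, Z, np.nan), r, az, cov)


def fea_rpc(prog: ProgramResult, cfg: PowerMapConfig | None = None,
            pre_step: str = "iop_inflation", post_step: str | None = None,
            n_az: int = 180, n_r: int = 180) -> PolarMap:
    """FEA-predicted RPC: power change between inflated and lens-worn surfaces."""
    cfg = cfg or PowerMapConfig()
    pre_pts = prog.anterior_coords(pre_step)
    post_name = post_step or prog.result.steps[-1].name
    post_pts = prog.anterior_coords(post_name)
    # curvature is a geometric invariant: remove any net rigid-body motion
    # of the anterior cloud so only true shape change enters the RPC
    from ..registration import _kabsch
    R, T = _kabsch(post_pts, pre_pts)
    post_pts = post_pts @ R.T + T
    r_max = 0.98 * min(np.hypot(pre_pts[:, 0], pre_pts[:, 1]).max(),
                       np.hypot(post_pts[:, 0], post_pts[:, 1]).max())
    rec_pre = surface_to_polar_record(pre_pts, n_az, n_r, r_max)
    rec_post = surface_to_polar_record(post_pts, n_az, n_r, r_max)
    maps = []
    for rec in (rec_pre, rec_post):
        curv = tangential_curvature_map(rec, cfg)
        power = tangential_power_map(curv, cfg)
        maps.append(smooth_map(power, cfg))
    return rpc_map(maps[0], maps[1])
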