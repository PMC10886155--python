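"""The staged load program on the cornea-lens-eyelid assembly.

Load schedule (after the stress-free reference geometry is found):

1. stress-free iterations (see :mod:`orthok.fea.stressfree`)
2. IOP inflation of the eye, applied statically in equal increments
3. blink settle: eyelid pressure (8.0 mmHg) pressing the lid onto the
   lens and eye, solved quasi-statically
4. tear-film surface tension (43.6 mPa) as a uniform attractive normal
   traction on the lens back surface
5. eyelid closure pressure (8.0 mmHg), the steady closed-eye state

Contact pairs: cornea anterior (master) vs lens back (slave), lens front
(master) vs eyelid back (slave), cornea anterior (master) vs eyelid back
(slave); penalty friction with mu = 0.01.  The free-floating lens is
stabilised with weak grounding springs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..meshing import HexMesh
from .contact import ContactPair
from .model import (Assembly, FEAResult, FEModel, MaterialModel, MMHG_TO_MPA,
                    PressureLoad)

LENS_MATERIAL = MaterialModel(E=1500.0, nu=0.49, density=1270.0)
EYELID_MATERIAL = MaterialModel(E=1.73, nu=0.49, density=1000.0)


@dataclass
class LoadProgram:
    """Loads, increments and solver tolerances for the five-step program."""

    iop_mmhg: float = 15.0
    iop_increments: int = 10
    eyelid_pressure_mmhg: float = 8.0
    eyelid_increments: int = 5
    tear_surface_tension_pa: float = 43.6e-3     # 43.6 mPa, applied as printed
    friction: float = 0.01
    penalty_factor: float = 5.0
    lens_spring_n_per_mm: float = 1e-5
    newton_tol: float = 1e-4
    # increments whose Newton loop stalls on contact chatter are accepted
    # (and logged as 'loose') if the out-of-balance force stays below this
    # fraction of the external load
    chatter_tol_rel: float = 0.01
    nlgeom: bool = False

    def __post_init__(self) -> None:
        if min(self.iop_mmhg, self.eyelid_pressure_mmhg) < 0:
            raise ValueError("pressures must be non-negative")


@dataclass
class ProgramResult:
    """Merged model + per-step results, ready for field extraction."""

    model: FEModel
    mesh: HexMesh
    node_ranges: dict
    elem_ranges: dict
    result: FEAResult
    loads_at_end: list
    contacts: list
    anterior_node_ids: np.ndarray
    anterior_quads: np.ndarray
    program: LoadProgram

    def anterior_coords(self, step_name: str) -> np.ndarray:
        u = self.result.step(step_name).u.reshape(-1, 3)
        return self.mesh.nodes[self.anterior_node_ids] + u[self.anterior_node_ids]


def build_assembly(cornea: HexMesh, cornea_material: MaterialModel,
                   lens: HexMesh | None = None,
                   eyelid: HexMesh | None = None) -> Assembly:
    asm = Assembly()
    asm.add_part("cornea", cornea, cornea_material)
    if lens is not None:
        asm.add_part("lens", lens, LENS_MATERIAL)
    if eyelid is not None:
        asm.add_part("eyelid", eyelid, EYELID_MATERIAL)
    return asm


def run_load_program(assembly: Assembly, program: LoadProgram,
                     log: list | None = None) -> ProgramResult:
    """Execute the staged loads on an assembled cornea(-lens-eyelid) model.

    The cornea part is expected to be the stress-free reference geometry;
    lens and eyelid parts (optional) must be pre-seated/pre-draped with a
    small clearance.
    """
    mesh, E, nu, nrange, erange = assembly.merged()
    model = FEModel(mesh, E, nu, nlgeom=program.nlgeom)
    model.fix(mesh.node_sets["cornea:rim_fixed"])
    has_lens = "lens" in assembly.parts
    has_lid = "eyelid" in assembly.parts
    if has_lid:
        model.fix(mesh.node_sets["eyelid:eyelid_perimeter"])
    if has_lens:
        model.add_springs(mesh.node_sets["lens:all"], program.lens_spring_n_per_mm)

    cornea_mat = assembly.parts["cornea"][1]
    ant_quads = mesh.facet_quads("cornea:anterior_surface")
    ant_area = _quad_areas(mesh.nodes, ant_quads).mean()
    h = _wall_h(assembly, ant_area)
    penalty = program.penalty_factor * cornea_mat.E * ant_area / h

    # slave-node sets are filtered laterally at build time so nodes that
    # hang past a master surface's rim can never pair with it
    contacts = []
    ant_lat = np.hypot(*mesh.nodes[mesh.facet_set_nodes("cornea:anterior_surface")][:, :2].T).max()
    if has_lens:
        contacts.append(ContactPair(
            "cornea_lens", ant_quads, mesh.node_sets["lens:back_nodes"],
            penalty, program.friction))
    if has_lid:
        lid_back = mesh.node_sets["eyelid:back_nodes"]
        lat = np.hypot(mesh.nodes[lid_back, 0], mesh.nodes[lid_back, 1])
        if has_lens:
            lens_nodes = mesh.nodes[mesh.node_sets["lens:back_nodes"]]
            lens_c = lens_nodes[:, :2].mean(axis=0)
            lens_r = np.hypot(*(lens_nodes[:, :2] - lens_c).T).max()
            lat_lens = np.hypot(*(mesh.nodes[lid_back, :2] - lens_c).T)
            contacts.append(ContactPair(
                "eyelid_lens", mesh.facet_quads("lens:lens_front"),
                lid_back[lat_lens < 0.93 * lens_r], penalty, program.friction))
        contacts.append(ContactPair(
            "eyelid_cornea", ant_quads, lid_back[lat < 0.93 * ant_lat],
            penalty, program.friction))

    iop = PressureLoad(mesh.facet_quads("cornea:inner_wall"),
                       program.iop_mmhg * MMHG_TO_MPA)
    res = FEAResult(mesh=mesh, convergence_log=log if log is not None else [])

    step2 = model.solve([iop], contacts=contacts, increments=program.iop_increments,
                        tol=program.newton_tol, chatter_tol_rel=program.chatter_tol_rel,
                        log=res.convergence_log,
                        step_name="iop_inflation")
    res.steps.append(step2)
    loads_end = [iop]

    if has_lid:
        lid = PressureLoad(mesh.facet_quads("eyelid:eyelid_outer"),
                           program.eyelid_pressure_mmhg * MMHG_TO_MPA)
        step3 = model.solve([lid], contacts=contacts, held_loads=[iop],
                            u0=step2.u, increments=program.eyelid_increments,
                            tol=program.newton_tol, chatter_tol_rel=program.chatter_tol_rel,
                            log=res.convergence_log,
                            step_name="blink_settle")
        res.steps.append(step3)
        loads_end = [iop, lid]
    else:
        step3 = step2

    if has_lens:
        tear = PressureLoad(mesh.facet_quads("lens:lens_back"),
                            -program.tear_surface_tension_pa * 1e-6)
        step4 = model.solve([tear], contacts=contacts, held_loads=loads_end,
                            u0=step3.u, increments=1,
                            tol=program.newton_tol, chatter_tol_rel=program.chatter_tol_rel,
                            log=res.convergence_log,
                            step_name="tear_surface_tension")
        res.steps.append(step4)
        loads_end = loads_end + [tear]
    else:
        step4 = step3

    step5 = model.solve([], contacts=contacts, held_loads=loads_end,
                        u0=step4.u, increments=1,
                        tol=program.newton_tol, chatter_tol_rel=program.chatter_tol_rel,
                        log=res.convergence_log,
                        step_name="eyelid_closure")
    res.steps.append(step5)

    return ProgramResult(
        model=model, mesh=mesh, node_ranges=nrange, elem_ranges=erange,
        result=res, loads_at_end=loads_end, contacts=contacts,
        anterior_node_ids=mesh.node_sets["cornea:anterior_nodes"],
        anterior_quads=ant_quads, program=program)


def _quad_areas(nodes: np.ndarray, quads: np.ndarray) -> np.ndarray:
    P = nodes[quads]
    return 0.5 * np.linalg.norm(np.cross(P[:, 2] - P[:, 0], P[:, 3] - P[:, 1]), axis=1)


def _wall_h(assembly: Assembly, facet_area: float) -> float:
    cornea = assembly.parts["cornea"][0]
    # characteristic through-thickness element size: mean volume / facet area
    vol = cornea.jacobians().sum() / cornea.n_elems
    return max(vol / facet_area, 0.02)
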