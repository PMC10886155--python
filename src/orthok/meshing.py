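"""Hexahedral meshing of the anterior eye and the reverse-geometry lens.

The anterior eye is meshed nonparametrically: a pre-meshed template cap is
mapped through spherical coordinates, replacing every template node's
radius with a cubic interpolant of the measured surface radius at the
node's (azimuth, elevation).  The lens is meshed by revolving its
zone-arc cross-section over a structured disk ("butterfly"/O-grid)
topology: a central ``b x b`` quad patch surrounded by concentric rings of
``4 b`` quads each, so a disk layer holds ``b**2 + 4*b*rings`` elements.

All meshes are 8-node hexahedra with named node and facet sets for loads,
contacts and boundary conditions, exportable as legacy ASCII VTK and an
Abaqus-style ``.inp`` subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topography import ExtendedSurface, RadialSurface

__all__ = [
    "HexMesh",
    "LensDesign",
    "MeshError",
    "disk_grid",
    "spherical_template_map",
    "build_cornea_mesh",
    "build_lens_profile",
    "build_lens_mesh",
    "sphere_shell_mesh",
    "default_lens_design",
]

# Local faces of a hex (nodes 0-3 bottom, 4-7 top), wound so the normal
# points out of the element.
FACE_NODES = np.array([
    [0, 3, 2, 1],   # bottom
    [4, 5, 6, 7],   # top
    [0, 1, 5, 4],
    [1, 2, 6, 5],
    [2, 3, 7, 6],
    [3, 0, 4, 7],
])

_GP = np.array([-1.0, 1.0]) / np.sqrt(3.0)


class MeshError(ValueError):
    pass


def _hex_shape_gradients():
    """dN/dxi at the 2x2x2 Gauss points: (8 gp, 8 nodes, 3)."""
    corners = np.array([
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ], dtype=float)
    gps = np.array([[x, y, z] for z in _GP for y in _GP for x in _GP])
    dN = np.empty((8, 8, 3))
    for g, (xi, eta, ze) in enumerate(gps):
        for a, (ca, cb, cc) in enumerate(corners):
            dN[g, a, 0] = 0.125 * ca * (1 + cb * eta) * (1 + cc * ze)
            dN[g, a, 1] = 0.125 * cb * (1 + ca * xi) * (1 + cc * ze)
            dN[g, a, 2] = 0.125 * cc * (1 + ca * xi) * (1 + cb * eta)
    return dN


HEX_DN = _hex_shape_gradients()


@dataclass
class HexMesh:
    """8-node hexahedral mesh with named node and facet sets.

    ``facet_sets`` map a name to an (k, 2) int array of (element index,
    local face index).
    """

    nodes: np.ndarray
    elems: np.ndarray
    node_sets: dict = field(default_factory=dict)
    facet_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elems = np.asarray(self.elems, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def copy(self) -> "HexMesh":
        return HexMesh(self.nodes.copy(), self.elems.copy(),
                       {k: np.array(v) for k, v in self.node_sets.items()},
                       {k: np.array(v) for k, v in self.facet_sets.items()})

    # -- geometry ---------------------------------------------------------

    def jacobians(self) -> np.ndarray:
        """det J at the 2x2x2 quadrature points, shape (n_elems, 8)."""
        X = self.nodes[self.elems]                      # (m, 8, 3)
        J = np.einsum("gak,mai->mgki", HEX_DN, X)        # (m, 8gp, 3, 3)
        return np.linalg.det(J)

    def check(self, dup_tol: float = 1e-9) -> None:
        """Validity: positive Jacobians, no duplicate nodes, closed boundary."""
        det = self.jacobians()
        if np.any(det <= 0):
            bad = np.unique(np.nonzero(det <= 0)[0])
            raise MeshError(f"non-positive Jacobian in elements {bad.tolist()[:20]}")
        # duplicate nodes
        key = np.round(self.nodes / dup_tol).astype(np.int64)
        _, counts = np.unique(key, axis=0, return_counts=True)
        if np.any(counts > 1):
            raise MeshError("duplicate nodes within tolerance")
        # watertight boundary: every boundary component a genus-0 closed
        # surface (chi = 2 per component; a hollow shell has two)
        faces = self.boundary_faces()
        v_idx = np.unique(faces)
        edges = set()
        for f in faces:
            for i in range(4):
                a, b = f[i], f[(i + 1) % 4]
                edges.add((min(a, b), max(a, b)))
        chi = v_idx.size - len(edges) + faces.shape[0]
        import scipy.sparse as _sp
        from scipy.sparse.csgraph import connected_components
        e = np.array(sorted(edges))
        remap = {v: k for k, v in enumerate(v_idx)}
        ei = np.vectorize(remap.get)(e)
        adj = _sp.coo_matrix((np.ones(len(ei)), (ei[:, 0], ei[:, 1])),
                             shape=(v_idx.size, v_idx.size))
        ncomp, _ = connected_components(adj, directed=False)
        if chi != 2 * ncomp:
            raise MeshError(
                f"boundary is not watertight (chi={chi}, components={ncomp})")

    def boundary_faces(self) -> np.ndarray:
        """(k, 4) node quads of faces that appear exactly once."""
        quads = self.elems[:, FACE_NODES].reshape(-1, 4)
        key = np.sort(quads, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return quads[counts[inv] == 1]

    def facet_quads(self, set_name: str) -> np.ndarray:
        fs = self.facet_sets[set_name]
        return self.elems[fs[:, 0]][np.arange(len(fs))[:, None], FACE_NODES[fs[:, 1]]]

    def facet_set_nodes(self, set_name: str) -> np.ndarray:
        return np.unique(self.facet_quads(set_name))

    def facet_areas_normals(self, set_name: str, coords: np.ndarray | None = None):
        """Per-facet area (mm^2) and unit outward normal, from bilinear quads."""
        X = (self.nodes if coords is None else coords)[self.facet_quads(set_name)]
        d1 = X[:, 2] - X[:, 0]
        d2 = X[:, 3] - X[:, 1]
        cr = np.cross(d1, d2) * 0.5
        area = np.linalg.norm(cr, axis=1)
        return area, cr / area[:, None]

    def transform(self, R: np.ndarray, t: np.ndarray) -> "HexMesh":
        out = self.copy()
        out.nodes = self.nodes @ np.asarray(R).T + np.asarray(t)
        return out

    # -- export -----------------------------------------------------------

    def to_vtk(self, path, point_data: dict | None = None) -> None:
        """Legacy ASCII VTK unstructured grid (cell type 12 = hexahedron)."""
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\northok mesh\nASCII\n")
            fh.write("DATASET UNSTRUCTURED_GRID\n")
            fh.write(f"POINTS {self.n_nodes} double\n")
            for p in self.nodes:
                fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
            fh.write(f"CELLS {self.n_elems} {self.n_elems * 9}\n")
            for e in self.elems:
                fh.write("8 " + " ".join(str(i) for i in e) + "\n")
            fh.write(f"CELL_TYPES {self.n_elems}\n")
            fh.write("\n".join(["12"] * self.n_elems) + "\n")
            if point_data:
                fh.write(f"POINT_DATA {self.n_nodes}\n")
                for name, vals in point_data.items():
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.12g}" for v in np.asarray(vals)) + "\n")

    def to_inp(self, path, part_name: str = "PART", element_type: str = "C3D8") -> None:
        """Abaqus-style input deck subset: NODE/ELEMENT/NSET/SURFACE blocks."""
        with open(path, "w") as fh:
            fh.write(f"*HEADING\n orthok export {part_name}\n")
            fh.write("*NODE\n")
            for i, p in enumerate(self.nodes, start=1):
                fh.write(f"{i}, {p[0]:.12g}, {p[1]:.12g}, {p[2]:.12g}\n")
            fh.write(f"*ELEMENT, TYPE={element_type}\n")
            for j, e in enumerate(self.elems, start=1):
                fh.write(f"{j}, " + ", ".join(str(i + 1) for i in e) + "\n")
            for name, ids in self.node_sets.items():
                fh.write(f"*NSET, NSET={name.upper()}\n")
                ids1 = np.asarray(ids) + 1
                for k in range(0, len(ids1), 12):
                    fh.write(", ".join(str(i) for i in ids1[k:k + 12]) + "\n")
            for name, fs in self.facet_sets.items():
                fh.write(f"*SURFACE, TYPE=ELEMENT, NAME={name.upper()}\n")
                for e, f in np.asarray(fs):
                    fh.write(f"{e + 1}, S{f + 1}\n")

    @staticmethod
    def merge(parts: dict[str, "HexMesh"]) -> "HexMesh":
        """Merge meshes; set names are prefixed ``part:set``. No node fusion."""
        nodes, elems, nsets, fsets = [], [], {}, {}
        n_off = e_off = 0
        for name, m in parts.items():
            nodes.append(m.nodes)
            elems.append(m.elems + n_off)
            for s, ids in m.node_sets.items():
                nsets[f"{name}:{s}"] = np.asarray(ids) + n_off
            for s, fs in m.facet_sets.items():
                fs = np.asarray(fs).copy()
                fs[:, 0] += e_off
                fsets[f"{name}:{s}"] = fs
            nsets[f"{name}:all"] = np.arange(m.n_nodes) + n_off
            n_off += m.n_nodes
            e_off += m.n_elems
        return HexMesh(np.vstack(nodes), np.vstack(elems), nsets, fsets)


# ----------------------------------------------------------------------------
# Disk ("butterfly"/O-grid) topology
# ----------------------------------------------------------------------------

def disk_grid(base: int = 4, rings: int = 30, patch_fraction: float = 0.4):
    """Structured unit-disk quad grid: central base x base patch + rings.

    Returns (points2d (N, 2), quads (M, 4), perimeter (4*base,) node ids in
    CCW order).  Node count (base+1)**2 + 4*base*rings; quad count
    base**2 + 4*base*rings.
    """
    b = base
    rho0 = patch_fraction
    # central patch via elliptical square->disc map, boundary exactly circular
    u = np.linspace(-1.0, 1.0, b + 1)
    U, V = np.meshgrid(u, u, indexing="ij")
    px = U * np.sqrt(1 - V**2 / 2) * rho0
    py = V * np.sqrt(1 - U**2 / 2) * rho0
    patch_pts = np.column_stack([px.ravel(), py.ravel()])
    idx = np.arange((b + 1) ** 2).reshape(b + 1, b + 1)

    quads = []
    for i in range(b):
        for j in range(b):
            quads.append([idx[i, j], idx[i + 1, j], idx[i + 1, j + 1], idx[i, j + 1]])
    # CCW patch perimeter starting at corner (-1, -1)
    per = (list(idx[:, 0]) + list(idx[-1, 1:]) +
           list(idx[-2::-1, -1]) + list(idx[0, -2:0:-1]))
    per = np.array(per)
    assert per.size == 4 * b
    # check orientation of patch quads (+z normals)
    p = patch_pts
    q0 = quads[0]
    v1, v2 = p[q0[1]] - p[q0[0]], p[q0[3]] - p[q0[0]]
    if v1[0] * v2[1] - v1[1] * v2[0] < 0:  # flip winding

        quads = [[q[0], q[3], q[2], q[1]] for q in quads]
        per = per[::-1]
        per = np.roll(per, 1)

    pts = [patch_pts]
    angles = np.arctan2(patch_pts[per, 1], patch_pts[per, 0])
    # radial rays from the patch perimeter angles out to the unit circle
    inner = per
    n_off = (b + 1) ** 2
    for j in range(1, rings + 1):
        rho = rho0 + (1.0 - rho0) * j / rings
        ring_pts = rho * np.column_stack([np.cos(angles), np.sin(angles)])
        ring_ids = np.arange(4 * b) + n_off
        pts.append(ring_pts)
        for k in range(4 * b):
            k1 = (k + 1) % (4 * b)
            quads.append([inner[k], ring_ids[k], ring_ids[k1], inner[k1]])
        inner = ring_ids
        n_off += 4 * b
    points = np.vstack(pts)
    # orientation check for ring quads too
    quads = np.asarray(quads, dtype=np.int64)
    return points, quads, inner  # inner now = outer perimeter ids


def _extrude_quads_to_hexes(quads: np.ndarray, n_nodes_layer: int, layers: int):
    """Stack quad layers into hexes; node layer k occupies ids + k*n."""
    hexes = []
    for k in range(layers):
        lo = quads + k * n_nodes_layer
        hi = quads + (k + 1) * n_nodes_layer
        hexes.append(np.hstack([lo, hi]))
    return np.vstack(hexes)


# ----------------------------------------------------------------------------
# Spherical-interpolation mapping and cornea mesh
# ----------------------------------------------------------------------------

def spherical_template_map(surface: RadialSurface, az_deg: np.ndarray,
                           el_rad: np.ndarray) -> np.ndarray:
    """Map template directions onto a star-shaped surface.

    Each template node's radius is replaced by the cubic interpolant of the
    surface radius at the node's (azimuth, elevation) and transformed back
    to Cartesian coordinates.
    """
    r = surface.radius(az_deg, el_rad)
    az = np.deg2rad(np.asarray(az_deg, float))
    el = np.asarray(el_rad, float)
    return surface.centre + np.column_stack([
        r * np.sin(el) * np.cos(az),
        r * np.sin(el) * np.sin(az),
        r * np.cos(el),
    ])


# Mesh density presets: (base, rings, layers).  ``paper`` approaches the
# clinical-study density; ``desk`` is the default working resolution.
CORNEA_PRESETS = {"desk": (4, 12, 5), "paper": (4, 28, 5)}


def build_cornea_mesh(
    ext: ExtendedSurface,
    cct_mm: float,
    layers: int = 5,
    base: int = 4,
    rings: int = 12,
    lateral_radius_mm: float = 8.0,
    limbal_radius_mm: float = 5.5,
    peripheral_extra_mm: float = 0.18,
    preset: str | None = None,
) -> HexMesh:
    """Anterior-eye solid: template-mapped anterior surface, CCT-based wall.

    Wall thickness varies linearly from ``cct_mm`` at the apex to
    ``cct_mm + peripheral_extra_mm`` at the limbal radius and is constant
    beyond.  Node sets: ``rim_fixed`` (edge), ``anterior_nodes``; facet
    sets: ``anterior_surface`` (outer), ``inner_wall`` (posterior, for IOP).
    """
    if preset is not None:
        base, rings, layers = CORNEA_PRESETS[preset]
    radial = ext.to_radial()
    el_cap = radial.el_at_lateral_radius(lateral_radius_mm)
    pts2d, quads, perimeter = disk_grid(base, rings)
    rho = np.hypot(pts2d[:, 0], pts2d[:, 1])
    theta = np.arctan2(pts2d[:, 1], pts2d[:, 0])
    el = rho * el_cap
    az = np.rad2deg(theta) % 360.0

    anterior = spherical_template_map(radial, az, el)
    normals = _radial_surface_normals(radial, az, el)
    r_lat = np.hypot(anterior[:, 0], anterior[:, 1])
    thick = cct_mm + peripheral_extra_mm * np.minimum(r_lat / limbal_radius_mm, 1.0)
    # self-intersection guard: thickness must stay below local centre distance
    if np.any(thick > 0.8 * np.linalg.norm(anterior - radial.centre, axis=1)):
        raise MeshError("wall thickness exceeds local radius; posterior would self-intersect")

    npl = anterior.shape[0]
    node_layers = []
    for k in range(layers + 1):
        frac = 1.0 - k / layers       # k=0 posterior .. k=layers anterior
        node_layers.append(anterior - normals * thick[:, None] * frac)
    nodes = np.vstack(node_layers)
    elems = _extrude_quads_to_hexes(quads, npl, layers)

    rim = np.concatenate([perimeter + k * npl for k in range(layers + 1)])
    anterior_ids = np.arange(npl) + layers * npl
    nq = quads.shape[0]
    top_layer = np.arange(nq) + (layers - 1) * nq
    bottom_layer = np.arange(nq)
    fsets = {
        "anterior_surface": np.column_stack([top_layer, np.full(nq, 1)]),
        "inner_wall": np.column_stack([bottom_layer, np.full(nq, 0)]),
    }
    mesh = HexMesh(nodes, elems,
                   {"rim_fixed": rim, "anterior_nodes": anterior_ids}, fsets)
    det = mesh.jacobians()
    if np.any(det <= 0):
        raise MeshError("cornea mesh has inverted elements")
    return mesh


def _radial_surface_normals(surface: RadialSurface, az_deg, el_rad) -> np.ndarray:
    """Outward unit normals from the spline's partial derivatives."""
    az = np.asarray(az_deg, float) % 360.0
    el = np.asarray(el_rad, float)
    elc = np.clip(el, 1e-6, surface.el_max - 1e-9)
    r = surface._spline(az, elc, grid=False)
    dr_da = surface._spline(az, elc, dx=1, grid=False) * 180.0 / np.pi  # per rad
    dr_de = surface._spline(az, elc, dy=1, grid=False)
    a = np.deg2rad(az)
    sa, ca, se, ce = np.sin(a), np.cos(a), np.sin(elc), np.cos(elc)
    u = np.column_stack([se * ca, se * sa, ce])
    du_da = np.column_stack([-se * sa, se * ca, np.zeros_like(a)])
    du_de = np.column_stack([ce * ca, ce * sa, -se])
    pa = dr_da[:, None] * u + r[:, None] * du_da
    pe = dr_de[:, None] * u + r[:, None] * du_de
    n = np.cross(pe, pa)
    # at the apex pa degenerates; fall back to the radial direction
    bad = np.linalg.norm(n, axis=1) < 1e-9
    n[bad] = u[bad]
    return n / np.linalg.norm(n, axis=1, keepdims=True)


# ----------------------------------------------------------------------------
# Lens design, profile, and mesh
# ----------------------------------------------------------------------------

@dataclass
class LensDesign:
    """Rigid reverse-geometry lens: back zone arcs, front arcs, thickness.

    Radii and widths in mm.  Back zones from centre: base (BOZ), reverse,
    two alignment, peripheral.  Zone widths must sum to diameter/2.
    """

    base_radius: float = 8.80
    base_width: float = 3.00           # BOZD 6.00 mm
    reverse_radius: float = 6.80
    reverse_width: float = 0.60
    alignment1_radius: float = 7.80
    alignment1_width: float = 0.80
    alignment2_radius: float = 8.00
    alignment2_width: float = 0.60
    peripheral_radius: float = 11.50
    peripheral_width: float = 0.30
    front_radii: tuple = (8.70, 8.10, 4.00)
    front_widths: tuple = (3.40, 1.50, 0.40)
    centre_thickness: float = 0.22
    diameter: float = 10.60
    edge_thickness: float = 0.08

    def __post_init__(self) -> None:
        widths = [self.base_width, self.reverse_width, self.alignment1_width,
                  self.alignment2_width, self.peripheral_width]
        radii = [self.base_radius, self.reverse_radius, self.alignment1_radius,
                 self.alignment2_radius, self.peripheral_radius, *self.front_radii]
        if self.centre_thickness <= 0:
            raise ValueError("centre thickness must be positive")
        if any(r <= 0 for r in radii):
            raise ValueError("all curve radii must be positive")
        if abs(sum(widths) - self.diameter / 2) > 1e-9:
            raise ValueError(
                f"back zone widths sum to {sum(widths)}, expected diameter/2 = {self.diameter / 2}")
        if abs(sum(self.front_widths) - self.diameter / 2) > 1e-9:
            raise ValueError("front zone widths must sum to diameter/2")

    @property
    def back_zones(self) -> list[tuple[float, float]]:
        return [(self.base_radius, self.base_width),
                (self.reverse_radius, self.reverse_width),
                (self.alignment1_radius, self.alignment1_width),
                (self.alignment2_radius, self.alignment2_width),
                (self.peripheral_radius, self.peripheral_width)]


def default_lens_design() -> LensDesign:
    return LensDesign()


def _axis_arc_sag(R: float, r: np.ndarray) -> np.ndarray:
    arg = R**2 - r**2
    if np.any(arg <= 0):
        raise MeshError(f"arc radius {R} mm cannot span requested zone")
    return R - np.sqrt(arg)


class LensProfile:
    """Planar (r, z) cross-section of the lens: back and front polylines."""

    def __init__(self, design: LensDesign, n_per_mm: int = 200):
        self.design = design
        rmax = design.diameter / 2
        self.r = np.linspace(0.0, rmax, int(n_per_mm * rmax) + 1)
        self.z_back = self._back(self.r)
        self.z_front_raw = self._front(self.r)
        # enforce a minimum edge thickness so the revolved solid stays valid
        t = self.z_front_raw - self.z_back
        self.z_front = self.z_back + np.maximum(t, design.edge_thickness)

    def _back(self, r: np.ndarray) -> np.ndarray:
        """Axis-centred zone arcs, sag-matched (C0) at junctions; apex z=0."""
        z = np.empty_like(r)
        r_lo, z_lo = 0.0, 0.0
        for R, w in self.design.back_zones:
            r_hi = r_lo + w
            sel = (r >= r_lo - 1e-12) & (r <= r_hi + 1e-12)
            z[sel] = z_lo - (_axis_arc_sag(R, r[sel]) - _axis_arc_sag(R, np.array([r_lo]))[0])
            z_lo = z_lo - (_axis_arc_sag(R, np.array([r_hi]))[0]
                           - _axis_arc_sag(R, np.array([r_lo]))[0])
            r_lo = r_hi
        return z

    def _front(self, r: np.ndarray) -> np.ndarray:
        """Front arcs: central axis-centred, outer zones tangent-matched."""
        d = self.design
        z = np.empty_like(r)
        R0 = d.front_radii[0]
        w0 = d.front_widths[0]
        z0_apex = d.centre_thickness
        sel = r <= w0 + 1e-12
        z[sel] = z0_apex - _axis_arc_sag(R0, r[sel])
        # state at junction
        r_lo = w0
        z_lo = z0_apex - _axis_arc_sag(R0, np.array([r_lo]))[0]
        m = -r_lo / np.sqrt(R0**2 - r_lo**2)
        for R, w in zip(d.front_radii[1:], d.front_widths[1:]):
            r_hi = r_lo + w
            den = np.sqrt(1 + m**2)
            rc = r_lo + m * R / den
            zc = z_lo - R / den
            sel = (r > r_lo + 1e-12) & (r <= r_hi + 1e-12)
            arg = R**2 - (r[sel] - rc) ** 2
            if np.any(arg <= 0):
                raise MeshError(f"front arc radius {R} mm cannot span its zone")
            z[sel] = zc + np.sqrt(arg)
            z_lo = zc + np.sqrt(R**2 - (r_hi - rc) ** 2)
            m = -(r_hi - rc) / (z_lo - zc)
            r_lo = r_hi
        return z

    def back_at(self, r: np.ndarray) -> np.ndarray:
        return np.interp(r, self.r, self.z_back)

    def front_at(self, r: np.ndarray) -> np.ndarray:
        return np.interp(r, self.r, self.z_front)

    def junction_gaps(self) -> np.ndarray:
        """Sag mismatch at back zone junctions (continuity check)."""
        gaps = []
        r_lo, z_lo = 0.0, 0.0
        for R, w in self.design.back_zones:
            r_hi = r_lo + w
            z_end = z_lo - (_axis_arc_sag(R, np.array([r_hi]))[0]
                            - _axis_arc_sag(R, np.array([r_lo]))[0])
            gaps.append(abs(self.back_at(np.array([r_hi]))[0] - z_end))
            r_lo, z_lo = r_hi, z_end
        return np.array(gaps)


def build_lens_profile(design: LensDesign) -> LensProfile:
    """Construct the lens cross-section from its zone arc description."""
    return LensProfile(design)


def build_lens_mesh(design: LensDesign, element_base: int = 4, rings: int = 30,
                    layers: int = 2) -> HexMesh:
    """Revolve the lens profile over the structured disk topology.

    Element count per layer is ``element_base**2 + 4*element_base*rings``.
    Facet sets ``lens_back`` and ``lens_front`` cover the revolved back and
    front surfaces.
    """
    profile = build_lens_profile(design)
    pts2d, quads, _ = disk_grid(element_base, rings)
    rho = np.hypot(pts2d[:, 0], pts2d[:, 1])
    r = rho * design.diameter / 2
    zb = profile.back_at(r)
    zf = profile.front_at(r)
    npl = pts2d.shape[0]
    theta = np.arctan2(pts2d[:, 1], pts2d[:, 0])
    x, y = r * np.cos(theta), r * np.sin(theta)
    node_layers = []
    for k in range(layers + 1):
        z = zb + (zf - zb) * k / layers
        node_layers.append(np.column_stack([x, y, z]))
    nodes = np.vstack(node_layers)
    elems = _extrude_quads_to_hexes(quads, npl, layers)
    nq = quads.shape[0]
    fsets = {
        "lens_back": np.column_stack([np.arange(nq), np.zeros(nq, dtype=int)]),
        "lens_front": np.column_stack([np.arange(nq) + (layers - 1) * nq,
                                       np.ones(nq, dtype=int)]),
    }
    nsets = {"back_nodes": np.arange(npl),
             "front_nodes": np.arange(npl) + layers * npl}
    mesh = HexMesh(nodes, elems, nsets, fsets)
    det = mesh.jacobians()
    if np.any(det <= 0):
        bad = np.unique(np.nonzero(det <= 0)[0])
        raise MeshError(f"lens mesh inverted elements {bad.tolist()[:10]}")
    return mesh


# ----------------------------------------------------------------------------
# Closed spherical shell (solver verification geometry)
# ----------------------------------------------------------------------------

def sphere_shell_mesh(inner_radius: float, outer_radius: float, base: int = 4,
                      rings: int = 12, layers: int = 3) -> HexMesh:
    """Closed thick-walled spherical shell from two glued hemisphere caps.

    Facet sets: ``inner_wall`` (internal pressure), ``outer_wall``.
    """
    pts2d, quads, perimeter = disk_grid(base, rings)
    rho = np.hypot(pts2d[:, 0], pts2d[:, 1])
    theta = np.arctan2(pts2d[:, 1], pts2d[:, 0])
    el = rho * (np.pi / 2)
    npl = pts2d.shape[0]

    def cap_nodes(sign: float) -> np.ndarray:
        layers_pts = []
        for k in range(layers + 1):
            rr = inner_radius + (outer_radius - inner_radius) * k / layers
            layers_pts.append(np.column_stack([
                rr * np.sin(el) * np.cos(theta),
                rr * np.sin(el) * np.sin(theta),
                sign * rr * np.cos(el),
            ]))
        return np.vstack(layers_pts)

    north_nodes = cap_nodes(+1.0)
    north_elems = _extrude_quads_to_hexes(quads, npl, layers)

    # southern cap: mirror z, re-wind quads to keep positive Jacobians,
    # and reuse the shared equator nodes (the disk perimeter at el=90deg)
    south_quads = quads[:, ::-1]
    south_nodes = cap_nodes(-1.0)
    eq = set(perimeter.tolist())
    remap = np.empty(npl * (layers + 1), dtype=np.int64)
    new_nodes = []
    n_next = north_nodes.shape[0]
    for k in range(layers + 1):
        for i in range(npl):
            gid = k * npl + i
            if i in eq:
                remap[gid] = k * npl + i      # same node as the northern cap
            else:
                remap[gid] = n_next
                new_nodes.append(south_nodes[gid])
                n_next += 1
    south_elems = remap[_extrude_quads_to_hexes(south_quads, npl, layers)]

    nodes = np.vstack([north_nodes, np.array(new_nodes)])
    elems = np.vstack([north_elems, south_elems])
    nq = quads.shape[0]
    inner = np.column_stack([np.arange(nq), np.zeros(nq, dtype=int)])
    outer = np.column_stack([np.arange(nq) + (layers - 1) * nq, np.ones(nq, dtype=int)])
    inner_s = np.column_stack([np.arange(nq) + layers * nq, np.zeros(nq, dtype=int)])
    outer_s = np.column_stack([np.arange(nq) + (2 * layers - 1) * nq, np.ones(nq, dtype=int)])
    fsets = {"inner_wall": np.vstack([inner, inner_s]),
             "outer_wall": np.vstack([outer, outer_s])}
    mesh = HexMesh(nodes, elems, {}, fsets)
    det = mesh.jacobians()
    if np.any(det <= 0):
        raise MeshError("sphere shell mesh has inverted elements")
    return mesh
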