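"""Node-to-facet penalty contact with regularised Coulomb friction.

Each slave node is paired with the nearest master facet (by deformed
centroid); the signed gap is the node's offset along the facet normal.
Penetrating nodes receive a penalty force along the facet normal,
reacted uniformly onto the facet's nodes, plus a tangential elastic
force capped at mu times the normal force (friction is tiny here,
mu = 0.01).  The consistent normal-penalty stiffness blocks
(k n n^T between slave and master nodes) enter the tangent matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ..meshing import FACE_NODES


@dataclass
class ContactPair:
    """master facets press back against penetrating slave nodes."""

    name: str
    master_quads: np.ndarray     # (k, 4) node ids of master facets
    slave_nodes: np.ndarray      # (s,) node ids
    penalty: float               # N/mm per slave node
    mu: float = 0.01
    # quadratic force regularisation depth (mm): the normal force grows
    # smoothly from zero over this penetration, killing active-set chatter
    reg_depth: float = 1e-2
    # per-step tangential anchors (set when a step starts)
    anchors: np.ndarray | None = None

    def start_step(self, coords: np.ndarray) -> None:
        self.anchors = coords[self.slave_nodes].copy()

    def convect_anchors(self, coords: np.ndarray) -> None:
        """Slip update at increment acceptance: move each anchor so the
        current friction force is carried elastically (releases the
        accumulated slip without a force jump)."""
        if self.anchors is None:
            return
        _, _, _, _, st = evaluate_contact(self, coords)
        xs = coords[self.slave_nodes]
        act = st.active & (st.kt > 0)
        self.anchors[act] = xs[act] + st.tangential_force[act] / st.kt[act, None]
        self.anchors[~st.active] = xs[~st.active]


@dataclass
class ContactState:
    """Converged-state bookkeeping for one pair."""

    active: np.ndarray            # bool per slave node
    gaps: np.ndarray              # signed gap per slave node (mm)
    normal_force: np.ndarray      # (s,) N, >= 0
    facet_idx: np.ndarray         # paired master facet per slave node
    normals: np.ndarray           # (s, 3)
    tangential_force: np.ndarray | None = None   # (s, 3) N
    kt: np.ndarray | None = None                 # (s,) tangential stiffness


def evaluate_contact(pair: ContactPair, coords: np.ndarray):
    """Forces, tangent triplets and state for the current configuration.

    Returns (f (n_nodes, 3) additive, rows, cols, vals for the tangent in
    COO form, state).
    """
    quads = pair.master_quads
    P = coords[quads]                       # (k, 4, 3)
    cent = P.mean(axis=1)
    n = np.cross(P[:, 2] - P[:, 0], P[:, 3] - P[:, 1])
    n /= np.linalg.norm(n, axis=1, keepdims=True)

    xs = coords[pair.slave_nodes]
    tree = cKDTree(cent)
    _, fid = tree.query(xs)
    nf = n[fid]
    dx = xs - cent[fid]
    gap = np.einsum("ij,ij->i", dx, nf)
    # contact only counts where the node's in-plane projection falls on the
    # paired facet (guards against spurious far-field pairings past a rim)
    e1 = 0.5 * (P[:, 1] + P[:, 2] - P[:, 0] - P[:, 3])   # facet axis 1
    e2 = 0.5 * (P[:, 3] + P[:, 2] - P[:, 0] - P[:, 1])   # facet axis 2
    tang = dx - gap[:, None] * nf
    l1 = np.linalg.norm(e1, axis=1)[fid]
    l2 = np.linalg.norm(e2, axis=1)[fid]
    c1 = np.abs(np.einsum("ij,ij->i", tang, e1[fid])) / np.maximum(l1**2, 1e-30)
    c2 = np.abs(np.einsum("ij,ij->i", tang, e2[fid])) / np.maximum(l2**2, 1e-30)
    on_facet = (c1 <= 1.0) & (c2 <= 1.0)
    depth_cap = np.maximum(l1, l2)
    active = (gap < 0.0) & on_facet & (gap > -depth_cap)

    f = np.zeros_like(coords)
    rows, cols, vals = [], [], []
    s_act = np.flatnonzero(active)
    state = ContactState(active=active, gaps=gap,
                         normal_force=np.zeros(xs.shape[0]),
                         facet_idx=fid, normals=nf,
                         tangential_force=np.zeros_like(xs),
                         kt=np.zeros(xs.shape[0]))
    if s_act.size == 0:
        return f, rows, cols, vals, state

    k = pair.penalty
    g_reg = pair.reg_depth
    pen = -gap[s_act]                        # >= 0
    shallow = pen < g_reg
    fn_mag = np.where(shallow, k * pen**2 / (2 * g_reg), k * (pen - g_reg / 2))
    k_eff = np.where(shallow, k * pen / g_reg, k)
    state.normal_force[s_act] = fn_mag
    fn = fn_mag[:, None] * nf[s_act]         # force on slave, outward
    slave_ids = pair.slave_nodes[s_act]
    np.add.at(f, slave_ids, fn)
    mq = quads[fid[s_act]]                   # (na, 4)
    np.add.at(f, mq.ravel(), np.repeat(-fn / 4.0, 4, axis=0))

    # friction: tangential spring from the step anchor with a smooth
    # (tanh) Coulomb saturation at mu*fn -- a hard cap makes the force
    # discontinuous across iterations and leaves Newton stalled at a
    # mu-sized residual floor
    sticking = np.zeros(s_act.size, dtype=bool)
    kt = 0.1 * k_eff
    if pair.mu > 0 and pair.anchors is not None:
        d = xs[s_act] - pair.anchors[s_act]
        dt = d - np.einsum("ij,ij->i", d, nf[s_act])[:, None] * nf[s_act]
        ft = -kt[:, None] * dt
        ft_mag = np.linalg.norm(ft, axis=1)
        cap = np.maximum(pair.mu * fn_mag, 1e-30)
        ratio = ft_mag / cap
        sticking = ratio < 1.0
        scale = np.where(ratio > 1e-9, np.tanh(ratio) / np.maximum(ratio, 1e-9), 1.0)
        ft *= scale[:, None]
        state.tangential_force[s_act] = ft
        state.kt[s_act] = kt
        np.add.at(f, slave_ids, ft)
        np.add.at(f, mq.ravel(), np.repeat(-ft / 4.0, 4, axis=0))

    # tangent: k (n n^T) normal blocks plus the tangential spring for
    # sticking nodes, slave-slave, slave-master, master-master
    nn = nf[s_act][:, :, None] * nf[s_act][:, None, :]     # (na, 3, 3)
    block = (k_eff[:, None, None] * nn
             + (0.1 * k_eff * sticking)[:, None, None] * (np.eye(3) - nn))
    ids5 = np.column_stack([slave_ids, mq])                # (na, 5)
    W = np.array([1.0, -0.25, -0.25, -0.25, -0.25])
    blocks = np.einsum("i,j,nab->nijab", W, W, block)      # (na, 5, 5, 3, 3)
    ax = np.arange(3)
    rows = (3 * ids5[:, :, None, None, None] + ax[None, None, None, :, None])
    rows = np.broadcast_to(rows, blocks.shape).ravel()
    cols = (3 * ids5[:, None, :, None, None] + ax[None, None, None, None, :])
    cols = np.broadcast_to(cols, blocks.shape).ravel()
    vals = blocks.ravel()
    return f, rows, cols, vals, state
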