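"""8-node hexahedral element kernels.

Near-incompressibility (nu = 0.49) is handled with the B-bar
(mean-dilatation) treatment: the volumetric part of the
strain-displacement matrix is replaced by its element average over the
2x2x2 quadrature points, which controls volumetric locking without a
mixed pressure formulation.  Kinematics are small-strain by default; the
optional finite-displacement path uses a total-Lagrangian
St. Venant-Kirchhoff update with the same mean-dilatation treatment of
the strain (approximate tangent).
"""

from __future__ import annotations

import numpy as np

from ..meshing import HEX_DN

VOIGT = ((0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (0, 2))


def isotropic_D(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """(m, 6, 6) isotropic elasticity in Voigt order xx,yy,zz,xy,yz,zx."""
    E = np.atleast_1d(np.asarray(E, float))
    nu = np.atleast_1d(np.asarray(nu, float))
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    m = E.size
    D = np.zeros((m, 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
    for i in range(3, 6):
        D[:, i, i] = mu
    return D


def gradients(nodes: np.ndarray, elems: np.ndarray):
    """Shape-function gradients in physical coords.

    Returns (dNdX (m, 8gp, 8nodes, 3), detJ (m, 8gp)).
    """
    X = nodes[elems]                                  # (m, 8, 3)
    J = np.einsum("gak,mai->mgki", HEX_DN, X)          # (m, g, 3, 3)
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)            # J_{ki} = dx_i/dxi_k, so dN/dx_i = Jinv_{ik} dN/dxi_k
    dNdX = np.einsum("mgik,gak->mgai", Jinv, HEX_DN)
    return dNdX, detJ


def b_matrices(dNdX: np.ndarray, detJ: np.ndarray):
    """Small-strain B (engineering shear) with mean-dilatation B-bar.

    Returns Bbar (m, 8gp, 6, 24) and quadrature weights w = detJ.
    """
    m, g, a, _ = dNdX.shape
    B = np.zeros((m, g, 6, 24))
    dx, dy, dz = dNdX[..., 0], dNdX[..., 1], dNdX[..., 2]
    for a_ in range(8):
        B[:, :, 0, 3 * a_ + 0] = dx[:, :, a_]
        B[:, :, 1, 3 * a_ + 1] = dy[:, :, a_]
        B[:, :, 2, 3 * a_ + 2] = dz[:, :, a_]
        B[:, :, 3, 3 * a_ + 0] = dy[:, :, a_]
        B[:, :, 3, 3 * a_ + 1] = dx[:, :, a_]
        B[:, :, 4, 3 * a_ + 1] = dz[:, :, a_]
        B[:, :, 4, 3 * a_ + 2] = dy[:, :, a_]
        B[:, :, 5, 3 * a_ + 0] = dz[:, :, a_]
        B[:, :, 5, 3 * a_ + 2] = dx[:, :, a_]
    # volumetric part and its element mean
    Bvol = np.zeros_like(B)
    row_dil = (B[:, :, 0] + B[:, :, 1] + B[:, :, 2]) / 3.0      # (m, g, 24)
    for i in range(3):
        Bvol[:, :, i] = row_dil
    w = detJ
    vol = w.sum(axis=1)
    Bvol_mean = np.einsum("mgik,mg->mik", Bvol, w) / vol[:, None, None]
    Bbar = B - Bvol + Bvol_mean[:, None, :, :]
    return Bbar, w


def element_stiffness(nodes: np.ndarray, elems: np.ndarray,
                      E: np.ndarray, nu: np.ndarray):
    """Ke (m, 24, 24) plus (Bbar, w, D) for stress recovery."""
    dNdX, detJ = gradients(nodes, elems)
    if np.any(detJ <= 0):
        raise ValueError("non-positive Jacobian during stiffness assembly")
    Bbar, w = b_matrices(dNdX, detJ)
    D = isotropic_D(E, nu)
    DB = np.einsum("mij,mgjk->mgik", D, Bbar)
    Ke = np.einsum("mgji,mgjk,mg->mik", Bbar, DB, w)
    return Ke, Bbar, w, D, dNdX


def gp_stresses(Bbar: np.ndarray, D: np.ndarray, elems: np.ndarray,
                u: np.ndarray) -> np.ndarray:
    """Small-strain Gauss-point stresses (m, 8gp, 6) from nodal displacements."""
    ue = u[elems].reshape(elems.shape[0], 24)
    eps = np.einsum("mgik,mk->mgi", Bbar, ue)
    return np.einsum("mij,mgj->mgi", D, eps)


def deformation_gradients(dNdX: np.ndarray, elems: np.ndarray,
                          u: np.ndarray) -> np.ndarray:
    """F = I + du/dX at the Gauss points, (m, 8gp, 3, 3)."""
    ue = u[elems]                                      # (m, 8, 3)
    grad = np.einsum("mai,mgaj->mgij", ue, dNdX)
    return grad + np.eye(3)


def voigt_to_tensor(s: np.ndarray) -> np.ndarray:
    """(..., 6) Voigt stress -> (..., 3, 3) symmetric tensor."""
    out = np.zeros(s.shape[:-1] + (3, 3))
    out[..., 0, 0] = s[..., 0]
    out[..., 1, 1] = s[..., 1]
    out[..., 2, 2] = s[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = s[..., 3]
    out[..., 1, 2] = out[..., 2, 1] = s[..., 4]
    out[..., 0, 2] = out[..., 2, 0] = s[..., 5]
    return out


def log_strain_tensors(F: np.ndarray) -> np.ndarray:
    """Logarithmic (Hencky) strain ln V from F, (..., 3, 3)."""
    b = F @ np.swapaxes(F, -1, -2)          # left Cauchy-Green
    lam2, vecs = np.linalg.eigh(b)
    lam2 = np.clip(lam2, 1e-30, None)
    logl = 0.5 * np.log(lam2)
    return np.einsum("...ik,...k,...jk->...ij", vecs, logl, vecs)
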