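"""Programmatic generators of test structures.

Every input the analyses need can be built here deterministically, with
geometry known by construction: dihedral-defined poly-alanine backbones
(sequential internal-to-Cartesian placement), ideal helix / strand /
random-coil chains, paired antiparallel strands with an inter-strand
hydrogen-bond register, hollow shells of known internal cavity volume,
mirrored (D-chirality) structures, Gaussian-perturbed conformer
ensembles, and compact helix bundles for packing calibration.

Backbone bond lengths and angles are the same reference constants the
quality checks standardize against, so a backbone built at its defaults
scores zero geometric deviation by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .conformation_analysis import (
    CHIRAL_REF_ANGLE,
    REF_BOND_ANGLES,
    REF_BOND_LENGTHS,
    hbond_energy,
    phi_psi,
    place_amide_hydrogen,
)
from .structure_io import Atom, CATrace, Ensemble, StructureModel

__all__ = [
    "BackboneSpec",
    "build_backbone",
    "ideal_helix",
    "ideal_strand",
    "random_coil",
    "strand_pair",
    "helix_bundle",
    "hollow_shell",
    "mirror",
    "perturb_ensemble",
    "HELIX_PHI_PSI",
    "STRAND_PHI_PSI",
]

# Canonical torsion sets (degrees): textbook alpha-helix and antiparallel
# beta-strand values.
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)

_B_N_CA = REF_BOND_LENGTHS[("N", "CA")][0]
_B_CA_C = REF_BOND_LENGTHS[("CA", "C")][0]
_B_C_N = REF_BOND_LENGTHS[("C", "N")][0]
_B_C_O = REF_BOND_LENGTHS[("C", "O")][0]
_A_N_CA_C = REF_BOND_ANGLES[("N", "CA", "C")][0]
_A_CA_C_N = REF_BOND_ANGLES[("CA", "C", "N")][0]
_A_C_N_CA = REF_BOND_ANGLES[("C", "N", "CA")][0]
_A_CA_C_O = REF_BOND_ANGLES[("CA", "C", "O")][0]
_B_CA_CB = 1.521
_A_C_CA_CB = 110.1


@dataclass
class BackboneSpec:
    """Internal-coordinate description of a backbone to build."""

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray | None = None
    res_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.psi = np.atleast_1d(np.asarray(self.psi, dtype=float))
        if len(self.phi) != len(self.psi):
            raise ValueError("phi and psi must have equal length")
        n = len(self.phi)
        if self.omega is None:
            self.omega = np.full(n, 180.0)
        else:
            self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
            if len(self.omega) != n:
                raise ValueError("omega must match phi/psi length")
        if self.res_names is None:
            self.res_names = ["ALA"] * n
        elif len(self.res_names) != n:
            raise ValueError("res_names must match phi/psi length")

    def __len__(self) -> int:
        return len(self.phi)


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d bonded to c with |cd| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (natural-extension chain placement)."""
    if not (0.0 < angle_deg < 180.0):
        raise ValueError(f"impossible bond angle {angle_deg}°")
    th = math.radians(angle_deg)
    ph = -math.radians(torsion_deg)  # sign chosen so dihedral(a,b,c,d) = +torsion_deg
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(th), bond * math.sin(th) * math.cos(ph),
         bond * math.sin(th) * math.sin(ph)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(spec: BackboneSpec, chain_id: str = "A") -> StructureModel:
    """Build Cartesian coordinates for a dihedral-defined backbone.

    Atoms per residue: N, CA, C, O and (except glycine) CB placed at the
    L-configuration reference chirality.  Round-trip property: measuring
    phi/psi on the built model recovers the spec's angles to well under
    0.5°.
    """
    nres = len(spec)
    if nres < 2:
        raise ValueError("backbone needs at least 2 residues")

    N = np.zeros((nres, 3))
    CA = np.zeros((nres, 3))
    C = np.zeros((nres, 3))

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])

    for i in range(1, nres):
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, spec.psi[i - 1])
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, spec.omega[i])
        C[i] = _place(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, spec.phi[i])

    atoms: list[Atom] = []
    for i in range(nres):
        res = spec.res_names[i]
        idx = i + 1
        atoms.append(Atom("N", "N", idx, res, chain_id, N[i]))
        atoms.append(Atom("CA", "C", idx, res, chain_id, CA[i]))
        if res != "GLY":
            cb = _place(N[i], C[i], CA[i], _B_CA_CB, _A_C_CA_CB, CHIRAL_REF_ANGLE)
            atoms.append(Atom("CB", "C", idx, res, chain_id, cb))
        atoms.append(Atom("C", "C", idx, res, chain_id, C[i]))
        # carbonyl O antiperiplanar to the next N: dihedral(N, CA, C, O) = psi + 180
        o = _place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, spec.psi[i] + 180.0)
        atoms.append(Atom("O", "O", idx, res, chain_id, o))
    return StructureModel(atoms)


def _uniform_spec(n: int, phi: float, psi: float) -> BackboneSpec:
    return BackboneSpec(np.full(n, phi), np.full(n, psi))


def ideal_helix(n: int) -> StructureModel:
    """Poly-alanine alpha-helix at (phi, psi) = (-57, -47)."""
    if n < 5:
        raise ValueError("fixture chains need at least 5 residues")
    return build_backbone(_uniform_spec(n, *HELIX_PHI_PSI))


def ideal_strand(n: int) -> StructureModel:
    """Poly-alanine extended strand at (phi, psi) = (-139, 135)."""
    if n < 5:
        raise ValueError("fixture chains need at least 5 residues")
    return build_backbone(_uniform_spec(n, *STRAND_PHI_PSI))


def random_coil(n: int, seed: int) -> StructureModel:
    """Poly-alanine chain with phi/psi sampled uniformly outside the
    helix and strand basins (30° exclusion radius), deterministic in
    *seed*."""
    if n < 5:
        raise ValueError("fixture chains need at least 5 residues")
    rng = np.random.default_rng(seed)
    phi = np.empty(n)
    psi = np.empty(n)
    basins = np.array([HELIX_PHI_PSI, STRAND_PHI_PSI])
    for i in range(n):
        while True:
            cand = rng.uniform(-180.0, 180.0, size=2)
            d = np.abs((cand - basins + 180.0) % 360.0 - 180.0)
            if np.all(np.hypot(d[:, 0], d[:, 1]) > 30.0):
                phi[i], psi[i] = cand
                break
    return build_backbone(BackboneSpec(phi, psi))


# ---------------------------------------------------------------------------
# Paired antiparallel strands
# ---------------------------------------------------------------------------

def _rigid_apply(params: np.ndarray, coords: np.ndarray) -> np.ndarray:
    rot = Rotation.from_rotvec(params[:3])
    return coords @ rot.as_matrix().T + params[3:]


def strand_pair(n: int = 8) -> StructureModel:
    """Two antiparallel ideal strands placed in hydrogen-bond register.

    Strand B is a rigidly transformed copy of strand A (proper rotation,
    so chirality is preserved); its placement is found by minimising the
    Kabsch-Sander energies of the intended inter-strand N-H···O=C pairs.
    Residues are numbered consecutively with a 10-residue index gap
    between strands so that no backbone connectivity is implied.
    """
    if n < 6:
        raise ValueError("strand pair needs at least 6 residues per strand")
    model_a = ideal_strand(n)
    coords_a = model_a.coords()

    # initial guess: rotate 180° about the x axis (roughly the strand
    # axis is x after building), shift sideways by ~4.8 Å
    ca = np.array([a.coord for a in model_a.atoms if a.name == "CA"])
    axis = ca[-1] - ca[0]
    axis = axis / np.linalg.norm(axis)
    x0 = np.concatenate([axis * math.pi, ca.mean(axis=0) * 0 + np.array([0.0, 4.8, 0.0])])

    # intended antiparallel register: residue i of A pairs with residue
    # n-1-i of B; alternating residues form the two-bond "wide" pairs
    pairs = [(i, n - 1 - i) for i in range(1, n - 1, 2)]

    def merged(params: np.ndarray) -> StructureModel:
        atoms = [Atom(a.name, a.element, a.res_index, a.res_name, "A", a.coord.copy())
                 for a in model_a.atoms]
        moved = _rigid_apply(params, coords_a)
        for a, xyz in zip(model_a.atoms, moved):
            atoms.append(Atom(a.name, a.element, a.res_index + n + 10, a.res_name,
                              "A", xyz))
        return StructureModel(atoms)

    def objective(params: np.ndarray) -> float:
        geom = phi_psi(place_amide_hydrogen(merged(params)))
        total = 0.0
        for i, j in pairs:
            jj = n + j  # strand B residues follow strand A in the chain
            for d, a in ((i, jj), (jj, i)):
                e = hbond_energy(d, a, geom)
                if np.isfinite(e):
                    total += max(e, -4.0)  # clip so one contact cannot dominate
        return total

    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-4, "fatol": 1e-6})
    return merged(res.x)


def helix_bundle(n_helices: int = 4, helix_len: int = 16, spacing: float = 10.0) -> StructureModel:
    """Compact bundle of parallel/antiparallel ideal helices on a square
    lattice — a desk-scale stand-in for a well-packed globular core, used
    to calibrate and test the packing score."""
    base = ideal_helix(helix_len)
    ca = np.array([a.coord for a in base.atoms if a.name == "CA"])
    # align the helix axis with z
    axis = ca[-1] - ca[0]
    axis = axis / np.linalg.norm(axis)
    rot, _ = Rotation.align_vectors(np.array([[0.0, 0.0, 1.0]]), axis[None, :])
    coords = (base.coords() - ca.mean(axis=0)) @ rot.as_matrix().T

    offsets = []
    side = math.ceil(math.sqrt(n_helices))
    for k in range(n_helices):
        offsets.append(np.array([(k % side) * spacing, (k // side) * spacing, 0.0]))

    atoms: list[Atom] = []
    res_offset = 0
    flip = Rotation.from_euler("x", 180, degrees=True).as_matrix()
    for k, off in enumerate(offsets):
        xyz = coords @ flip.T if k % 2 else coords.copy()
        for a, p in zip(base.atoms, xyz):
            atoms.append(Atom(a.name, a.element, a.res_index + res_offset, a.res_name,
                              "A", p + off))
        res_offset += helix_len
    return StructureModel(atoms)


# ---------------------------------------------------------------------------
# Cavity fixtures
# ---------------------------------------------------------------------------

_SHELL_PAD = 1.70 + 1.40  # carbon vdW + water probe: void measured at default params


def _fibonacci_sphere(r: float, count: int) -> np.ndarray:
    k = np.arange(count) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / count)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return r * np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def hollow_shell(
    outer_r: float,
    inner_r: float,
    atom_spacing: float = 1.2,
    channel_width: float | None = None,
) -> StructureModel:
    """Spherical shell of carbon pseudo-atoms enclosing a void.

    *inner_r* is the radius of the accessible void as measured with the
    default probe (1.4 Å) and carbon vdW radius: the innermost
    atom-centre shell sits at inner_r + 3.1 Å so that probe-inflated
    occupancy leaves exactly a radius-inner_r cavity.  ``inner_r = 0``
    gives a solid ball with no void.  *channel_width*, if set, bores an
    open channel of that accessible width along +z connecting the void
    to the outside.
    """
    if inner_r < 0 or outer_r <= inner_r + 2 * atom_spacing:
        raise ValueError("need outer_r > inner_r + 2*atom_spacing and inner_r >= 0")
    if inner_r == 0:
        radii = np.arange(0.0, outer_r + 1e-9, atom_spacing)
    else:
        start = inner_r + _SHELL_PAD
        if start + atom_spacing > outer_r:
            raise ValueError(
                f"outer_r={outer_r} leaves no room for shells at >= {start:.2f} Å"
            )
        radii = np.arange(start, outer_r + 1e-9, atom_spacing)

    pts: list[np.ndarray] = []
    for r in radii:
        if r == 0.0:
            pts.append(np.zeros((1, 3)))
            continue
        count = max(int(math.ceil(4.0 * math.pi * r * r / atom_spacing**2)), 12)
        pts.append(_fibonacci_sphere(r, count))
    coords = np.concatenate(pts, axis=0)

    if channel_width is not None:
        keep_r = channel_width / 2.0 + _SHELL_PAD
        rho = np.hypot(coords[:, 0], coords[:, 1])
        keep = ~((rho < keep_r) & (coords[:, 2] > 0))
        coords = coords[keep]

    atoms = [
        Atom("C", "C", i + 1, "UNK", "A", xyz) for i, xyz in enumerate(coords)
    ]
    return StructureModel(atoms)


# ---------------------------------------------------------------------------
# Mirroring and ensembles
# ---------------------------------------------------------------------------

def mirror(model: StructureModel) -> StructureModel:
    """Mirror image: negate the x coordinate of every atom (involution)."""
    out = model.copy()
    for a in out.atoms:
        a.coord = a.coord * np.array([-1.0, 1.0, 1.0])
    return out


def perturb_ensemble(model: StructureModel, sigma: float, n_models: int,
                     seed: int) -> Ensemble:
    """Ensemble of *n_models* copies with iid Gaussian coordinate noise
    (std *sigma* Å per component); the first model is the unperturbed
    input.  Deterministic in *seed*."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rng = np.random.default_rng(seed)
    models = []
    for k in range(n_models):
        m = model.copy()
        m.model_id = k + 1
        if k > 0:
            for a in m.atoms:
                a.coord = a.coord + rng.normal(0.0, sigma, size=3)
        models.append(m)
    return Ensemble(models)
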