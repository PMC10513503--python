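"""Boundary-element forward model for piecewise-homogeneous torso conductors.

The potential generated by a current dipole inside a volume conductor made of
nested homogeneous compartments satisfies a surface integral equation: at a
point r on interface S_k,

    (sigma_k^- + sigma_k^+)/2 * phi(r)
        = g(r) + sum_l (sigma_l^- - sigma_l^+)/(4*pi) * \\int_{S_l} phi dOmega,

where g(r) = p . (r - r0) / (4*pi |r - r0|^3) is the (conductivity-free)
primary dipole term and dOmega is the solid angle element of the surface seen
from r (a closed surface subtends 4*pi from inside in this physical sign;
the geometry module's convention is the negative of this).

Discretisation is vertex collocation: potentials live at mesh vertices and
each triangle's analytic solid angle is lumped in equal thirds onto its
corners. The own-vertex (auto solid angle) coefficient is fixed by the
row-sum identity — the angles a closed surface presents to one of its own
points must total 2*pi — which also makes constant potentials an exact
solution of the discrete system. The assembled operator has a rank-1 null
space (potentials are defined up to a constant because the exterior is
insulating); it is removed by deflation with the constant vector on the
outermost surface, and all outputs are re-referenced to zero mean over the
torso vertices.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .geometry import ElectrodeMontage, TriMesh, mesh_solid_angles, points_inside

__all__ = [
    "VolumeConductor",
    "TransferStack",
    "BEMSystem",
    "infinite_medium_potential",
    "assemble_bem",
    "build_transfer_matrix",
    "build_transfer_stack",
    "forward_bsp",
    "save_transfer_stack",
    "load_transfer_stack",
]

#: default bulk torso conductivity, S/m
TORSO_CONDUCTIVITY = 0.2
#: conductivity of lung tissue relative to torso (air-filled lungs)
LUNG_RATIO = 0.25
#: conductivity of blood-filled heart cavities relative to torso
CAVITY_RATIO = 3.0


@dataclass(frozen=True)
class VolumeConductor:
    """Nested closed surfaces with per-surface inside/outside conductivities.

    ``surfaces[0]`` is the outermost torso boundary (``sigma_out[0]`` must be
    0: insulating exterior). Inner surfaces bound organ compartments — lungs
    and blood cavities in the cardiac application — and must lie strictly
    inside the torso.
    """

    surfaces: tuple
    sigma_in: np.ndarray
    sigma_out: np.ndarray
    montage: ElectrodeMontage

    def __post_init__(self):
        object.__setattr__(self, "surfaces", tuple(self.surfaces))
        object.__setattr__(self, "sigma_in", np.asarray(self.sigma_in, dtype=np.float64))
        object.__setattr__(self, "sigma_out", np.asarray(self.sigma_out, dtype=np.float64))
        ns = len(self.surfaces)
        if not (self.sigma_in.size == self.sigma_out.size == ns):
            raise ValueError("one sigma_in/sigma_out pair per surface required")
        if self.sigma_out[0] != 0.0:
            raise ValueError("outermost surface must have sigma_out = 0 (insulating exterior)")
        if np.any(self.sigma_in + self.sigma_out <= 0):
            raise ValueError("sigma_in + sigma_out must be positive on every surface")
        if self.montage.vertex_ids.max() >= self.surfaces[0].n_vertices:
            raise ValueError("montage indices exceed torso vertex count")

    def validate_nesting(self, n_samples: int = 8) -> None:
        """Verify (on a vertex sample) that inner surfaces are inside the torso."""
        torso = self.surfaces[0]
        for s in self.surfaces[1:]:
            idx = np.linspace(0, s.n_vertices - 1, n_samples).astype(int)
            if not points_inside(torso, s.vertices[idx]).all():
                raise ValueError(f"surface {s.name!r} is not contained in the torso")

    @property
    def n_surfaces(self) -> int:
        return len(self.surfaces)

    @property
    def n_electrodes(self) -> int:
        return self.montage.n_electrodes

    def geometry_hash(self) -> str:
        h = hashlib.sha256()
        for s in self.surfaces:
            h.update(s.vertices.tobytes())
            h.update(s.triangles.tobytes())
        h.update(self.sigma_in.tobytes())
        h.update(self.sigma_out.tobytes())
        h.update(self.montage.vertex_ids.tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class TransferStack:
    """Per-candidate-position transfer matrices.

    ``blocks[j]`` is the M x 3 lead-field of a unit dipole at ``positions[j]``:
    column k holds the electrode potentials of a unit dipole along axis k
    (ordered X, Y, Z). Candidate positions are the vertices of the
    endo-epicardial heart mesh.
    """

    positions: np.ndarray  # (J, 3) mm
    blocks: np.ndarray  # (J, M, 3)
    conductor_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=np.float64))
        object.__setattr__(self, "blocks", np.asarray(self.blocks, dtype=np.float64))
        if self.blocks.ndim != 3 or self.blocks.shape[2] != 3:
            raise ValueError("blocks must have shape (J, M, 3)")
        if self.positions.shape != (self.blocks.shape[0], 3):
            raise ValueError("positions must have shape (J, 3) matching blocks")
        if self.blocks.shape[0] == 0:
            raise ValueError("transfer stack needs at least one candidate position")
        s3 = np.linalg.svd(self.blocks, compute_uv=False)[:, 2]
        if np.any(s3 <= 0):
            raise ValueError("rank-deficient transfer block (sigma_3 = 0)")

    @property
    def n_positions(self) -> int:
        return self.blocks.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.blocks.shape[1]

    def subset_electrodes(self, rows: np.ndarray) -> "TransferStack":
        """Restrict every block to the given electrode rows (identical subset)."""
        rows = np.asarray(rows, dtype=np.int64)
        return TransferStack(self.positions, self.blocks[:, rows, :], self.conductor_id + f"|rows{len(rows)}")


def infinite_medium_potential(src, moment, field_pts, sigma: float) -> np.ndarray:
    """Potential of a current dipole in an unbounded homogeneous medium.

    phi(r) = p . (r - src) / (4*pi*sigma*|r - src|^3); moment in mA.mm and
    distances in mm give phi in mV for sigma in S/m (units consistent up to
    the common 1e-3 scale carried through the whole pipeline).
    """
    src = np.asarray(src, dtype=np.float64)
    moment = np.asarray(moment, dtype=np.float64)
    r = np.atleast_2d(np.asarray(field_pts, dtype=np.float64)) - src
    d = np.linalg.norm(r, axis=1)
    if np.any(d == 0):
        raise ValueError("field point coincides with the source position")
    return (r @ moment) / (4.0 * np.pi * sigma * d**3)


class BEMSystem:
    """Assembled and LU-factorised boundary-element system for one conductor.

    Holds the vertex table of all surfaces, the deflated collocation matrix
    factorisation, and the bookkeeping needed to turn a dipole position into
    transfer-matrix columns. Built once per conductor and reused for every
    candidate source.
    """

    def __init__(self, vc: VolumeConductor):
        vc.validate_nesting()
        self.conductor = vc
        self.offsets = np.cumsum([0] + [s.n_vertices for s in vc.surfaces])
        self.n_total = int(self.offsets[-1])
        self.all_vertices = np.concatenate([s.vertices for s in vc.surfaces])
        self.n_torso = vc.surfaces[0].n_vertices
        A = self._assemble()
        # deflation: remove the constant null vector through the torso block
        n0 = self.n_torso
        A[:n0, :n0] += 1.0 / n0
        self.lu = sla.lu_factor(A)
        self.condition_estimate = None

    def _assemble(self) -> np.ndarray:
        vc = self.conductor
        N = self.n_total
        A = np.zeros((N, N))
        # surface membership of each collocation vertex
        for k, sk in enumerate(vc.surfaces):
            ck = 0.5 * (vc.sigma_in[k] + vc.sigma_out[k])
            idx = np.arange(self.offsets[k], self.offsets[k + 1])
            A[idx, idx] += ck
        for l, sl in enumerate(vc.surfaces):
            coef = (vc.sigma_in[l] - vc.sigma_out[l]) / (4.0 * np.pi)
            if coef == 0.0:
                continue
            cols = slice(self.offsets[l], self.offsets[l + 1])
            W = self._lumped_weights(sl)  # (N_obs_total, n_vertices of sl), physical sign
            A[:, cols] -= coef * W
        return A

    def _lumped_weights(self, surf: TriMesh) -> np.ndarray:
        """Physical-sign solid-angle weights of ``surf`` at every collocation
        vertex, lumped per triangle in thirds onto its corners; own-surface
        rows get the auto term fixed so they sum to exactly 2*pi."""
        vc = self.conductor
        tri = surf.triangles
        n_obs = self.n_total
        W = np.zeros((n_obs, surf.n_vertices))
        own = None
        for k, sk in enumerate(vc.surfaces):
            if sk is surf:
                own = k
        for i in range(n_obs):
            obs = self.all_vertices[i]
            k = int(np.searchsorted(self.offsets, i, side="right") - 1)
            if k == own:
                local = i - self.offsets[k]
                skip = np.any(tri == local, axis=1)
                omega = -mesh_solid_angles(surf, obs, skip=skip)  # physical sign
            else:
                omega = -mesh_solid_angles(surf, obs)
            np.add.at(W[i], tri[:, 0], omega / 3.0)
            np.add.at(W[i], tri[:, 1], omega / 3.0)
            np.add.at(W[i], tri[:, 2], omega / 3.0)
            if k == own:
                local = i - self.offsets[k]
                W[i, local] = 0.0
                W[i, local] = 2.0 * np.pi - W[i].sum()
        return W

    def solve_sources(self, src_positions: np.ndarray) -> np.ndarray:
        """Surface potentials for unit dipoles along X, Y, Z at each source.

        Returns an array (J, n_total, 3); potentials are re-referenced to zero
        mean over the torso vertices.
        """
        src_positions = np.atleast_2d(np.asarray(src_positions, dtype=np.float64))
        J = src_positions.shape[0]
        r = self.all_vertices[None, :, :] - src_positions[:, None, :]  # (J, N, 3)
        d3 = np.linalg.norm(r, axis=2) ** 3
        if np.any(d3 == 0):
            raise ValueError("source coincides with a surface vertex")
        G = r / (4.0 * np.pi * d3[:, :, None])  # (J, N, 3): g for unit moment each axis
        rhs = G.transpose(1, 0, 2).reshape(self.n_total, 3 * J)
        phi = sla.lu_solve(self.lu, rhs)
        phi = phi.reshape(self.n_total, J, 3).transpose(1, 0, 2)
        phi -= phi[:, : self.n_torso, :].mean(axis=1, keepdims=True)
        return phi

    def check_source_region(self, src_positions: np.ndarray) -> None:
        """Sources must be strictly inside the torso and outside every organ."""
        src_positions = np.atleast_2d(src_positions)
        vc = self.conductor
        if not points_inside(vc.surfaces[0], src_positions).all():
            raise ValueError("source position outside the torso surface")
        for s in vc.surfaces[1:]:
            if points_inside(s, src_positions).any():
                raise ValueError(f"source position inside organ surface {s.name!r}")


def assemble_bem(vc: VolumeConductor) -> BEMSystem:
    """Assemble, deflate and factorise the BEM system for a conductor."""
    return BEMSystem(vc)


def build_transfer_matrix(vc_or_system, src) -> np.ndarray:
    """M x 3 transfer matrix for one dipole position.

    Column k holds the montage-electrode potentials of a unit dipole along
    axis k at ``src`` (zero-mean referenced over torso vertices). Accepts a
    :class:`VolumeConductor` (assembled on the fly) or a pre-assembled
    :class:`BEMSystem`.
    """
    system = vc_or_system if isinstance(vc_or_system, BEMSystem) else assemble_bem(vc_or_system)
    system.check_source_region(np.atleast_2d(src))
    phi = system.solve_sources(np.atleast_2d(src))[0]
    return phi[system.conductor.montage.vertex_ids, :]


def build_transfer_stack(vc_or_system, heart: TriMesh) -> TransferStack:
    """Transfer matrices for all heart-mesh vertices, sharing one factorisation."""
    system = vc_or_system if isinstance(vc_or_system, BEMSystem) else assemble_bem(vc_or_system)
    system.check_source_region(heart.vertices)
    phi = system.solve_sources(heart.vertices)  # (J, N, 3)
    blocks = phi[:, system.conductor.montage.vertex_ids, :]
    return TransferStack(heart.vertices, blocks, system.conductor.geometry_hash())


def forward_bsp(block: np.ndarray, moments: np.ndarray, sample_rate: float = 1000.0, labels=None):
    """Body-surface potentials of a dipole trajectory: Phi = block @ moments.

    ``moments`` is 3 x T (mA.mm); returns a :class:`~ecgidipole.inverse.BSPMap`.
    """
    from .inverse import BSPMap

    block = np.asarray(block, dtype=np.float64)
    moments = np.asarray(moments, dtype=np.float64)
    if block.ndim != 2 or block.shape[1] != 3 or moments.ndim != 2 or moments.shape[0] != 3:
        raise ValueError(f"shape mismatch: block {block.shape}, moments {moments.shape}")
    if labels is None:
        labels = [f"E{i}" for i in range(block.shape[0])]
    return BSPMap(block @ moments, sample_rate=sample_rate, electrode_labels=labels)


def save_transfer_stack(stack: TransferStack, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=stack.positions)
        f.create_dataset("blocks", data=stack.blocks)
        f.attrs["conductor_id"] = stack.conductor_id


def load_transfer_stack(path) -> TransferStack:
    import h5py

    with h5py.File(path, "r") as f:
        return TransferStack(f["positions"][...], f["blocks"][...], str(f.attrs.get("conductor_id", "")))
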