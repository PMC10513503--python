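"""Self-contained torso phantoms with known dipole ground truth.

The generator emulates the study conditions the pipeline assumes: a strip
montage of 16 x 8 = 128 torso electrodes, a nested ellipsoidal geometry
(torso, ventricular surface, optionally two lungs and two blood cavities),
and a noisy 30-sample / 1 kHz body-surface map of an averaged ectopic beat
whose source is a single dipole fixed at a known heart-mesh vertex. All
surfaces are subdivided icosahedra scaled to ellipsoids, so every phantom is
bit-reproducible from its spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import trimesh as _trimesh

from .bem import (
    CAVITY_RATIO,
    LUNG_RATIO,
    TORSO_CONDUCTIVITY,
    VolumeConductor,
    assemble_bem,
    build_transfer_matrix,
    forward_bsp,
)
from .geometry import TriMesh, place_electrode_strips
from .inverse import BSPMap

__all__ = ["PhantomSpec", "ellipsoid_mesh", "make_phantom", "simulate_pvc_map"]


def ellipsoid_mesh(center, semiaxes, refinement: int, name: str = "ellipsoid") -> TriMesh:
    """Subdivided-icosahedron ellipsoid: 10 * 4**refinement + 2 vertices."""
    ico = _trimesh.creation.icosphere(subdivisions=refinement, radius=1.0)
    v = np.asarray(ico.vertices) * np.asarray(semiaxes, dtype=np.float64)
    v = v + np.asarray(center, dtype=np.float64)
    return TriMesh(v, np.asarray(ico.faces), name).validate()


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, montage, source and noise parameters of one phantom.

    Dimensions are millimetres. The default torso is an adult-sized ellipsoid
    (semi-axes 150 x 110 x 280 mm); the ventricular surface is an ellipsoid
    of roughly left-ventricular size placed anteriorly left in the chest.
    ``snr_db`` is the global signal-to-noise ratio of the map in dB
    (``inf`` = noise-free); the default 20 dB represents a conservatively
    noisy averaged beat.
    """

    torso_semiaxes: tuple = (150.0, 110.0, 280.0)
    heart_center: tuple = (35.0, 25.0, 60.0)
    heart_semiaxes: tuple = (45.0, 40.0, 55.0)
    include_lungs: bool = False
    include_cavities: bool = False
    lung_centers: tuple = ((-85.0, -30.0, 100.0), (85.0, -30.0, 100.0))
    lung_semiaxes: tuple = (26.0, 36.0, 85.0)
    cavity_centers: tuple = ((17.0, 25.0, 60.0), (53.0, 25.0, 60.0))
    cavity_semiaxes: tuple = (14.0, 18.0, 26.0)
    torso_refinement: int = 3
    heart_refinement: int = 2
    organ_refinement: int = 2
    n_strips: int = 16
    per_strip: int = 8
    z_range: tuple = (0.2, 0.8)
    torso_conductivity: float = TORSO_CONDUCTIVITY
    lung_ratio: float = LUNG_RATIO
    cavity_ratio: float = CAVITY_RATIO
    true_vertex: int = 0
    snr_db: float = 20.0
    seed: int = 0
    n_samples: int = 30
    sample_rate: float = 1000.0
    peak_moment: float = 15.0  # mA.mm, adult equivalent-dipole scale
    inverse_crime: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        def tt(x):
            return tuple(tt(i) for i in x) if isinstance(x, (list, tuple)) else x

        return cls(**{k: tt(v) for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)


def make_phantom(spec: PhantomSpec):
    """Build the phantom's volume conductor and candidate-source heart mesh.

    Returns ``(VolumeConductor, heart TriMesh)``. The heart surface is not a
    conductivity interface (myocardium is assigned the bulk torso
    conductivity); it only carries the candidate dipole positions. Nesting and
    organ containment are verified geometrically.
    """
    torso = ellipsoid_mesh((0.0, 0.0, 0.0), spec.torso_semiaxes, spec.torso_refinement, "torso")
    heart = ellipsoid_mesh(spec.heart_center, spec.heart_semiaxes, spec.heart_refinement, "heart")
    surfaces = [torso]
    sig = spec.torso_conductivity
    sigma_in, sigma_out = [sig], [0.0]
    if spec.include_lungs:
        for i, c in enumerate(spec.lung_centers):
            surfaces.append(ellipsoid_mesh(c, spec.lung_semiaxes, spec.organ_refinement, f"lung{i}"))
            sigma_in.append(spec.lung_ratio * sig)
            sigma_out.append(sig)
    if spec.include_cavities:
        for i, c in enumerate(spec.cavity_centers):
            surfaces.append(
                ellipsoid_mesh(c, spec.cavity_semiaxes, spec.organ_refinement, f"cavity{i}")
            )
            sigma_in.append(spec.cavity_ratio * sig)
            sigma_out.append(sig)
    montage = place_electrode_strips(torso, spec.n_strips, spec.per_strip, spec.z_range)
    vc = VolumeConductor(tuple(surfaces), sigma_in, sigma_out, montage)
    vc.validate_nesting()
    _check_disjoint(surfaces[1:])
    return vc, heart


def _check_disjoint(organs) -> None:
    from .geometry import points_inside

    for i, a in enumerate(organs):
        for b in organs[i + 1 :]:
            idx = np.linspace(0, b.n_vertices - 1, 8).astype(int)
            if points_inside(a, b.vertices[idx]).any():
                raise ValueError(f"organ surfaces {a.name!r} and {b.name!r} overlap")


def simulate_pvc_map(vc: VolumeConductor, heart: TriMesh, spec: PhantomSpec, system=None):
    """Forward-simulate a noisy ectopic-beat map with known dipole ground truth.

    The source is a dipole fixed at heart vertex ``spec.true_vertex`` with a
    seeded random unit direction and a linearly ramping magnitude over the
    ``n_samples`` window — the minimal trajectory consistent with a growing
    early-activation wavefront of constant orientation. Zero-mean Gaussian
    noise is added so that the realized global SNR (signal power over noise
    power, on the vectorized clean map) equals ``snr_db`` in expectation.

    Returns ``(BSPMap, truth position, true 3 x T moments)``.
    """
    if not (0 <= spec.true_vertex < heart.n_vertices):
        raise ValueError(f"true_vertex {spec.true_vertex} invalid for heart with {heart.n_vertices} vertices")
    rng = np.random.default_rng(spec.seed)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    ramp = np.linspace(1.0 / spec.n_samples, 1.0, spec.n_samples) * spec.peak_moment
    moments = direction[:, None] * ramp[None, :]
    truth = heart.vertices[spec.true_vertex].copy()

    if spec.inverse_crime:
        if system is None:
            system = assemble_bem(vc)
        block = build_transfer_matrix(system, truth)
    else:
        # honest mode: simulate on a once-refined torso so the inversion sees
        # forward-model discretisation error rather than its own operator;
        # electrodes stay at the same physical sites (snapped to the nearest
        # fine-torso vertex)
        fine_torso = ellipsoid_mesh(
            (0.0, 0.0, 0.0), spec.torso_semiaxes, spec.torso_refinement + 1, "torso"
        )
        coarse_pos = vc.montage.positions(vc.surfaces[0])
        d2 = ((fine_torso.vertices[None, :, :] - coarse_pos[:, None, :]) ** 2).sum(axis=2)
        from .geometry import ElectrodeMontage

        montage = ElectrodeMontage(
            np.argmin(d2, axis=1), vc.montage.labels, vc.montage.strip_of
        )
        fine_vc = VolumeConductor(
            (fine_torso,) + vc.surfaces[1:], vc.sigma_in, vc.sigma_out, montage
        )
        block = build_transfer_matrix(assemble_bem(fine_vc), truth)

    labels = list(vc.montage.labels)
    clean = forward_bsp(block, moments, sample_rate=spec.sample_rate, labels=labels)
    pot = clean.potentials
    if np.isfinite(spec.snr_db):
        sig_power = float(np.mean(pot**2))
        noise_sd = np.sqrt(sig_power / 10.0 ** (spec.snr_db / 10.0))
        if not noise_sd > 0:
            raise ValueError("non-positive noise scaling; check snr_db and signal amplitude")
        pot = pot + rng.normal(scale=noise_sd, size=pot.shape)
    return BSPMap(pot, spec.sample_rate, tuple(labels)), truth, moments
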