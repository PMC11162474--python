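"""Synthetic phantoms: ground truth + ensembles of probabilistic segmentations.

The generator emulates what an ensemble of probabilistic segmentation
models produces for a blob-like 3D structure, with the two sources of
predictive uncertainty controlled independently:

* ``boundary_softness`` (mm) — the logistic length-scale of the probability
  falloff across the structure surface.  Every sample is soft in the same
  way, so this drives the *aleatoric* (expected-entropy) component.
* ``member_jitter`` (mm) — random rigid shift plus a low-order smooth
  surface deformation applied per ensemble member, so members disagree
  about where the boundary is.  This drives the *epistemic* (mutual
  information / CV) component.
* ``degradation`` (mm) — case difficulty.  It displaces the whole ensemble
  systematically away from the truth (shared offset of scale
  ``degradation``) and additionally widens the between-member scatter (the
  effective member jitter is ``member_jitter + 0.5 * degradation``),
  mirroring real cohorts where hard cases both fail and split the
  ensemble.  This coupling is what lets ensemble-internal measures such as
  CV track the true DSC across a degradation-spanning cohort.

Ground truth is a union of random ellipsoids; each sample's probability
volume is ``logistic(signed_distance / boundary_softness)`` with the signed
Euclidean distance (mm, positive inside) to that member's perturbed
surface.  Draws within a member add a weaker smooth perturbation
(amplitude ``0.5 * member_jitter``), mimicking posterior sampling of a
single model.  Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .measures import SampleStack
from .volumes import BinaryMask

__all__ = [
    "PhantomSpec",
    "SyntheticPatient",
    "generate_phantom",
    "generate_cohort",
    "derive_patient_seed",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic patient.

    Defaults describe a desk-scale analogue of a PET/CT tumor-segmentation
    ensemble: a 64 mm^3 field of view at 1 mm isotropic spacing, one-to-two
    tumor-like blobs of 6-12 mm radius, mild boundary softness, and a
    five-member ensemble (the common deep-ensemble size) with one draw per
    member.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_blobs: int = 2
    blob_radius_range: tuple[float, float] = (6.0, 12.0)
    boundary_softness: float = 1.5
    member_jitter: float = 1.0
    degradation: float = 0.0
    n_members: int = 5
    n_draws: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1 or self.n_draws < 1:
            raise ValueError("n_members and n_draws must be >= 1")
        if self.n_blobs < 1:
            raise ValueError("n_blobs must be >= 1")
        for name in ("boundary_softness", "member_jitter", "degradation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.shape) < 8:
            raise ValueError("phantom shape must be at least 8 voxels per axis")
        lo, hi = self.blob_radius_range
        if not 0 < lo <= hi:
            raise ValueError("blob_radius_range must satisfy 0 < lo <= hi")


@dataclass
class SyntheticPatient:
    """Ground truth + probabilistic sample stack for one synthetic patient."""

    truth: BinaryMask
    stack: SampleStack
    spec: PhantomSpec
    member_offsets: np.ndarray  # (E, 3) rigid shifts in mm, incl. shared part

    @property
    def patient_seed(self) -> int:
        return self.spec.seed


def _ellipsoid_union(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    centers: np.ndarray,
    semiaxes: np.ndarray,
) -> np.ndarray:
    """Boolean union of ellipsoids; centers/semiaxes in mm."""
    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    mask = np.zeros(shape, dtype=bool)
    for c, a in zip(centers, semiaxes):
        q = sum(((coords[d] - c[d]) / a[d]) ** 2 for d in range(3))
        mask |= q <= 1.0
    return mask


def _signed_distance_mm(
    mask: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Signed Euclidean distance to the mask surface (mm, positive inside)."""
    if mask.all() or not mask.any():
        # constant field: distance to the (absent) surface is unbounded
        return np.where(mask, np.inf, -np.inf)
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return inside - outside


def _smooth_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    amplitude: float,
    n_modes: int = 3,
) -> np.ndarray:
    """Low-order random cosine field with per-mode amplitude
    ``amplitude / sqrt(n_modes)`` (mm), wavelengths around half the extent."""
    if amplitude == 0.0:
        return np.zeros(shape)
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    out = np.zeros(shape)
    per_mode = amplitude / np.sqrt(n_modes)
    for _ in range(n_modes):
        # wavelength between one third and one full extent per axis
        freq = rng.uniform(1.0, 3.0, size=3) / extent
        phase = rng.uniform(0.0, 2.0 * np.pi)
        arg = 2.0 * np.pi * sum(freq[d] * coords[d] for d in range(3)) + phase
        out += per_mode * np.cos(arg)
    return out


def _probability_from_distance(sd: np.ndarray, softness: float) -> np.ndarray:
    """Logistic falloff across the surface; hard step when softness is 0."""
    if softness == 0.0:
        return (sd >= 0).astype(float)
    with np.errstate(over="ignore"):
        return expit(sd / softness)


def generate_phantom(spec: PhantomSpec) -> SyntheticPatient:
    """Generate one synthetic patient, fully determined by ``spec`` (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    r_lo, r_hi = spec.blob_radius_range

    # blob centers in the interior so the truth never touches the border
    margin = r_hi + 2.0
    lo = np.minimum(margin, extent * 0.45)
    centers = rng.uniform(lo, extent - lo, size=(spec.n_blobs, 3))
    semiaxes = rng.uniform(r_lo, r_hi, size=(spec.n_blobs, 3))

    truth_grid = _ellipsoid_union(shape, spacing, centers, semiaxes)
    if not truth_grid.any():  # pragma: no cover - excluded by construction
        raise RuntimeError("generated an empty truth mask")
    truth = BinaryMask(grid=truth_grid, spacing=spacing)

    # systematic (shared) displacement: drives true DSC down without
    # increasing ensemble disagreement
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    shared_offset = spec.degradation * direction
    # hard cases also split the ensemble: degradation widens member scatter
    jitter_eff = spec.member_jitter + 0.5 * spec.degradation

    member_offsets = np.empty((spec.n_members, 3))
    volumes = np.empty((spec.n_members, spec.n_draws) + tuple(shape))
    for e in range(spec.n_members):
        shift = rng.normal(scale=jitter_eff, size=3) if jitter_eff else np.zeros(3)
        offset = shared_offset + shift
        member_offsets[e] = offset
        member_mask = _ellipsoid_union(shape, spacing, centers + offset, semiaxes)
        sd = _signed_distance_mm(member_mask, spacing)
        sd = sd + _smooth_field(rng, shape, spacing, jitter_eff)
        for s in range(spec.n_draws):
            sd_draw = sd
            if spec.n_draws > 1:
                sd_draw = sd + _smooth_field(
                    rng, shape, spacing, 0.5 * jitter_eff
                )
            volumes[e, s] = _probability_from_distance(
                np.nan_to_num(sd_draw, posinf=1e6, neginf=-1e6),
                spec.boundary_softness,
            )
    stack = SampleStack(probs=volumes, spacing=spacing)
    return SyntheticPatient(
        truth=truth, stack=stack, spec=spec, member_offsets=member_offsets
    )


def derive_patient_seed(master_seed: int, index: int) -> int:
    """Stable per-patient seed from (master seed, patient index)."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    n_patients: int,
    degradation_schedule: list[float] | tuple[float, ...],
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
) -> list[SyntheticPatient]:
    """Generate a cohort whose degradation cycles through the schedule.

    The schedule is recycled when shorter than the cohort, so patient ``i``
    gets ``degradation_schedule[i % len(schedule)]``.  Per-patient seeds
    derive deterministically from the master seed.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not degradation_schedule:
        raise ValueError("degradation_schedule must be nonempty")
    cohort = []
    for i in range(n_patients):
        spec = dataclasses.replace(
            base_spec,
            degradation=float(degradation_schedule[i % len(degradation_schedule)]),
            seed=derive_patient_seed(seed, i),
        )
        cohort.append(generate_phantom(spec))
    return cohort
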