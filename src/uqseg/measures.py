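"""Voxel-wise uncertainty maps and the eight patient-level uncertainty measures.

A :class:`SampleStack` holds the Monte-Carlo substrate: M = E*S probability
volumes, one per (ensemble member e, dropout draw s).  The posterior
predictive foreground probability at a voxel is the two-level average of the
per-sample probabilities (mean over draws within a member, then over
members; equal to the flat mean since every member carries the same number
of draws).

From the stack we compute three voxel-wise maps,

* ``h``  — predictive entropy of the posterior mean (total uncertainty),
* ``eh`` — expected per-sample entropy (aleatoric component),
* ``mi`` — mutual information ``h - eh`` (epistemic component),

all binary entropies in nats, and eight patient-level scalars:

=========  ==================================================================
H, EH, I   voxel maps aggregated over the volume (mean by default, sum
           optionally)
CV         coefficient of variation of the per-sample predicted structure
           volume (population SD / mean)
SEH        structure expected entropy: per-sample mean entropy over that
           sample's own predicted structure, averaged over samples
SH         structure predictive entropy: mean of ``h`` over the posterior
           mean's predicted structure
SI         SH - SEH (may be negative: the two terms average over different
           voxel sets; stored as computed)
R_DSC      DSC-risk: negative expected Dice between voxel-wise Bernoulli
           samples of the posterior mean and the thresholded mean prediction
=========  ==================================================================

Every measure is oriented so that larger = more uncertain; "certainty" is
negated uncertainty.  Degenerate cases (empty predicted structures) yield
NaN plus a named flag rather than an exception, so cohort runs never abort;
downstream referral treats flagged patients as maximally uncertain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .volumes import BinaryMask, ImageVolume

__all__ = [
    "SampleStack",
    "UncertaintyMaps",
    "PatientUncertainty",
    "MEASURE_NAMES",
    "binary_entropy",
    "posterior_mean",
    "entropy_maps",
    "patient_entropy",
    "structure_set",
    "coefficient_of_variation",
    "structure_expected_entropy",
    "structure_entropy_mi",
    "dsc_risk",
    "patient_uncertainty",
]

#: probability clamp before logarithms
EPS = 1e-12

#: canonical measure order used in records, CSVs and reports
MEASURE_NAMES = ("h", "eh", "mi", "cv", "seh", "sh", "si", "r_dsc")

Aggregation = Literal["mean", "sum"]


@dataclass
class SampleStack:
    """M = E*S probability volumes indexed by (member, draw).

    ``probs`` has shape (E, S, nx, ny, nz) with values in [0, 1]; all
    samples share shape and spacing.
    """

    probs: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim == 4:  # (M, x, y, z) -> single-draw members
            p = p[:, None]
        if p.ndim != 5:
            raise ValueError(
                f"probs must have shape (E, S, nx, ny, nz), got {p.shape}"
            )
        if p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError("stack needs at least one member and one draw")
        if p.size == 0:
            raise ValueError("empty sample stack")
        if float(p.min()) < 0.0 or float(p.max()) > 1.0:
            raise ValueError("sample probabilities must lie in [0, 1]")
        self.probs = p
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]

    @classmethod
    def from_samples(
        cls,
        samples: Iterable[tuple[int, int, np.ndarray]],
        spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    ) -> "SampleStack":
        """Build a stack from (member, draw, volume) triples (1-based or
        0-based contiguous indices)."""
        tagged = {(int(e), int(s)): np.asarray(v, dtype=float) for e, s, v in samples}
        if not tagged:
            raise ValueError("empty sample stack")
        members = sorted({e for e, _ in tagged})
        draws = sorted({s for _, s in tagged})
        grid = np.stack(
            [np.stack([tagged[(e, s)] for s in draws]) for e in members]
        )
        return cls(probs=grid, spacing=spacing)

    @property
    def n_members(self) -> int:
        return self.probs.shape[0]

    @property
    def n_draws(self) -> int:
        return self.probs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.n_members * self.n_draws

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probs.shape[2:]  # type: ignore[return-value]

    @property
    def flat(self) -> np.ndarray:
        """(M, nx, ny, nz) view collapsing the member/draw axes."""
        return self.probs.reshape((-1,) + self.probs.shape[2:])


@dataclass
class UncertaintyMaps:
    """Voxel-wise predictive entropy, expected entropy and mutual information.

    All values in nats and >= 0; ``h = eh + mi`` holds voxel-wise to float
    precision (mi is clipped below at 0 to absorb round-off).
    """

    h: np.ndarray
    eh: np.ndarray
    mi: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def as_volumes(self) -> dict[str, ImageVolume]:
        """The three maps as exportable volumes."""
        return {
            name: ImageVolume(grid=getattr(self, name), spacing=self.spacing)
            for name in ("h", "eh", "mi")
        }


@dataclass
class PatientUncertainty:
    """The eight patient-level measures for one sample stack.

    Degenerate situations leave the affected field NaN and add a flag:
    ``empty_structure_mean`` (posterior-mean prediction empty: sh, si and
    r_dsc undefined), ``empty_structure_samples`` (>= 1 per-sample structure
    empty: its SEH contribution is 0), ``zero_mean_volume`` (cv undefined).
    """

    h: float
    eh: float
    mi: float
    cv: float
    seh: float
    sh: float
    si: float
    r_dsc: float
    aggregation: Aggregation = "mean"
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MEASURE_NAMES}


def binary_entropy(p: np.ndarray) -> np.ndarray:
    """Binary Shannon entropy in nats, with probabilities clamped to
    [EPS, 1-EPS] before the logarithms."""
    p = np.clip(np.asarray(p, dtype=float), EPS, 1.0 - EPS)
    return -(p * np.log(p) + (1.0 - p) * np.log(1.0 - p))


def posterior_mean(st: SampleStack) -> ImageVolume:
    """Monte-Carlo posterior predictive probability: mean over draws within
    each member, then uniform mean over members."""
    mean = st.probs.mean(axis=1).mean(axis=0)
    return ImageVolume(
        grid=np.clip(mean, 0.0, 1.0), spacing=st.spacing, modality="PROB"
    )


def entropy_maps(st: SampleStack) -> UncertaintyMaps:
    """Voxel-wise entropy decomposition of the stack.

    ``h`` is the binary entropy of the posterior mean, ``eh`` the average of
    per-sample binary entropies (two-level, like the posterior mean), and
    ``mi = h - eh`` clipped below at zero.
    """
    pbar = posterior_mean(st).grid
    h = binary_entropy(pbar)
    eh = binary_entropy(st.probs).mean(axis=1).mean(axis=0)
    mi = np.clip(h - eh, 0.0, None)
    return UncertaintyMaps(h=h, eh=eh, mi=mi, spacing=st.spacing)


def patient_entropy(
    maps: UncertaintyMaps, aggregation: Aggregation = "mean"
) -> tuple[float, float, float]:
    """Aggregate the three maps over all voxels (mean by default)."""
    if aggregation not in ("mean", "sum"):
        raise ValueError(f"aggregation must be 'mean' or 'sum', got {aggregation!r}")
    agg = np.mean if aggregation == "mean" else np.sum
    return float(agg(maps.h)), float(agg(maps.eh)), float(agg(maps.mi))


def structure_set(p: ImageVolume | np.ndarray) -> np.ndarray:
    """Boolean grid of voxels predicted as foreground (probability >= 0.5;
    ties included)."""
    grid = p.grid if isinstance(p, ImageVolume) else np.asarray(p, dtype=float)
    if float(grid.min()) < 0.0 or float(grid.max()) > 1.0:
        raise ValueError("probabilities must lie in [0, 1]")
    return grid >= 0.5


def _per_sample_structures(st: SampleStack) -> np.ndarray:
    """(M, nx, ny, nz) boolean per-sample predicted structures."""
    return st.flat >= 0.5


def coefficient_of_variation(st: SampleStack) -> float:
    """CV of the per-sample predicted structure volume: population SD of
    ``|G(x, theta_m)|`` divided by its mean.  NaN when the mean is 0."""
    sizes = _per_sample_structures(st).sum(axis=(1, 2, 3)).astype(float)
    mu = sizes.mean()
    if mu == 0.0:
        return float("nan")
    return float(sizes.std() / mu)  # ddof=0: raw-moment (population) form


def structure_expected_entropy(st: SampleStack) -> float:
    """SEH: mean over samples of the per-sample mean binary entropy over
    that sample's own predicted structure.

    A sample with an empty structure contributes 0 (its 1/|G| normalizer is
    undefined); callers can detect this via :func:`patient_uncertainty`
    flags.
    """
    flat = st.flat
    structures = flat >= 0.5
    ent = binary_entropy(flat)
    sizes = structures.sum(axis=(1, 2, 3))
    sums = np.where(structures, ent, 0.0).sum(axis=(1, 2, 3))
    per_sample = np.where(sizes > 0, sums / np.maximum(sizes, 1), 0.0)
    return float(per_sample.mean())


def structure_entropy_mi(st: SampleStack) -> tuple[float, float]:
    """SH and SI.

    SH is the mean voxel-wise predictive entropy over the posterior mean's
    predicted structure; SI = SH - SEH.  SI may be negative because SH and
    SEH average over different voxel sets; it is stored as computed.  Both
    are NaN when the posterior-mean structure is empty.
    """
    pbar = posterior_mean(st).grid
    g = pbar >= 0.5
    if not g.any():
        return float("nan"), float("nan")
    sh = float(binary_entropy(pbar)[g].mean())
    si = sh - structure_expected_entropy(st)
    return sh, si


def dsc_risk(
    st: SampleStack | ImageVolume | np.ndarray,
    n_draws: int = 200,
    seed: int | np.random.Generator = 0,
) -> float:
    """DSC-risk: Monte-Carlo estimate of ``-E[DSC(c, ỹ)]``.

    ``ỹ`` is the thresholded (>= 0.5) posterior mean and each ``c`` is a
    binary volume drawn voxel-wise independently as Bernoulli(p̄) from the
    posterior mean — the "doubly stochastic" estimator (the posterior mean
    itself is already a Monte-Carlo average).  The value lies in [-1, 0];
    -1 means every plausible segmentation agrees perfectly with the
    prediction.  NaN when ``ỹ`` is empty.

    Accepts a stack, a posterior-mean volume, or a raw probability grid;
    only the posterior mean matters, so the estimate is invariant to sample
    order.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if isinstance(st, SampleStack):
        pbar = posterior_mean(st).grid
    elif isinstance(st, ImageVolume):
        pbar = np.asarray(st.grid, dtype=float)
    else:
        pbar = np.asarray(st, dtype=float)
    pflat = pbar.ravel()
    yhat = pflat >= 0.5
    n_yhat = int(yhat.sum())
    if n_yhat == 0:
        return float("nan")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # Only voxels with nonextreme probability are stochastic; fixed voxels
    # contribute deterministic terms to |c| and |c ∩ ỹ|.
    random_idx = (pflat > 0.0) & (pflat < 1.0)
    fixed_fg = pflat == 1.0
    base_c = int(fixed_fg.sum())
    base_inter = int((fixed_fg & yhat).sum())
    p_rand = pflat[random_idx]
    in_yhat = yhat[random_idx]

    total = 0.0
    done = 0
    # batch the draws to bound memory on large volumes
    batch = max(1, int(2e7 // max(1, p_rand.size)))
    while done < n_draws:
        nb = min(batch, n_draws - done)
        if p_rand.size:
            draws = rng.random((nb, p_rand.size)) < p_rand
            c_sizes = base_c + draws.sum(axis=1)
            inters = base_inter + (draws & in_yhat).sum(axis=1)
        else:
            c_sizes = np.full(nb, base_c)
            inters = np.full(nb, base_inter)
        denom = c_sizes + n_yhat  # > 0 since ỹ nonempty
        total += float((2.0 * inters / denom).sum())
        done += nb
    return -total / n_draws


def patient_uncertainty(
    st: SampleStack,
    aggregation: Aggregation = "mean",
    n_draws: int = 200,
    seed: int | np.random.Generator = 0,
) -> PatientUncertainty:
    """Compute all eight measures for one patient's sample stack."""
    maps = entropy_maps(st)
    h, eh, mi = patient_entropy(maps, aggregation)
    cv = coefficient_of_variation(st)
    seh = structure_expected_entropy(st)
    sh, si = structure_entropy_mi(st)
    r = dsc_risk(st, n_draws=n_draws, seed=seed)

    flags: list[str] = []
    sizes = _per_sample_structures(st).sum(axis=(1, 2, 3))
    if (sizes == 0).any():
        flags.append("empty_structure_samples")
    if np.isnan(cv):
        flags.append("zero_mean_volume")
    if np.isnan(sh):
        flags.append("empty_structure_mean")
    return PatientUncertainty(
        h=h, eh=eh, mi=mi, cv=cv, seh=seh, sh=sh, si=si, r_dsc=r,
        aggregation=aggregation, flags=tuple(flags),
    )
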