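"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: smooth streamline
bundles with planted, detectable outliers; scalar maps sampled from an
analytic field; MZ/DZ twin cohorts with a specified per-node heritability;
and phenotypes with a planted group-sparse linear dependence on profile
features.  All randomness flows through explicit integer seeds -- identical
seeds give bit-identical outputs.

The generators emulate the *statistical* structure the analysis sees (bundle
geometry, per-node trait variances, family blocks), not the physics of
diffusion MRI: no raw diffusion signal, gradient tables or scanner artifacts
are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .core import (
    METRIC_NAMES,
    TRACT_NAMES,
    ScalarMap,
    SpatialReference,
    Tractogram,
    TractProfileSet,
    concat_tractograms,
)
from .profiles import resample_streamline

__all__ = [
    "BundleSpec",
    "TwinSimSpec",
    "make_bundle",
    "make_scalar_map",
    "make_twin_cohort",
    "make_phenotype",
    "make_profile_sets",
    "make_subject",
    "default_family_sizes",
    "PhenotypeResult",
]

#: Fractional positions of the smooth-jitter spline knots along each
#: streamline.  At a knot the perpendicular offset has magnitude
#: ``radial_sd * sqrt(2)`` with uniformly random direction, so each offset
#: component has second moment ``radial_sd**2`` exactly.
JITTER_KNOTS = np.linspace(0.0, 1.0, 13)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class BundleSpec:
    """Recipe for one synthetic streamline bundle."""

    name: str
    centerline: np.ndarray            # (K, 3) control points, mm
    n_streamlines: int = 100
    radial_sd: float = 1.0            # mm, scale of smooth perpendicular jitter
    points_per_streamline: int = 100
    outlier_fraction: float = 0.0     # in [0, 1)
    outlier_offset: float = 0.0       # mm, perpendicular displacement
    seed: int = 0

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=float)
        if not np.all(np.isfinite(self.centerline)):
            raise ValueError("centerline control points must be finite")
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise ValueError("centerline must be (K, 3)")
        if len(np.unique(self.centerline, axis=0)) < 2:
            raise ValueError("centerline needs >= 2 distinct points")
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be positive")
        if self.points_per_streamline < 2:
            raise ValueError("points_per_streamline must be >= 2")
        if self.radial_sd < 0:
            raise ValueError("radial_sd must be >= 0")
        if not (0 <= self.outlier_fraction < 1):
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.outlier_fraction > 0 and self.outlier_offset <= 3 * self.radial_sd:
            raise ValueError(
                "outlier_offset must exceed 3 * radial_sd so planted outliers "
                "are detectable"
            )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "name", "n_streamlines", "radial_sd", "points_per_streamline",
            "outlier_fraction", "outlier_offset", "seed",
        )}
        d["centerline"] = self.centerline.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BundleSpec":
        return cls(**d)


@dataclass
class TwinSimSpec:
    """Recipe for a simulated MZ/DZ twin cohort with per-node heritability."""

    n_mz_pairs: int
    n_dz_pairs: int
    h2_true: np.ndarray          # per-node, in [0, 1]
    total_variance: np.ndarray   # per-node, > 0
    mean_profile: np.ndarray     # per-node
    seed: int = 0

    def __post_init__(self):
        self.h2_true = np.atleast_1d(np.asarray(self.h2_true, dtype=float))
        self.total_variance = np.atleast_1d(
            np.asarray(self.total_variance, dtype=float)
        )
        self.mean_profile = np.atleast_1d(np.asarray(self.mean_profile, dtype=float))
        if not (
            len(self.h2_true) == len(self.total_variance) == len(self.mean_profile)
        ):
            raise ValueError("h2_true, total_variance, mean_profile lengths differ")
        if np.any(self.h2_true < 0) or np.any(self.h2_true > 1):
            raise ValueError("h2_true values must lie in [0, 1]")
        if np.any(self.total_variance <= 0):
            raise ValueError("total_variance must be positive")
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise ValueError("pair counts must be non-negative")

    def to_dict(self) -> dict:
        return {
            "n_mz_pairs": self.n_mz_pairs,
            "n_dz_pairs": self.n_dz_pairs,
            "h2_true": self.h2_true.tolist(),
            "total_variance": self.total_variance.tolist(),
            "mean_profile": self.mean_profile.tolist(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwinSimSpec":
        return cls(**d)


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

def _perpendicular_frame(center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Propagated orthonormal frame (e1, e2) perpendicular to the tangent."""
    tangents = np.gradient(center, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    n = len(center)
    e1 = np.empty_like(center)
    seed_vec = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed_vec, tangents[0])) > 0.9:
        seed_vec = np.array([0.0, 1.0, 0.0])
    prev = seed_vec
    for j in range(n):
        v = prev - np.dot(prev, tangents[j]) * tangents[j]
        norm = np.linalg.norm(v)
        if norm < 1e-12:  # tangent flipped by ~90 deg in one step
            v = np.cross(tangents[j], prev)
            norm = np.linalg.norm(v)
        e1[j] = v / norm
        prev = e1[j]
    e2 = np.cross(tangents, e1)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    return e1, e2


def _default_reference(points: np.ndarray, voxel_size: float = 2.0,
                       margin: float = 10.0) -> SpatialReference:
    lo = np.floor(points.min(axis=0) - margin)
    hi = np.ceil(points.max(axis=0) + margin)
    shape = tuple(int(np.ceil(v)) for v in (hi - lo) / voxel_size + 1)
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = lo
    return SpatialReference(shape, (voxel_size,) * 3, affine)


def make_bundle(
    spec: BundleSpec, reference: SpatialReference | None = None
) -> Tractogram:
    """Generate a coherent bundle around a centerline, with planted outliers.

    Each streamline is the resampled centerline plus a *smooth* per-streamline
    offset of constant magnitude ``radial_sd*sqrt(2)`` in the perpendicular
    plane whose direction winds smoothly along the tract (a cubic spline
    through random phase angles at the :data:`JITTER_KNOTS` fractions), so
    streamlines remain plausible coherent curves, never cross the bundle
    core, and form a statistically exchangeable ensemble from which planted
    outliers separate cleanly.  ``round(outlier_fraction * n)``
    streamlines are additionally displaced by ``outlier_offset`` mm in a
    random perpendicular direction; their indices are recorded in
    ``metadata['outlier_indices']``.  Half of the streamlines are stored
    reversed (``metadata['reversed_indices']``) to exercise orientation
    harmonization downstream.
    """
    rng = np.random.default_rng(spec.seed)
    n_pts = spec.points_per_streamline
    center = resample_streamline(spec.centerline, n_pts)
    e1, e2 = _perpendicular_frame(center)
    t_grid = np.linspace(0.0, 1.0, n_pts)

    n = spec.n_streamlines
    amp = spec.radial_sd * np.sqrt(2.0)
    streamlines = []
    for _ in range(n):
        # smooth winding: the offset keeps constant radius `amp` while its
        # direction drifts; interpolating the phase angle (not its cos/sin)
        # guarantees no streamline ever crosses the bundle core
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        # fixed-magnitude drift steps with random signs: every streamline
        # carries the same winding energy, so none becomes a length or
        # tangential outlier by construction
        drift = (np.pi / 4.0) * rng.choice([-1.0, 1.0],
                                           size=len(JITTER_KNOTS) - 1)
        knot_phases = phi0 + np.concatenate([[0.0], np.cumsum(drift)])
        if spec.radial_sd > 0:
            phi = CubicSpline(JITTER_KNOTS, knot_phases)(t_grid)
            u1 = amp * np.cos(phi)
            u2 = amp * np.sin(phi)
        else:
            u1 = u2 = np.zeros(n_pts)
        streamlines.append(center + u1[:, None] * e1 + u2[:, None] * e2)

    n_out = int(round(spec.outlier_fraction * n))
    outlier_idx = np.sort(rng.choice(n, size=n_out, replace=False))
    for i in outlier_idx:
        theta = rng.uniform(0, 2 * np.pi)
        direction = np.cos(theta) * e1 + np.sin(theta) * e2
        streamlines[i] = streamlines[i] + spec.outlier_offset * direction

    reversed_idx = np.sort(rng.choice(n, size=n // 2, replace=False))
    for i in reversed_idx:
        streamlines[i] = streamlines[i][::-1].copy()

    if reference is None:
        reference = _default_reference(np.concatenate(streamlines))
    return Tractogram(
        streamlines,
        reference,
        groups={spec.name: np.arange(n, dtype=np.int64)},
        metadata={
            "outlier_indices": outlier_idx,
            "reversed_indices": reversed_idx,
            "seed": spec.seed,
            "spec": spec.to_dict(),
        },
    )


# ---------------------------------------------------------------------------
# Scalar maps
# ---------------------------------------------------------------------------

def make_scalar_map(
    grid_shape: Sequence[int],
    affine: np.ndarray,
    field: Callable[[np.ndarray], np.ndarray],
    noise_sd: float = 0.0,
    seed: int = 0,
    metric_name: str = "scalar",
) -> ScalarMap:
    """Evaluate an analytic field at voxel centers, plus Gaussian noise.

    ``field`` receives an (N, 3) array of RAS-mm voxel-center coordinates
    and must return N values (vectorized).
    """
    affine = np.asarray(affine, dtype=float)
    shape = tuple(int(s) for s in grid_shape)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]).astype(float)
    ras = vox @ affine[:3, :3].T + affine[:3, 3]
    values = np.asarray(field(ras), dtype=float).reshape(shape)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=shape)
    return ScalarMap(values, affine, metric_name)


# ---------------------------------------------------------------------------
# Twin cohorts
# ---------------------------------------------------------------------------

def make_twin_cohort(spec: TwinSimSpec):
    """Simulate node-level twin traits under the additive-genetic model.

    For pair i at node j, members are ``Y = mu_j + g + e`` with
    ``Var(g) = h2_j * sigma2_j``, ``Var(e) = (1 - h2_j) * sigma2_j`` and
    ``corr(g_1, g_2) = pi`` (1.0 for MZ, 0.5 for DZ); environments are
    independent.  Traits are simulated directly at node level: the
    heritability model operates on profile values only, so no imaging is
    involved.  The drawn genetic components are kept in
    ``cohort.metadata['g1']/['g2']`` for diagnostics.
    """
    from .heritability import TwinCohort

    rng = np.random.default_rng(spec.seed)
    n_nodes = len(spec.h2_true)
    sigma_g = np.sqrt(spec.h2_true * spec.total_variance)
    sigma_e = np.sqrt((1.0 - spec.h2_true) * spec.total_variance)

    n_pairs = spec.n_mz_pairs + spec.n_dz_pairs
    zygosity = np.array(["MZ"] * spec.n_mz_pairs + ["DZ"] * spec.n_dz_pairs)
    pi = np.where(zygosity == "MZ", 1.0, 0.5)

    z_shared = rng.standard_normal((n_pairs, n_nodes))
    z_own = rng.standard_normal((2, n_pairs, n_nodes))
    e = rng.standard_normal((2, n_pairs, n_nodes)) * sigma_e

    root_pi = np.sqrt(pi)[:, None]
    root_rest = np.sqrt(1.0 - pi)[:, None]
    g1 = sigma_g * (root_pi * z_shared + root_rest * z_own[0])
    g2 = sigma_g * (root_pi * z_shared + root_rest * z_own[1])
    y1 = spec.mean_profile + g1 + e[0]
    y2 = spec.mean_profile + g2 + e[1]

    return TwinCohort(
        pair_ids=np.arange(n_pairs),
        zygosity=zygosity,
        y1=y1[:, None, None, :],
        y2=y2[:, None, None, :],
        tract_names=["SIM"],
        metric_names=["trait"],
        metadata={"g1": g1, "g2": g2, "spec": spec.to_dict()},
    )


# ---------------------------------------------------------------------------
# Profiles and phenotypes
# ---------------------------------------------------------------------------

def make_profile_sets(
    n_subjects: int,
    tract_names: Sequence[str] = TRACT_NAMES,
    metric_names: Sequence[str] = METRIC_NAMES,
    n_nodes: int = 100,
    seed: int = 0,
    between_subject_sd: float = 0.1,
    smoothness: int = 10,
) -> list[TractProfileSet]:
    """Random smooth tract profiles for a set of subjects.

    Each (tract, metric) has a shared smooth mean curve; subjects deviate
    from it by smooth random curves of SD ``between_subject_sd`` (smoothing
    by a moving average of width ``smoothness`` nodes).
    """
    rng = np.random.default_rng(seed)
    k, m = len(tract_names), len(metric_names)

    def smooth(x):
        kernel = np.ones(smoothness) / smoothness
        pad = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(smoothness, smoothness)],
                     mode="reflect")
        return np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="same"), -1, pad
        )[..., smoothness:-smoothness]

    base = 0.5 + 0.1 * smooth(rng.standard_normal((k, m, n_nodes)))
    out = []
    for s in range(n_subjects):
        dev = between_subject_sd * smooth(rng.standard_normal((k, m, n_nodes)))
        # moving-average smoothing shrinks the SD; rescale to the nominal level
        dev *= np.sqrt(smoothness)
        out.append(
            TractProfileSet(f"sub-{s:04d}", list(tract_names),
                            list(metric_names), base + dev)
        )
    return out


def default_family_sizes(n_subjects: int, pair_fraction: float = 0.5) -> list[int]:
    """Size-2 sibling pairs plus singletons, mirroring a twin-study cohort."""
    n_pairs = int(n_subjects * pair_fraction) // 2
    sizes = [2] * n_pairs + [1] * (n_subjects - 2 * n_pairs)
    return sizes


@dataclass
class PhenotypeResult:
    """A simulated phenotype table plus its generating ground truth."""

    table: pd.DataFrame            # subject_id, family_id, phenotype, value
    signal: np.ndarray             # noiseless linear predictor per subject
    weights: np.ndarray            # generating weights on standardized features
    phenotype: str = "synthetic"


def make_phenotype(
    profiles: list[TractProfileSet],
    active_groups: Sequence[tuple[str, str]],
    effect_weights: np.ndarray,
    noise_sd: float,
    family_sizes: Sequence[int] | None = None,
    seed: int = 0,
    phenotype: str = "synthetic",
) -> PhenotypeResult:
    """Phenotype with a sparse, group-structured linear dependence.

    The phenotype is a linear combination of *standardized* profile features
    restricted to ``active_groups`` (each a (tract, metric) pair; the same
    per-node ``effect_weights`` apply within every active group) plus
    Gaussian noise.  Subjects are partitioned into families in order
    according to ``family_sizes`` (default: size-2 pairs plus singletons).
    """
    from .prediction import build_features

    fm = build_features(profiles)
    n = fm.X.shape[0]
    if family_sizes is None:
        family_sizes = default_family_sizes(n)
    if sum(family_sizes) != n:
        raise ValueError(
            f"family_sizes sum to {sum(family_sizes)} but there are {n} subjects"
        )
    effect_weights = np.asarray(effect_weights, dtype=float)

    sd = fm.X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (fm.X - fm.X.mean(axis=0)) / sd

    group_keys = list(zip(fm.feature_info["tract"], fm.feature_info["metric"]))
    w = np.zeros(fm.X.shape[1])
    for tract, metric in active_groups:
        cols = [i for i, key in enumerate(group_keys) if key == (tract, metric)]
        if not cols:
            raise ValueError(f"active group {(tract, metric)!r} not in features")
        if len(cols) != len(effect_weights):
            raise ValueError(
                f"effect_weights has {len(effect_weights)} entries but group "
                f"{(tract, metric)!r} has {len(cols)} features"
            )
        w[cols] = effect_weights

    signal = Z @ w
    rng = np.random.default_rng(seed)
    y = signal + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)

    family_ids = np.repeat(
        [f"fam-{i:04d}" for i in range(len(family_sizes))], family_sizes
    )
    table = pd.DataFrame(
        {
            "subject_id": fm.subject_ids,
            "family_id": family_ids,
            "phenotype": phenotype,
            "value": y,
        }
    )
    return PhenotypeResult(table, signal, w, phenotype)


# ---------------------------------------------------------------------------
# Whole-subject fixture
# ---------------------------------------------------------------------------

def _random_centerline(rng: np.random.Generator, lo: np.ndarray,
                       hi: np.ndarray) -> np.ndarray:
    """A gently curved 4-control-point path spanning the box diagonal-ish."""
    span = hi - lo
    a = lo + span * rng.uniform(0.05, 0.3, 3)
    b = lo + span * rng.uniform(0.7, 0.95, 3)
    mids = [a + (b - a) * f + span * rng.uniform(-0.12, 0.12, 3)
            for f in (0.33, 0.66)]
    return np.array([a, mids[0], mids[1], b])


def make_subject(
    n_streamlines: int = 500,
    tract_names: Sequence[str] = TRACT_NAMES,
    seed: int = 0,
    radial_sd: float = 2.0,
    points_per_streamline: int = 100,
    outlier_fraction: float = 0.0,
    outlier_offset: float = 0.0,
    noise_sd: float = 0.005,
    metric_names: Sequence[str] = ("FA",),
) -> tuple[Tractogram, list[ScalarMap]]:
    """A full simulated subject: a grouped multi-tract tractogram plus
    smooth tissue-property maps on a shared 2 mm grid.

    The volume is head-centered (RAS coordinates span roughly +/- 80-96 mm
    around the origin, as in ACPC-aligned brain data), which also keeps
    half-float coordinate rounding small.  All bundles lie comfortably
    inside the volume, so every node sample is interior.
    """
    rng = np.random.default_rng(seed)
    voxel_size = 2.0
    shape = (80, 96, 80)
    extent = np.array(shape) * voxel_size
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = -extent / 2.0 + voxel_size / 2.0
    reference = SpatialReference(shape, (voxel_size,) * 3, affine)
    lo = -extent / 2.0 + 16.0
    hi = extent / 2.0 - 16.0

    bundles = []
    for i, name in enumerate(tract_names):
        spec = BundleSpec(
            name=name,
            centerline=_random_centerline(rng, lo, hi),
            n_streamlines=n_streamlines,
            radial_sd=radial_sd,
            points_per_streamline=points_per_streamline,
            outlier_fraction=outlier_fraction,
            outlier_offset=outlier_offset,
            seed=int(rng.integers(2**31 - 1)),
        )
        bundles.append((name, make_bundle(spec, reference=reference)))
    tractogram = concat_tractograms(bundles)

    def fa_field(p):
        x, y, z = p[:, 0], p[:, 1], p[:, 2]
        vals = (
            0.45
            + 0.15 * np.sin(2 * np.pi * x / extent[0])
            * np.cos(2 * np.pi * y / extent[1])
            + 0.10 * z / extent[2]
        )
        return np.clip(vals, 0.05, 0.95)

    def md_field(p):
        x = p[:, 0]
        return 0.7e-3 + 0.2e-3 * np.cos(2 * np.pi * x / extent[0]) + 0.4e-3

    def mk_field(p):
        y = p[:, 1]
        return 0.9 + 0.3 * np.sin(2 * np.pi * y / extent[1])

    def awf_field(p):
        z = p[:, 2]
        return np.clip(0.4 + 0.2 * np.cos(2 * np.pi * z / extent[2]), 0.05, 0.95)

    fields = {"FA": (fa_field, noise_sd), "MD": (md_field, 0.0),
              "MK": (mk_field, 0.0), "AWF": (awf_field, noise_sd)}
    maps = []
    for metric in metric_names:
        field_fn, nsd = fields[metric]
        maps.append(
            make_scalar_map(
                shape, affine, field_fn, noise_sd=nsd,
                seed=int(rng.integers(2**31 - 1)), metric_name=metric,
            )
        )
    return tractogram, maps
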