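"""Core in-memory containers for tractometry data.

All geometry lives in RAS+ millimetres.  Voxel indices are 0-based and the
voxel-to-RAS affine maps *voxel centers*; conversions to format-specific
spaces (e.g. TrackVis voxel-mm) are explicit and live in :mod:`.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 24 major white-matter pathways profiled by default: 16 association /
#: projection tracts (left/right) and 8 callosal subdivisions.
TRACT_NAMES: tuple[str, ...] = (
    "ATR_L", "ATR_R",
    "CST_L", "CST_R",
    "CGC_L", "CGC_R",
    "IFO_L", "IFO_R",
    "ILF_L", "ILF_R",
    "SLF_L", "SLF_R",
    "UNC_L", "UNC_R",
    "ARC_L", "ARC_R",
    "Orbital", "AntFrontal", "SupFrontal", "Motor",
    "SupParietal", "PostParietal", "Occipital", "Temporal",
)

#: Tissue-property metrics profiled by default (diffusion-kurtosis derived).
METRIC_NAMES: tuple[str, ...] = ("FA", "MD", "MK", "AWF")


def _as_affine(affine) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise ValueError("affine contains non-finite values")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass(frozen=True)
class SpatialReference:
    """Voxel grid geometry shared by a tractogram and its scalar maps."""

    shape: tuple[int, int, int]
    voxel_sizes: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(
            self, "voxel_sizes", tuple(float(v) for v in self.voxel_sizes)
        )
        object.__setattr__(self, "affine", _as_affine(self.affine))
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive ints, got {self.shape}")
        if any(v <= 0 for v in self.voxel_sizes):
            raise ValueError("voxel sizes must be positive")

    @classmethod
    def from_affine(cls, shape, affine) -> "SpatialReference":
        affine = _as_affine(affine)
        voxel_sizes = tuple(np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
        return cls(tuple(shape), voxel_sizes, affine)


def validate_streamline(points) -> np.ndarray:
    """Coerce one streamline to an (N, 3) float array and check invariants."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"streamline must be (N, 3), got {pts.shape}")
    if pts.shape[0] < 2:
        raise ValueError("streamline needs at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("streamline contains non-finite coordinates")
    if np.all(pts == pts[0]):
        raise ValueError("streamline is degenerate (all points identical)")
    return pts


@dataclass
class Tractogram:
    """Streamlines in RAS mm, a spatial reference, and named groups (tracts).

    ``groups`` maps a tract name to the indices of its member streamlines;
    a streamline may belong to at most one group in practice but this is not
    enforced.  ``metadata`` carries provenance such as planted-outlier
    indices from the synthetic generator.
    """

    streamlines: list[np.ndarray]
    reference: SpatialReference
    groups: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.streamlines = [validate_streamline(s) for s in self.streamlines]
        n = len(self.streamlines)
        clean_groups: dict[str, np.ndarray] = {}
        for name, idx in self.groups.items():
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(
                    f"group {name!r} has streamline indices outside [0, {n})"
                )
            clean_groups[str(name)] = idx
        self.groups = clean_groups

    def __len__(self) -> int:
        return len(self.streamlines)

    @property
    def n_vertices(self) -> int:
        return sum(len(s) for s in self.streamlines)

    def group_streamlines(self, name: str) -> list[np.ndarray]:
        return [self.streamlines[i] for i in self.groups[name]]

    def copy(self) -> "Tractogram":
        return Tractogram(
            [s.copy() for s in self.streamlines],
            self.reference,
            {k: v.copy() for k, v in self.groups.items()},
            dict(self.metadata),
        )


def concat_tractograms(named: list[tuple[str, Tractogram]]) -> Tractogram:
    """Merge single-bundle tractograms into one grouped tractogram.

    All inputs must share the same spatial reference.  Metadata entries are
    namespaced per bundle.
    """
    if not named:
        raise ValueError("nothing to concatenate")
    ref = named[0][1].reference
    streamlines: list[np.ndarray] = []
    groups: dict[str, np.ndarray] = {}
    metadata: dict = {}
    for name, t in named:
        if t.reference.shape != ref.shape or not np.allclose(
            t.reference.affine, ref.affine
        ):
            raise ValueError("tractograms have incompatible references")
        offset = len(streamlines)
        streamlines.extend(t.streamlines)
        groups[name] = offset + np.arange(len(t.streamlines), dtype=np.int64)
        if t.metadata:
            meta = dict(t.metadata)
            if "outlier_indices" in meta:
                meta["outlier_indices"] = (
                    np.asarray(meta["outlier_indices"], dtype=np.int64) + offset
                )
            metadata[name] = meta
    return Tractogram(streamlines, ref, groups, metadata)


@dataclass
class ScalarMap:
    """A 3D map of one tissue property with its voxel-to-RAS affine.

    Known metrics carry physical range invariants: FA and AWF are fractions
    in [0, 1]; MD is a positive diffusivity (mm^2/s).
    """

    values: np.ndarray
    affine: np.ndarray
    metric_name: str = "scalar"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got {self.values.ndim}D")
        self.affine = _as_affine(self.affine)
        finite = self.values[np.isfinite(self.values)]
        tol = 1e-9
        if self.metric_name in ("FA", "AWF") and finite.size:
            if finite.min() < -tol or finite.max() > 1 + tol:
                raise ValueError(
                    f"{self.metric_name} values must lie in [0, 1]; "
                    f"got range [{finite.min():g}, {finite.max():g}]"
                )
        if self.metric_name == "MD" and finite.size and finite.min() <= 0:
            raise ValueError("MD values must be positive")

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.values.astype(np.float64), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path, metric_name: str = "scalar") -> "ScalarMap":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, metric_name)


@dataclass
class TractProfileSet:
    """Per-subject tract profiles: values indexed (tract, metric, node).

    Missing profiles (e.g. a tract that could not be sampled) are NaN.
    """

    subject_id: str
    tract_names: list[str]
    metric_names: list[str]
    values: np.ndarray  # (n_tracts, n_metrics, n_nodes)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.tract_names), len(self.metric_names))
        if self.values.ndim != 3 or self.values.shape[:2] != expected:
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{expected} tracts x metrics"
            )

    @property
    def n_nodes(self) -> int:
        return self.values.shape[2]

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long format: subjectID, tractID, nodeID + one column/metric."""
        k, m, n = self.values.shape
        rows = {
            "subjectID": np.repeat(self.subject_id, k * n),
            "tractID": np.repeat(self.tract_names, n),
            "nodeID": np.tile(np.arange(n), k),
        }
        df = pd.DataFrame(rows)
        for j, metric in enumerate(self.metric_names):
            df[metric] = self.values[:, j, :].reshape(-1)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        subject_id: str | None = None,
        tract_names=None,
        metric_names=None,
    ) -> "TractProfileSet":
        if subject_id is not None:
            df = df[df["subjectID"].astype(str) == str(subject_id)]
        else:
            ids = df["subjectID"].unique()
            if len(ids) != 1:
                raise ValueError("dataframe holds multiple subjects; pass subject_id")
            subject_id = str(ids[0])
        if tract_names is None:
            tract_names = list(dict.fromkeys(df["tractID"]))
        if metric_names is None:
            metric_names = [
                c for c in df.columns if c not in ("subjectID", "tractID", "nodeID")
            ]
        n_nodes = int(df["nodeID"].max()) + 1
        values = np.full((len(tract_names), len(metric_names), n_nodes), np.nan)
        t_index = {t: i for i, t in enumerate(tract_names)}
        for tract, sub in df.groupby("tractID", sort=False):
            i = t_index[tract]
            nodes = sub["nodeID"].to_numpy(dtype=int)
            for j, metric in enumerate(metric_names):
                values[i, j, nodes] = sub[metric].to_numpy(dtype=float)
        return cls(str(subject_id), list(tract_names), list(metric_names), values)


def profiles_to_csv(profile_sets: list[TractProfileSet], path) -> None:
    pd.concat([p.to_dataframe() for p in profile_sets], ignore_index=True).to_csv(
        path, index=False
    )


def profiles_from_csv(path) -> list[TractProfileSet]:
    df = pd.read_csv(path)
    return [
        TractProfileSet.from_dataframe(df, subject_id=sid)
        for sid in dict.fromkeys(df["subjectID"].astype(str))
    ]
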