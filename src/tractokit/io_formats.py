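"""TRK and TRX tractogram file formats, conversion, and a fidelity harness.

TRK (TrackVis version 2) stores one streamline group per file with a fixed
1000-byte header and float32 coordinates in "voxel-mm" space: voxel indices
with a corner-of-voxel origin, multiplied by voxel size.  The conversion
to/from the package's internal RAS-mm space is explicit here and is the
classic interoperability trap of the format.

TRX is a zip container holding a small JSON header, one flat typed positions
array (3 components per vertex, float16 or float32), a per-streamline offsets
array, and one index array per named group -- so a whole multi-tract subject
fits in a single file.  Unknown files inside the container are ignored on
read (forward compatibility); per-vertex/per-streamline data arrays are not
written.
"""

from __future__ import annotations

import json
import re
import time
import tracemalloc
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ScalarMap, SpatialReference, Tractogram

__all__ = [
    "TrkFormatError",
    "TrxFormatError",
    "write_trk",
    "read_trk",
    "write_trx",
    "read_trx",
    "convert",
    "compare_formats",
    "FormatComparison",
]


class TrkFormatError(ValueError):
    """Malformed or inconsistent TRK file."""


class TrxFormatError(ValueError):
    """Malformed or inconsistent TRX container."""


# ---------------------------------------------------------------------------
# TRK (TrackVis) dialect
# ---------------------------------------------------------------------------

TRK_HEADER_SIZE = 1000
TRK_MAGIC = b"TRACK"

_TRK_DTYPE = np.dtype(
    [
        ("id_string", "S6"),
        ("dim", "<i2", 3),
        ("voxel_size", "<f4", 3),
        ("origin", "<f4", 3),
        ("n_scalars", "<i2"),
        ("scalar_name", "S20", 10),
        ("n_properties", "<i2"),
        ("property_name", "S20", 10),
        ("vox_to_ras", "<f4", (4, 4)),
        ("reserved", "S444"),
        ("voxel_order", "S4"),
        ("pad2", "S4"),
        ("image_orientation_patient", "<f4", 6),
        ("pad1", "S2"),
        ("invert_x", "u1"),
        ("invert_y", "u1"),
        ("invert_z", "u1"),
        ("swap_xy", "u1"),
        ("swap_yz", "u1"),
        ("swap_zx", "u1"),
        ("n_count", "<i4"),
        ("version", "<i4"),
        ("hdr_size", "<i4"),
    ]
)
assert _TRK_DTYPE.itemsize == TRK_HEADER_SIZE


def _rasmm_to_voxmm(points: np.ndarray, ref: SpatialReference) -> np.ndarray:
    inv = np.linalg.inv(ref.affine)
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    return (vox + 0.5) * np.asarray(ref.voxel_sizes)


def _voxmm_to_rasmm(points: np.ndarray, ref: SpatialReference) -> np.ndarray:
    vox = points / np.asarray(ref.voxel_sizes) - 0.5
    return vox @ ref.affine[:3, :3].T + ref.affine[:3, 3]


def _voxel_order(affine: np.ndarray) -> bytes:
    from nibabel.orientations import aff2axcodes

    return "".join(aff2axcodes(affine)).encode("ascii")


def write_trk(t: Tractogram, path, group: str | None = None) -> None:
    """Write streamlines (optionally one named group) as a TRK file.

    TRK cannot represent multiple named groups; to persist a segmented
    tractogram write one file per tract.
    """
    if group is not None:
        streamlines = t.group_streamlines(group)
    else:
        streamlines = t.streamlines
    ref = t.reference
    hdr = np.zeros((), dtype=_TRK_DTYPE)
    hdr["id_string"] = TRK_MAGIC
    hdr["dim"] = ref.shape
    hdr["voxel_size"] = ref.voxel_sizes
    hdr["vox_to_ras"] = ref.affine.astype(np.float32)
    hdr["voxel_order"] = _voxel_order(ref.affine)
    hdr["n_count"] = len(streamlines)
    hdr["version"] = 2
    hdr["hdr_size"] = TRK_HEADER_SIZE
    with open(path, "wb") as f:
        f.write(hdr.tobytes())
        for s in streamlines:
            voxmm = _rasmm_to_voxmm(np.asarray(s, dtype=float), ref)
            f.write(np.int32(len(s)).tobytes())
            f.write(voxmm.astype("<f4").tobytes())


def read_trk(path, group_name: str | None = None) -> Tractogram:
    """Read a TRK file into a single-group tractogram (RAS mm).

    The group is named after ``group_name`` or the file stem.  Raises
    :class:`TrkFormatError` on a bad magic string, truncated records, or a
    header streamline count that disagrees with the records present.
    """
    path = Path(path)
    with open(path, "rb") as f:
        raw = f.read(TRK_HEADER_SIZE)
        if len(raw) < TRK_HEADER_SIZE:
            raise TrkFormatError(
                f"{path}: truncated header ({len(raw)} < {TRK_HEADER_SIZE} bytes)"
            )
        hdr = np.frombuffer(raw, dtype=_TRK_DTYPE)[0]
        if not bytes(hdr["id_string"]).startswith(TRK_MAGIC):
            raise TrkFormatError(
                f"{path}: bad magic {bytes(hdr['id_string'])!r}, expected {TRK_MAGIC!r}"
            )
        if int(hdr["hdr_size"]) != TRK_HEADER_SIZE:
            raise TrkFormatError(
                f"{path}: header size field is {int(hdr['hdr_size'])}, "
                f"expected {TRK_HEADER_SIZE}"
            )
        n_scalars = int(hdr["n_scalars"])
        n_properties = int(hdr["n_properties"])
        affine = np.array(hdr["vox_to_ras"], dtype=float)
        if affine[3, 3] == 0:
            # TRK version 1 files may leave the affine zeroed; refuse rather
            # than guess a spatial mapping.
            raise TrkFormatError(f"{path}: voxel-to-RAS affine is not set")
        ref = SpatialReference(
            tuple(int(d) for d in hdr["dim"]),
            tuple(float(v) for v in hdr["voxel_size"]),
            affine,
        )
        streamlines: list[np.ndarray] = []
        while True:
            count_raw = f.read(4)
            if not count_raw:
                break
            if len(count_raw) < 4:
                raise TrkFormatError(f"{path}: truncated streamline record")
            n_pts = int(np.frombuffer(count_raw, dtype="<i4")[0])
            if n_pts < 0:
                raise TrkFormatError(f"{path}: negative point count {n_pts}")
            n_bytes = n_pts * (3 + n_scalars) * 4 + n_properties * 4
            data = f.read(n_bytes)
            if len(data) < n_bytes:
                raise TrkFormatError(
                    f"{path}: truncated streamline record "
                    f"({len(data)} < {n_bytes} bytes)"
                )
            pts = np.frombuffer(data[: n_pts * (3 + n_scalars) * 4], dtype="<f4")
            pts = pts.reshape(n_pts, 3 + n_scalars)[:, :3].astype(float)
            streamlines.append(_voxmm_to_rasmm(pts, ref))
    n_count = int(hdr["n_count"])
    if n_count > 0 and n_count != len(streamlines):
        raise TrkFormatError(
            f"{path}: header declares n_count={n_count} but file holds "
            f"{len(streamlines)} streamlines"
        )
    name = group_name if group_name is not None else path.stem
    groups = {name: np.arange(len(streamlines), dtype=np.int64)}
    return Tractogram(streamlines, ref, groups)


# ---------------------------------------------------------------------------
# TRX dialect
# ---------------------------------------------------------------------------

_POSITION_DTYPES = {"float16": np.float16, "float32": np.float32, "float64": np.float64}
_POSITIONS_RE = re.compile(r"^positions\.3\.(float16|float32|float64)$")
_OFFSETS_RE = re.compile(r"^offsets\.(uint32|uint64)$")
_GROUP_RE = re.compile(r"^groups/(.+)\.(uint32|uint64)$")

DEFAULT_ZIP_LEVEL = 6


def write_trx(
    t: Tractogram,
    path,
    dtype: str = "float16",
    compress: bool = True,
    zip_level: int = DEFAULT_ZIP_LEVEL,
) -> None:
    """Write a whole grouped tractogram into one TRX zip container.

    Coordinates are stored in RAS mm with the requested dtype (``float16``
    halves the vertex payload at a max relative rounding error of 2^-11);
    ``compress`` turns on zip DEFLATE.
    """
    if dtype not in _POSITION_DTYPES:
        raise ValueError(f"dtype must be one of {sorted(_POSITION_DTYPES)}")
    lengths = np.array([len(s) for s in t.streamlines], dtype=np.uint64)
    offsets = np.zeros(len(lengths), dtype=np.uint64)
    if len(lengths) > 1:
        offsets[1:] = np.cumsum(lengths[:-1])
    if len(t.streamlines):
        positions = np.concatenate([np.asarray(s, float) for s in t.streamlines])
    else:
        positions = np.empty((0, 3))
    header = {
        "DIMENSIONS": list(t.reference.shape),
        "VOXEL_SIZES": list(t.reference.voxel_sizes),
        "VOXEL_TO_RASMM": t.reference.affine.tolist(),
        "NB_VERTICES": int(positions.shape[0]),
        "NB_STREAMLINES": len(t.streamlines),
    }
    compression = zipfile.ZIP_DEFLATED if compress else zipfile.ZIP_STORED
    with zipfile.ZipFile(
        path, "w", compression=compression, compresslevel=zip_level
    ) as zf:
        zf.writestr("header.json", json.dumps(header, indent=1))
        zf.writestr(
            f"positions.3.{dtype}",
            np.ascontiguousarray(positions, dtype=_POSITION_DTYPES[dtype]).tobytes(),
        )
        zf.writestr("offsets.uint64", offsets.tobytes())
        for name, idx in t.groups.items():
            zf.writestr(
                f"groups/{name}.uint32",
                np.asarray(idx, dtype=np.uint32).tobytes(),
            )


def read_trx(path) -> Tractogram:
    """Read a TRX container back into a grouped tractogram (RAS mm).

    Validates that the positions payload matches its declared dtype and the
    header vertex count, that offsets are consistent, and that group indices
    are in range.  Files not recognized by this dialect are ignored.
    """
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        names = zf.namelist()
        if "header.json" not in names:
            raise TrxFormatError(f"{path}: missing header.json")
        header = json.loads(zf.read("header.json"))
        try:
            nb_vertices = int(header["NB_VERTICES"])
            nb_streamlines = int(header["NB_STREAMLINES"])
            affine = np.asarray(header["VOXEL_TO_RASMM"], dtype=float)
            dims = tuple(int(d) for d in header["DIMENSIONS"])
        except (KeyError, TypeError) as exc:
            raise TrxFormatError(f"{path}: incomplete header ({exc})") from exc

        positions = offsets = None
        groups: dict[str, np.ndarray] = {}
        for name in names:
            m = _POSITIONS_RE.match(name)
            if m:
                dt = np.dtype(_POSITION_DTYPES[m.group(1)])
                raw = zf.read(name)
                expected = nb_vertices * 3 * dt.itemsize
                if len(raw) != expected:
                    raise TrxFormatError(
                        f"{path}: positions payload is {len(raw)} bytes, "
                        f"expected {expected} for {nb_vertices} vertices of {dt}"
                    )
                positions = np.frombuffer(raw, dtype=dt).reshape(-1, 3).astype(float)
                continue
            m = _OFFSETS_RE.match(name)
            if m:
                dt = np.dtype(m.group(1))
                raw = zf.read(name)
                if len(raw) != nb_streamlines * dt.itemsize:
                    raise TrxFormatError(
                        f"{path}: offsets payload is {len(raw)} bytes, expected "
                        f"{nb_streamlines * dt.itemsize}"
                    )
                offsets = np.frombuffer(raw, dtype=dt).astype(np.int64)
                continue
            m = _GROUP_RE.match(name)
            if m:
                groups[m.group(1)] = np.frombuffer(
                    zf.read(name), dtype=m.group(2)
                ).astype(np.int64)

    if positions is None:
        raise TrxFormatError(f"{path}: no positions array found")
    if offsets is None:
        raise TrxFormatError(f"{path}: no offsets array found")
    if len(offsets) and (
        np.any(np.diff(offsets) < 0) or offsets[0] != 0 or offsets[-1] > nb_vertices
    ):
        raise TrxFormatError(f"{path}: offsets are not a valid partition")
    bounds = np.concatenate([offsets, [nb_vertices]])
    streamlines = [
        positions[bounds[i]: bounds[i + 1]] for i in range(nb_streamlines)
    ]
    for name, idx in groups.items():
        if idx.size and (idx.min() < 0 or idx.max() >= nb_streamlines):
            raise TrxFormatError(
                f"{path}: group {name!r} indexes past {nb_streamlines} streamlines"
            )
    ref = SpatialReference.from_affine(dims, affine)
    return Tractogram(streamlines, ref, groups)


def convert(
    in_path,
    out_path,
    dtype: str = "float16",
    compress: bool = True,
    zip_level: int = DEFAULT_ZIP_LEVEL,
) -> None:
    """Convert between TRK and TRX based on file extensions."""
    in_path, out_path = Path(in_path), Path(out_path)
    if in_path.suffix == ".trk":
        t = read_trk(in_path)
    elif in_path.suffix == ".trx":
        t = read_trx(in_path)
    else:
        raise ValueError(f"unsupported input format {in_path.suffix!r}")
    if out_path.suffix == ".trk":
        write_trk(t, out_path)
    elif out_path.suffix == ".trx":
        write_trx(t, out_path, dtype=dtype, compress=compress, zip_level=zip_level)
    else:
        raise ValueError(f"unsupported output format {out_path.suffix!r}")


# ---------------------------------------------------------------------------
# Format fidelity harness
# ---------------------------------------------------------------------------

@dataclass
class FormatComparison:
    """Profile fidelity and storage comparison between TRK and TRX."""

    per_tract: pd.DataFrame          # tract, max_rel_diff_pct
    max_rel_diff_pct: float          # across all tracts/metrics/nodes
    trk_bytes: int
    trx_bytes: int
    size_ratio: float                # trx / trk
    time_ratio: float                # profile time trx / trk (informational)
    memory_ratio: float              # peak memory trx / trk (informational)
    extras: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        df = self.per_tract.copy()
        df["size_ratio"] = self.size_ratio
        df["time_ratio"] = self.time_ratio
        df["memory_ratio"] = self.memory_ratio
        df.to_csv(path, index=False)


def _profiles_from_trk_dir(trk_dir: Path, tract_names, maps, **profile_kw):
    from .profiles import extract_profiles

    values = None
    for ti, name in enumerate(tract_names):
        t = read_trk(trk_dir / f"{name}.trk", group_name=name)
        prof = extract_profiles(t, maps, subject_id="trk", **profile_kw)
        if values is None:
            values = np.full(
                (len(tract_names),) + prof.values.shape[1:], np.nan
            )
        values[ti] = prof.values[0]
    return values


def compare_formats(
    t: Tractogram,
    maps: list[ScalarMap],
    work_dir,
    dtype: str = "float16",
    compress: bool = True,
    zip_level: int = DEFAULT_ZIP_LEVEL,
    **profile_kw,
) -> FormatComparison:
    """Write ``t`` as per-tract TRKs and one TRX, re-profile from each, and
    report fidelity, disk-size, and (informational) time/memory ratios.

    The profile difference is reported as the maximum over tracts, metrics
    and nodes of ``|p_trk - p_trx| / |p_trk|`` in percent.  Time and memory
    ratios are hardware dependent and are never asserted by this package's
    tests.
    """
    from .profiles import extract_profiles

    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    tract_names = list(t.groups)

    trk_bytes = 0
    for name in tract_names:
        p = work_dir / f"{name}.trk"
        write_trk(t, p, group=name)
        trk_bytes += p.stat().st_size
    trx_path = work_dir / "subject.trx"
    write_trx(t, trx_path, dtype=dtype, compress=compress, zip_level=zip_level)
    trx_bytes = trx_path.stat().st_size

    tracemalloc.start()
    t0 = time.perf_counter()
    trk_values = _profiles_from_trk_dir(work_dir, tract_names, maps, **profile_kw)
    trk_time = time.perf_counter() - t0
    _, trk_peak = tracemalloc.get_traced_memory()
    tracemalloc.stop()

    tracemalloc.start()
    t0 = time.perf_counter()
    t_trx = read_trx(trx_path)
    trx_prof = extract_profiles(t_trx, maps, subject_id="trx", **profile_kw)
    trx_values = trx_prof.values[
        [list(t_trx.groups).index(n) for n in tract_names]
    ]
    trx_time = time.perf_counter() - t0
    _, trx_peak = tracemalloc.get_traced_memory()
    tracemalloc.stop()

    denom = np.abs(trk_values)
    tiny = np.finfo(float).tiny
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.abs(trk_values - trx_values) / np.maximum(denom, tiny)
    both_nan = np.isnan(trk_values) & np.isnan(trx_values)
    rel = np.where(both_nan, 0.0, rel)
    per_tract = pd.DataFrame(
        {
            "tract": tract_names,
            "max_rel_diff_pct": 100.0 * np.nanmax(rel, axis=(1, 2)),
        }
    )
    return FormatComparison(
        per_tract=per_tract,
        max_rel_diff_pct=float(100.0 * np.nanmax(rel)),
        trk_bytes=trk_bytes,
        trx_bytes=trx_bytes,
        size_ratio=trx_bytes / trk_bytes,
        time_ratio=trx_time / trk_time if trk_time > 0 else float("nan"),
        memory_ratio=trx_peak / trk_peak if trk_peak > 0 else float("nan"),
    )
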