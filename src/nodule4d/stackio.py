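"""Image-stack and table I/O.

The canonical in-memory carrier is :class:`ImageStack`: a ``T x Z x C x Y x X``
voxel grid with physical calibration.  All analysis modules consume this axis
order only; :func:`load_stack` normalises whatever order a TIFF was saved in.

Coordinate conventions
----------------------
Voxel indices are 0-based.  Physical coordinates are voxel-centre times voxel
size, in micrometres.  Z increases away from the substrate: the dish bottom is
the plane ``z = 0``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger(__name__)

AXES = "TZCYX"


@dataclass
class Calibration:
    """Physical calibration of a stack.

    ``voxel_size`` is ``(dx, dy, dz)`` in micrometres.  ``frame_interval`` is
    the time between consecutive T indices, in ``frame_unit`` ('s', 'h' or
    'day') — declared, never inferred.
    """

    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame_interval: float = 1.0
    frame_unit: str = "s"

    def __post_init__(self) -> None:
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be strictly positive, got {self.voxel_size}")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be strictly positive")
        if self.frame_unit not in ("s", "min", "h", "day"):
            raise ValueError(f"unknown frame unit {self.frame_unit!r}")

    @property
    def dx(self) -> float:
        return float(self.voxel_size[0])

    @property
    def dy(self) -> float:
        return float(self.voxel_size[1])

    @property
    def dz(self) -> float:
        return float(self.voxel_size[2])

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return self.dx * self.dy * self.dz

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """(dz, dy, dx) — the order scikit-image expects for ZYX arrays."""
        return (self.dz, self.dy, self.dx)

    def to_dict(self) -> dict:
        return {
            "voxel_size": list(self.voxel_size),
            "frame_interval": self.frame_interval,
            "frame_unit": self.frame_unit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        return cls(
            voxel_size=tuple(d["voxel_size"]),
            frame_interval=d["frame_interval"],
            frame_unit=d["frame_unit"],
        )


@dataclass
class ImageStack:
    """A calibrated T x Z x C x Y x X voxel grid."""

    data: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"expected 5 axes ({AXES}), got shape {self.data.shape}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("intensities must be nonnegative")
        if not self.channel_names:
            self.channel_names = tuple(f"C{i}" for i in range(self.data.shape[2]))
        if len(self.channel_names) != self.data.shape[2]:
            raise ValueError(
                f"{len(self.channel_names)} channel labels for {self.data.shape[2]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError(f"channel labels must be unique, got {self.channel_names}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def channel_index(self, label: str) -> int:
        if label not in self.channel_names:
            raise KeyError(f"channel {label!r} not in {self.channel_names}")
        return self.channel_names.index(label)

    def channel(self, label: str) -> np.ndarray:
        """The (T, Z, Y, X) sub-array of one channel."""
        return self.data[:, :, self.channel_index(label)]

    def with_data(self, data: np.ndarray) -> "ImageStack":
        return replace(self, data=data)


def _normalise_axes(arr: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand an array with named axes into TZCYX."""
    axes = axes.upper()
    if len(axes) != arr.ndim:
        raise ValueError(f"axes string {axes!r} does not match array with {arr.ndim} dims")
    unknown = set(axes) - set(AXES + "SQ")
    if unknown:
        raise ValueError(f"cannot interpret axes {sorted(unknown)} in {axes!r}")
    # treat sample/sequence axes as T if T absent, else error
    axes = axes.replace("Q", "T").replace("S", "C")
    if len(set(axes)) != len(axes):
        raise ValueError(f"duplicate axes after normalisation: {axes!r}")
    for ax in AXES:
        if ax not in axes:
            arr = arr[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in AXES]
    return np.transpose(arr, order)


def load_stack(
    path,
    calibration: Calibration | None = None,
    axes: str | None = None,
    channel_names: tuple[str, ...] = (),
) -> ImageStack:
    """Read a multi-dimensional TIFF into canonical TZCYX order.

    Axis interpretation comes from the file's metadata when present; ``axes``
    overrides it.  Missing axes are inserted with length 1.  ``calibration``
    supplies physical metadata the file lacks (and overrides file metadata
    when given).
    """
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        arr = series.asarray()
        file_axes = series.axes
        desc = tf.pages[0].description or ""
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (ValueError, TypeError):
            meta = {}
    use_axes = axes or meta.get("axes") or file_axes
    if use_axes is None or len(use_axes) != arr.ndim:
        raise ValueError(
            f"ambiguous axes for {path}: file reports {file_axes!r} for shape "
            f"{arr.shape}; pass axes= explicitly"
        )
    data = _normalise_axes(arr, use_axes)
    if calibration is None:
        if "calibration" in meta:
            calibration = Calibration.from_dict(meta["calibration"])
        else:
            raise ValueError(
                f"no calibration stored in {path} and none supplied"
            )
    names = channel_names or tuple(meta.get("channel_names", ()))
    stack = ImageStack(data=data, calibration=calibration, channel_names=names)
    log.info("loaded %s: shape %s, axes %s", path, stack.shape, AXES)
    return stack


def save_stack(stack: ImageStack, path) -> None:
    """Write a TZCYX TIFF with calibration in the image description."""
    if stack.data.shape[0] == 0:
        raise ValueError("refusing to save a stack with zero timepoints")
    meta = {
        "axes": AXES,
        "calibration": stack.calibration.to_dict(),
        "channel_names": list(stack.channel_names),
    }
    try:
        tifffile.imwrite(path, stack.data, description=json.dumps(meta))
    except OSError as exc:
        raise OSError(f"cannot write stack to {path}: {exc}") from exc
    log.info("saved %s: shape %s", path, stack.shape)


def write_table(records, path, units: dict[str, str] | None = None) -> None:
    """Write a list of records (dataclasses or dicts) to CSV.

    All records must share one schema; a header-only file is written for an
    empty list only when ``records`` is a DataFrame or a (possibly empty)
    list accompanied by a DataFrame-convertible schema.
    Units are documented in ``# column: unit`` header comments.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        keys = None
        for rec in records:
            d = rec if isinstance(rec, dict) else _record_dict(rec)
            if keys is None:
                keys = list(d)
            elif list(d) != keys:
                extra = set(d) ^ set(keys)
                raise ValueError(
                    f"heterogeneous record schemas; mismatched fields: {sorted(extra)}"
                )
            rows.append(d)
        df = pd.DataFrame(rows, columns=keys)
    with open(path, "w") as fh:
        for col, unit in (units or {}).items():
            fh.write(f"# {col}: {unit}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _record_dict(rec) -> dict:
    import dataclasses

    if dataclasses.is_dataclass(rec):
        out = {}
        for f in dataclasses.fields(rec):
            v = getattr(rec, f.name)
            if isinstance(v, (tuple, list, np.ndarray)):
                v = " ".join(repr(float(x)) for x in np.ravel(v))
            out[f.name] = v
        return out
    raise TypeError(f"cannot turn {type(rec).__name__} into a table row")
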