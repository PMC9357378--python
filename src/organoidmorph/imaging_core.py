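"""Calibrated image containers and the generic segmentation operators.

All spatial arrays are 0-based and ``(z, y, x)`` ordered; a 2D image is a
stack with a single z plane. Physical measurements are always reported in
micrometres through the per-axis ``voxel_size`` calibration. The default
connectivity is face connectivity (4-neighbour in-plane, 6-neighbour in 3D),
the most conservative choice against chaining isolated noise voxels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage import measure

from .errors import (
    ChannelNotFoundError,
    DegenerateHistogramError,
    GeometryError,
    InvalidParameterError,
)

Connectivity = Literal["face", "full"]


def _as_zyx(voxel_size: Sequence[float]) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) == 2:  # (y, x) given for a 2D image
        vs = (1.0,) + vs
    if len(vs) != 3 or any(v <= 0 or not np.isfinite(v) for v in vs):
        raise InvalidParameterError(f"voxel_size must be 3 positive values (z, y, x), got {voxel_size!r}")
    return vs  # type: ignore[return-value]


@dataclass
class ImageStack:
    """A calibrated multi-channel intensity stack indexed ``(z, y, x, channel)``.

    Parameters
    ----------
    data
        Non-negative finite intensities; a 2D field is stored with z-size 1.
    voxel_size
        Physical size per axis in µm, ``(z, y, x)``.
    channel_labels
        Ordered marker names, e.g. ``["ZO1", "DAPI"]``; unique, one per channel.
    metadata
        Free-form acquisition annotations.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_labels: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None, :, :, None]
        elif self.data.ndim == 3:  # (z, y, x) single channel
            self.data = self.data[..., None]
        if self.data.ndim != 4:
            raise GeometryError(f"expected (z, y, x, channel) data, got shape {self.data.shape}")
        self.voxel_size = _as_zyx(self.voxel_size)
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[-1]:
            raise GeometryError(
                f"{len(self.channel_labels)} channel labels for {self.data.shape[-1]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidParameterError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise InvalidParameterError("intensities must be non-negative finite numbers")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def is_2d(self) -> bool:
        return self.data.shape[0] == 1

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_labels.index(name)
        except ValueError:
            raise ChannelNotFoundError(
                f"channel {name!r} not in {self.channel_labels}"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """The ``(z, y, x)`` intensity array of one marker channel."""
        return self.data[..., self.channel_index(name)]

    def single_channel(self, name: str) -> "ImageStack":
        return ImageStack(
            self.channel(name), self.voxel_size, [name], dict(self.metadata)
        )


@dataclass
class BinaryMask:
    """A boolean mask sharing geometry with one ImageStack channel."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise GeometryError(f"mask must be (z, y, x), got shape {self.data.shape}")
        self.voxel_size = _as_zyx(self.voxel_size)


@dataclass
class LabelMap:
    """Integer-labelled connected components: 0 = background, k > 0 = object k."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    object_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise GeometryError(f"labels must be (z, y, x), got shape {self.data.shape}")
        if np.any(self.data < 0):
            raise InvalidParameterError("labels must be non-negative integers")
        self.data = self.data.astype(np.int32, copy=False)
        self.voxel_size = _as_zyx(self.voxel_size)
        present = sorted(int(v) for v in np.unique(self.data) if v != 0)
        if not self.object_ids:
            self.object_ids = present
        elif self.object_ids != present:
            raise InvalidParameterError("object_ids do not match labels present in data")

    @property
    def n_objects(self) -> int:
        return len(self.object_ids)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def pixel_area(self) -> float:
        return float(self.voxel_size[1] * self.voxel_size[2])

    def object_mask(self, object_id: int) -> np.ndarray:
        return self.data == object_id


@dataclass
class ObjectFilterCriteria:
    """Size/border/shape gates applied to labelled objects.

    ``min_size_um`` is an area in µm² for single-plane maps and a volume in
    µm³ for 3D maps. ``exclude_border`` drops any object with a voxel on the
    first/last y or x index (z is excluded: a 3D slab is a 2D field of view
    in depth). Shape limits apply to single-plane maps only.
    """

    min_size_um: float = 0.0
    exclude_border: bool = False
    min_circularity: float | None = None
    min_solidity: float | None = None

    def __post_init__(self) -> None:
        if self.min_size_um < 0:
            raise InvalidParameterError("min_size_um must be >= 0")
        for name in ("min_circularity", "min_solidity"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1):
                raise InvalidParameterError(f"{name} must lie in [0, 1]")


@dataclass
class SegmentationResult:
    """A LabelMap together with the threshold actually applied."""

    labels: LabelMap
    threshold: float
    method: str


def _connectivity_struct(ndim: int, connectivity: Connectivity) -> np.ndarray:
    order = 1 if connectivity == "face" else ndim
    return ndimage.generate_binary_structure(ndim, order)


def max_project(stack: ImageStack, channel: str) -> ImageStack:
    """Maximum-intensity projection of one channel along z.

    Idempotent on 2D input; the output keeps the (y, x) calibration.
    """
    arr = stack.channel(channel)
    proj = arr.max(axis=0)
    return ImageStack(
        proj[None, :, :, None],
        stack.voxel_size,
        [channel],
        dict(stack.metadata, projection="max-z"),
    )


def denoise(
    stack: ImageStack,
    sigma: float,
    method: Literal["gaussian", "median"] = "gaussian",
    sigma_in_um: bool = False,
) -> ImageStack:
    """Smooth every channel with a normalized Gaussian (or median) kernel.

    ``sigma`` is in pixels by default, or in µm with ``sigma_in_um=True``
    (converted per axis through the voxel size). ``sigma = 0`` returns the
    input unchanged. The Gaussian kernel is normalized, so total intensity
    of interior-supported signals is preserved.
    """
    if sigma < 0:
        raise InvalidParameterError("sigma must be >= 0")
    if sigma == 0:
        return stack
    out = np.empty_like(stack.data, dtype=float)
    if sigma_in_um:
        sig = [sigma / v for v in stack.voxel_size]
    else:
        sig = [sigma, sigma, sigma]
    if stack.is_2d:
        sig[0] = 0.0
    for c in range(stack.data.shape[-1]):
        if method == "gaussian":
            out[..., c] = ndimage.gaussian_filter(stack.data[..., c].astype(float), sigma=sig)
        elif method == "median":
            size = [max(1, int(round(2 * s + 1))) for s in sig]
            out[..., c] = ndimage.median_filter(stack.data[..., c].astype(float), size=size)
        else:
            raise InvalidParameterError(f"unknown denoise method {method!r}")
    return ImageStack(out, stack.voxel_size, stack.channel_labels, dict(stack.metadata))


def threshold_and_label(
    stack: ImageStack,
    method: Literal["fixed", "otsu"] = "otsu",
    value: float | None = None,
    connectivity: Connectivity = "face",
    channel: str | None = None,
) -> SegmentationResult:
    """Threshold a single channel and label connected foreground components.

    The mask is ``intensity > threshold``; with ``method="otsu"`` the
    threshold maximizes between-class variance, with ``method="fixed"`` the
    supplied ``value`` is used. The threshold actually applied is returned
    with the LabelMap so every run is reproducible from its log.
    """
    if channel is None:
        if stack.data.shape[-1] != 1:
            raise InvalidParameterError("multi-channel stack: specify channel")
        arr = stack.data[..., 0]
    else:
        arr = stack.channel(channel)
    arr = np.asarray(arr, dtype=float)
    if arr.size == 0:
        raise InvalidParameterError("empty image")
    if method == "fixed":
        if value is None:
            raise InvalidParameterError('method="fixed" requires a threshold value')
        thr = float(value)
    elif method == "otsu":
        if np.ptp(arr) == 0:
            raise DegenerateHistogramError(
                "constant image: Otsu threshold is undefined"
            )
        thr = otsu_threshold(arr)
    else:
        raise InvalidParameterError(f"unknown threshold method {method!r}")
    mask = arr > thr
    # a z=1 plane under the 3D structure reduces to 4-/8-connectivity in-plane
    labels, _ = ndimage.label(mask, structure=_connectivity_struct(3, connectivity))
    return SegmentationResult(
        labels=LabelMap(labels, stack.voxel_size),
        threshold=thr,
        method=method,
    )


def otsu_threshold(arr: np.ndarray) -> float:
    """Exact Otsu threshold by exhaustive sweep over the sorted intensities.

    Maximizes the between-class variance w0·w1·(µ0 − µ1)² over every split
    of the sorted values, without histogram binning — binned variants can
    flip boundary pixels when a mode's tail abuts an empty gap. Ties take
    the lowest threshold, so the result is deterministic.
    """
    v = np.sort(np.asarray(arr, dtype=float).ravel())
    n = v.size
    if v[0] == v[-1]:
        raise DegenerateHistogramError("constant image: Otsu threshold is undefined")
    csum = np.cumsum(v)
    i = np.arange(1, n)
    w0 = i / n
    mu0 = csum[:-1] / i
    mu1 = (csum[-1] - csum[:-1]) / (n - i)
    var = w0 * (1 - w0) * (mu0 - mu1) ** 2
    var[v[1:] == v[:-1]] = -np.inf  # split must fall between distinct values
    j = int(np.argmax(var))
    return float(0.5 * (v[j] + v[j + 1]))


def filter_labeled_objects(
    labels: LabelMap, criteria: ObjectFilterCriteria
) -> LabelMap:
    """Drop labelled objects violating size, border or shape criteria.

    Survivors keep their exact voxel membership and are relabelled
    consecutively in order of their original label, making the operation
    deterministic and idempotent.
    """
    data = labels.data
    is_2d = data.shape[0] == 1
    unit_size = labels.pixel_area if is_2d else labels.voxel_volume

    survivors: list[int] = []
    for oid in labels.object_ids:
        mask = data == oid
        size_um = mask.sum() * unit_size
        if size_um < criteria.min_size_um:
            continue
        if criteria.exclude_border and _touches_border(mask):
            continue
        if is_2d and (criteria.min_circularity is not None or criteria.min_solidity is not None):
            props = measure.regionprops(mask[0].astype(np.uint8))[0]
            if criteria.min_circularity is not None:
                circ = circularity(props.area, props.perimeter_crofton)
                if circ < criteria.min_circularity:
                    continue
            if criteria.min_solidity is not None and props.solidity < criteria.min_solidity:
                continue
        survivors.append(oid)

    out = np.zeros_like(data)
    for new_id, oid in enumerate(survivors, start=1):
        out[data == oid] = new_id
    return LabelMap(out, labels.voxel_size)


def _touches_border(mask: np.ndarray) -> bool:
    """Border contact in the (y, x) field-of-view sense; z faces excluded."""
    return bool(
        mask[:, 0, :].any()
        or mask[:, -1, :].any()
        or mask[:, :, 0].any()
        or mask[:, :, -1].any()
    )


def circularity(area: float, perimeter: float) -> float:
    """Isoperimetric circularity 4πA/P² — 1 for a disc, smaller otherwise."""
    if perimeter <= 0:
        return 1.0
    return float(4.0 * np.pi * area / perimeter**2)


# ---------------------------------------------------------------------------
# File I/O

def read_tiff(
    path: str | Path,
    voxel_size: Sequence[float] = (1.0, 1.0, 1.0),
    channel_labels: Sequence[str] | None = None,
) -> ImageStack:
    """Read a (multi-page) TIFF/OME-TIFF into an ImageStack.

    OME channel names and physical pixel sizes are honoured when present;
    otherwise ``voxel_size`` and ``channel_labels`` supply the calibration
    (labels default to ``C0..Cn``).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        axes = tf.series[0].axes if tf.series else ""
        ome_labels: list[str] | None = None
        ome_voxel: tuple[float, float, float] | None = None
        if tf.ome_metadata:
            ome_labels, ome_voxel = _parse_ome(tf.ome_metadata)
    arr = _reorder_axes(arr, axes)
    # plain multi-page TIFFs are ambiguous (pages may be z or channels);
    # an explicit channel_labels hint disambiguates
    if (
        channel_labels is not None
        and arr.shape[-1] != len(channel_labels)
        and arr.shape[0] == 1
        and arr.shape[-1] > 1
    ):
        if len(channel_labels) == 1:  # pages are z planes, not channels
            arr = arr[0].transpose(2, 0, 1)[..., None]
    n_ch = arr.shape[-1]
    if channel_labels is None:
        channel_labels = ome_labels if ome_labels and len(ome_labels) == n_ch else [
            f"C{i}" for i in range(n_ch)
        ]
    if ome_voxel is not None:
        voxel_size = ome_voxel
    return ImageStack(arr, tuple(voxel_size), list(channel_labels), {"source": str(path)})


def _parse_ome(ome_xml: str) -> tuple[list[str] | None, tuple[float, float, float] | None]:
    import xml.etree.ElementTree as ET

    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None, None
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    labels: list[str] = []
    voxel = None
    for px in root.iter(f"{{{ns['ome']}}}Pixels"):
        for ch in px.iter(f"{{{ns['ome']}}}Channel"):
            name = ch.get("Name")
            if name:
                labels.append(name)
        sz = px.get("PhysicalSizeZ")
        sy = px.get("PhysicalSizeY")
        sx = px.get("PhysicalSizeX")
        if sy and sx:
            voxel = (float(sz) if sz else 1.0, float(sy), float(sx))
        break
    return (labels or None), voxel


def _reorder_axes(arr: np.ndarray, axes: str) -> np.ndarray:
    """Coerce a tifffile array to (z, y, x, c)."""
    if axes and set(axes) <= set("TZCYXS") and len(axes) == arr.ndim:
        axes = axes.replace("S", "C")
        if "T" in axes:  # treat a singleton T as Z surrogate
            arr = arr.take(0, axis=axes.index("T")) if arr.shape[axes.index("T")] == 1 else arr
            if arr.ndim < len(axes):
                axes = axes.replace("T", "")
        order = [axes.index(a) for a in "ZYXC" if a in axes]
        arr = np.transpose(arr, order)
        if "Z" not in axes:
            arr = arr[None]
        if "C" not in axes:
            arr = arr[..., None]
        return arr
    # fall back on dimensionality heuristics
    if arr.ndim == 2:
        return arr[None, :, :, None]
    if arr.ndim == 3:  # ambiguous (z,y,x) vs (y,x,c): small last axis means channels
        if arr.shape[-1] <= 4:
            return arr[None]
        return arr[..., None]
    return arr


def write_label_map(
    path: str | Path,
    labels: LabelMap,
    threshold: float | None = None,
    criteria: ObjectFilterCriteria | None = None,
) -> None:
    """Write a LabelMap as 16-bit TIFF with a JSON provenance sidecar."""
    path = Path(path)
    data = labels.data
    if data.max() > np.iinfo(np.uint16).max:
        raise InvalidParameterError("more than 65535 objects cannot be stored as 16-bit TIFF")
    tifffile.imwrite(path, data.astype(np.uint16).squeeze())
    sidecar = {
        "voxel_size_um": list(labels.voxel_size),
        "n_objects": labels.n_objects,
        "threshold": threshold,
        "criteria": dataclasses.asdict(criteria) if criteria else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
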