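"""Core image container and TIFF I/O.

Every processing step in the package consumes and returns :class:`Image`: a
single-channel 2D intensity grid tagged with its physical pixel size in
micrometres, plus an optional exclusion mask of pixels that downstream
quantification must ignore (e.g. an astrocyte soma).

Multi-channel fields are plain ``dict[str, Image]`` keyed by channel role
(``pre``, ``post``, ``astro``, ...). On disk a field is a multi-page 16-bit
TIFF (one page per channel) with the pixel size stored both in the TIFF
resolution tags and in a JSON sidecar that also records the channel order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

MAX_UINT16 = 65535


@dataclass
class Image:
    """A single-channel 2D intensity image with physical pixel size.

    Parameters
    ----------
    values
        2D non-negative float array of intensities.
    pixel_size_um
        Lateral pixel size in micrometres per pixel (isotropic).
    excluded_mask
        Optional boolean array, same shape as ``values``; ``True`` marks
        pixels excluded from all downstream quantification.
    """

    values: np.ndarray
    pixel_size_um: float
    excluded_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"Image values must be 2D, got shape {self.values.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.excluded_mask is not None:
            self.excluded_mask = np.asarray(self.excluded_mask, dtype=bool)
            if self.excluded_mask.shape != self.values.shape:
                raise ValueError(
                    "excluded_mask shape "
                    f"{self.excluded_mask.shape} != values shape {self.values.shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def field_area_um2(self) -> float:
        """Total physical area of the field (including excluded pixels)."""
        return self.values.size * self.pixel_size_um**2

    @property
    def valid_area_um2(self) -> float:
        """Physical area of non-excluded pixels."""
        if self.excluded_mask is None:
            return self.field_area_um2
        return float((~self.excluded_mask).sum()) * self.pixel_size_um**2

    def with_values(self, values: np.ndarray) -> "Image":
        """Copy of this image with new intensity values, same metadata."""
        return replace(self, values=values)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_scene(channels: dict[str, Image], path: str | Path) -> Path:
    """Write a multi-channel field as a 16-bit multi-page TIFF + JSON sidecar.

    Intensities are clipped to [0, 65535] and rounded; the clipped-pixel
    fraction is logged. The pixel size goes into the TIFF X/Y resolution
    tags (pixels per centimetre) and, at full precision, into the sidecar.
    """
    path = Path(path)
    names = list(channels)
    pixel_sizes = {img.pixel_size_um for img in channels.values()}
    if len(pixel_sizes) != 1:
        raise ValueError(f"channels disagree on pixel_size_um: {sorted(pixel_sizes)}")
    pixel_size_um = pixel_sizes.pop()

    stack = np.stack([channels[n].values for n in names])
    n_clipped = int((stack > MAX_UINT16).sum() + (stack < 0).sum())
    if n_clipped:
        logger.warning(
            "write_scene: %.4f%% of pixels clipped to the 16-bit range",
            100.0 * n_clipped / stack.size,
        )
    data = np.clip(np.rint(stack), 0, MAX_UINT16).astype(np.uint16)

    px_per_cm = 1e4 / pixel_size_um
    tifffile.imwrite(
        path,
        data,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        metadata={"axes": "CYX"},
    )
    sidecar = {"pixel_size_um": pixel_size_um, "channels": names}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_scene(path: str | Path) -> dict[str, Image]:
    """Read a multi-channel TIFF written by :func:`write_scene`.

    The pixel size is taken from the JSON sidecar when present, otherwise
    from the TIFF resolution tags; a file carrying neither raises a
    ``ValueError`` naming ``pixel_size_um``. 8-bit input is promoted to the
    16-bit working range with a logged warning (values preserved).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        pixel_size_um = None
        names = None
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            pixel_size_um = meta.get("pixel_size_um")
            names = meta.get("channels")
        if pixel_size_um is None:
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if xres is not None and unit is not None and unit.value == 3:  # cm
                num, den = xres.value
                if num:
                    pixel_size_um = 1e4 * den / num
        if pixel_size_um is None:
            raise ValueError(
                f"{path}: missing pixel-size metadata (field 'pixel_size_um'); "
                "expected a JSON sidecar or TIFF resolution tags"
            )

    if data.ndim == 2:
        data = data[None]
    if data.dtype == np.uint8:
        logger.warning("read_scene: promoting 8-bit input of %s to 16-bit working range", path)
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    if len(names) != data.shape[0]:
        raise ValueError(f"{path}: sidecar lists {len(names)} channels, TIFF has {data.shape[0]}")
    return {
        n: Image(values=data[i].astype(np.float64), pixel_size_um=float(pixel_size_um))
        for i, n in enumerate(names)
    }
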