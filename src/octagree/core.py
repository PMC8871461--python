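"""Core data containers shared by all pipeline stages.

Coordinate convention (used everywhere in this package): row 0 is the top of
the B-scan (vitreous), depth increases downward; columns are A-scan indices.
All masks and layer curves use ``(row, col)`` indexing with 0-based, half-open
ranges. Physical units are micrometres; conversion between pixels and µm
happens only at input/output boundaries via the per-image scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import tifffile

#: Retinal/choroidal interfaces in anatomical depth order (anterior to
#: posterior).  Every :class:`LayerModel` carries one depth curve per entry.
INTERFACES: tuple[str, ...] = (
    "ILM",
    "RNFL_posterior",
    "ELM",
    "EZ_center",
    "RPE_center",
    "choroid_anterior",
    "choroid_scleral",
)

MODES = ("EDI", "conventional")

#: Best achievable device signal-to-noise score.
SNR_MAX = 35.0


@dataclass(frozen=True)
class BScanImage:
    """One grayscale OCT B-scan in the exported 8-bit log-display domain.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array, shape ``(rows, cols)``.
    axial_scale, lateral_scale
        Pixel pitch in µm/pixel along depth (rows) and laterally (cols).
    mode
        ``"EDI"`` or ``"conventional"``.
    snr_score
        Device quality score in ``[0, 35]`` (35 is the best score).
    id
        Free-form identifier (eye/scan id).
    """

    pixels: np.ndarray
    axial_scale: float
    lateral_scale: float
    mode: str
    snr_score: float = SNR_MAX
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.axial_scale <= 0 or self.lateral_scale <= 0:
            raise ValueError("pixel scales must be > 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0 <= self.snr_score <= SNR_MAX:
            raise ValueError(f"snr_score must lie in [0, {SNR_MAX}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "BScanImage":
        return replace(self, pixels=pixels)

    # -- I/O ---------------------------------------------------------------
    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.pixels, photometric="minisblack")

    @classmethod
    def from_tiff(
        cls,
        path: str | Path,
        *,
        axial_scale: float,
        lateral_scale: float,
        mode: str,
        snr_score: float = SNR_MAX,
        id: str = "",
    ) -> "BScanImage":
        px = tifffile.imread(str(path))
        if px.ndim == 3:  # tolerate gray saved as RGB
            px = px[..., 0]
        return cls(px.astype(np.uint8), axial_scale, lateral_scale, mode, snr_score, id)


class LayerModel:
    """Per-A-scan depth curves for the seven named interfaces.

    Depths are stored as fractional row indices in the frame of the image the
    model belongs to.  Ground-truth models from the synthetic generator are in
    the EDI frame; :meth:`translate` maps them into the conventional frame
    given a registration shift.
    """

    def __init__(
        self,
        depths: Mapping[str, np.ndarray],
        axial_scale: float,
        lateral_scale: float,
    ) -> None:
        missing = set(INTERFACES) - set(depths)
        if missing:
            raise ValueError(f"missing interface curves: {sorted(missing)}")
        widths = {len(np.asarray(depths[name])) for name in INTERFACES}
        if len(widths) != 1:
            raise ValueError("all interface curves must share the same width")
        self.depths = {name: np.asarray(depths[name], dtype=float) for name in INTERFACES}
        self.axial_scale = float(axial_scale)
        self.lateral_scale = float(lateral_scale)

    @property
    def width(self) -> int:
        return len(self.depths[INTERFACES[0]])

    def __getitem__(self, name: str) -> np.ndarray:
        return self.depths[name]

    def validate_order(self, strict: bool = True) -> None:
        """Assert that interfaces are depth-ordered at every column."""
        for upper, lower in zip(INTERFACES[:-1], INTERFACES[1:]):
            du, dl = self.depths[upper], self.depths[lower]
            ok = np.all(du < dl) if strict else np.all(du <= dl)
            if not ok:
                raise ValueError(f"interface {upper!r} is not above {lower!r} everywhere")

    def translate(self, drow: float, dcol: int) -> "LayerModel":
        """Return the model expressed in a frame shifted by ``(drow, dcol)``.

        A feature at ``(r, c)`` in this frame sits at ``(r + drow, c + dcol)``
        in the new frame.  Columns shifted in from outside the original domain
        are edge-padded.
        """
        dcol = int(dcol)
        out = {}
        for name, d in self.depths.items():
            shifted = np.empty_like(d)
            src = np.arange(len(d)) - dcol
            np.clip(src, 0, len(d) - 1, out=src)
            shifted[:] = d[src] + drow
            out[name] = shifted
        return LayerModel(out, self.axial_scale, self.lateral_scale)

    # -- I/O ---------------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "axial_scale_um_per_px": self.axial_scale,
            "lateral_scale_um_per_px": self.lateral_scale,
            "depths_px": {name: self.depths[name].tolist() for name in INTERFACES},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "LayerModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            {k: np.asarray(v, dtype=float) for k, v in payload["depths_px"].items()},
            payload["axial_scale_um_per_px"],
            payload["lateral_scale_um_per_px"],
        )


ROI_KINDS = ("retinal-HF", "choroid-CVI", "lateral-extent")


@dataclass
class ROIMask:
    """Boolean region-of-interest mask congruent with its image."""

    mask: np.ndarray
    kind: str
    origin_mode: str = "EDI"
    transferred: bool = False
    dropped_pixels: int = 0
    warnings: tuple[str, ...] = ()
    #: half-open ``(start, stop)`` column span for lateral-extent masks
    col_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.kind not in ROI_KINDS:
            raise ValueError(f"kind must be one of {ROI_KINDS}")
        if self.origin_mode not in MODES:
            raise ValueError(f"origin_mode must be one of {MODES}")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class Registration:
    """Integer rigid translation mapping EDI coordinates onto conventional
    coordinates: a feature at ``(r, c)`` in the EDI frame sits at
    ``(r + shift[0], c + shift[1])`` in the conventional frame."""

    shift: tuple[int, int]
    score: float


@dataclass(frozen=True)
class BiomarkerTriplet:
    """The three biomarkers quantified on one image."""

    hf_count: int
    ezr: float
    cvi: float


def as_float(image: BScanImage | np.ndarray) -> np.ndarray:
    """Pixel array of ``image`` as float64 (no copy semantics guaranteed)."""
    px = image.pixels if isinstance(image, BScanImage) else image
    return np.asarray(px, dtype=float)


def check_fields(obj, conditions: Iterable[tuple[bool, str]]) -> None:
    """Raise ``ValueError`` naming the first failing field condition."""
    for ok, message in conditions:
        if not ok:
            raise ValueError(message)
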