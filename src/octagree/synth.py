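"""Synthetic paired EDI/conventional OCT B-scans with exhaustive ground truth.

The generator emulates the features of a foveal SD-OCT B-scan that the
downstream quantification stages depend on: a layered retinal reflectivity
profile (RNFL … ELM … EZ … RPE), a choroid of bright stroma with dark vessel
lumens packed to a known luminal fraction, injectable hyperreflective foci
(< 30 µm, known count and positions), optional intraretinal cysts with
sub-cyst signal attenuation, multiplicative speckle, and a configurable
EDI-vs-conventional rendering difference (deep-signal gain up and
inner-retina contrast down in EDI, choroidal attenuation in the conventional
scan).  It is not a wave-optics simulation: intensities live directly in the
8-bit log-display domain in which clinical scans are exported, and speckle is
a gamma-distributed multiplicative field applied on the back-transformed
linear intensities.

Both members of a pair are crops of one common canvas, offset by the true
``mode_shift``, so they share scene *and* speckle (the two acquisitions image
the same tissue moments apart); per-acquisition noise is available via
``acq_noise_sigma`` but defaults to zero, reflecting 50-frame-averaged scans.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .core import INTERFACES, BScanImage, LayerModel, check_fields

# display transform: D = (2550 / DISPLAY_DB_RANGE) * log10(linear)
DISPLAY_DB_RANGE = 40.0
_LOG_GAIN = 2550.0 / DISPLAY_DB_RANGE

#: bands between consecutive interfaces, top to bottom; EZ and RPE are
#: finite-thickness bands centred on their interface curves.
BAND_NAMES = (
    "vitreous",
    "rnfl",
    "inner_retina",
    "outer_segments",
    "ez",
    "interdigitation",
    "rpe",
    "choroid_stroma",
    "choroid_lumen",
    "sclera",
)

DEFAULT_LAYER_DEPTHS = {
    # interface -> (mean depth µm, waviness amplitude µm)
    "ILM": (100.0, 15.0),
    "RNFL_posterior": (160.0, 15.0),
    "ELM": (600.0, 15.0),
    "EZ_center": (640.0, 15.0),
    "RPE_center": (710.0, 15.0),
    "choroid_anterior": (740.0, 15.0),
    "choroid_scleral": (1040.0, 25.0),
}

DEFAULT_BAND_REFLECTIVITIES = {
    "vitreous": 8.0,
    "rnfl": 120.0,
    "inner_retina": 60.0,
    "outer_segments": 45.0,
    "ez": 170.0,
    "interdigitation": 80.0,
    "rpe": 200.0,
    "choroid_stroma": 140.0,
    "choroid_lumen": 45.0,
    "sclera": 95.0,
}


@dataclass(frozen=True)
class SceneSpec:
    """Complete description of one synthetic eye (both rendering modes).

    Defaults describe a 512×320 px scan at 3.9 µm/px axial and 11 µm/px
    lateral pitch (high-speed raster of a ~5.6 mm line), so the central 3 mm
    region of interest (≈ 273 px) fits centred around ``fovea_x``.
    """

    width_px: int = 512
    height_px: int = 320
    axial_scale: float = 3.9
    lateral_scale: float = 11.0
    fovea_x: int = 256
    layer_depths: dict = field(default_factory=lambda: dict(DEFAULT_LAYER_DEPTHS))
    band_reflectivities: dict = field(
        default_factory=lambda: dict(DEFAULT_BAND_REFLECTIVITIES)
    )
    ez_band_halfwidth_um: float = 10.0
    rpe_band_halfwidth_um: float = 12.0

    # hyperreflective foci
    n_foci: int = 60
    focus_diameter_range: tuple[float, float] = (16.0, 28.0)
    focus_intensity: float = 230.0
    focus_min_separation_um: float = 40.0

    # choroidal vessel lumens
    luminal_fraction: float = 0.70
    lumen_lateral_radius_um: tuple[float, float] = (25.0, 90.0)
    lumen_axial_radius_um: tuple[float, float] = (12.0, 45.0)

    # intraretinal cysts (macular edema)
    n_cysts: int = 0
    cyst_intensity: float = 15.0
    cyst_attenuation: float = 0.8
    cyst_lateral_radius_um: tuple[float, float] = (80.0, 250.0)
    cyst_axial_radius_um: tuple[float, float] = (40.0, 110.0)

    # noise model
    speckle_contrast: float = 0.3
    acq_noise_sigma: float = 0.0

    # EDI vs conventional rendering difference (display-domain gains)
    edi_depth_gain: float = 1.25
    edi_inner_contrast: float = 0.85
    conv_depth_attenuation: float = 0.8

    # EDI-only extra foci (models the empirical macular-edema mode effect)
    edi_extra_foci_count: int = 0

    mode_shift: tuple[int, int] = (0, 0)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.focus_diameter_range
        check_fields(
            self,
            [
                (self.width_px >= 64 and self.height_px >= 64, "width_px/height_px too small"),
                (self.axial_scale > 0 and self.lateral_scale > 0, "axial_scale/lateral_scale must be > 0"),
                (0 <= self.fovea_x < self.width_px, "fovea_x outside image"),
                (0.0 <= self.luminal_fraction <= 1.0, "luminal_fraction must lie in [0, 1]"),
                (all(0.0 <= v <= 255.0 for v in self.band_reflectivities.values()),
                 "band_reflectivities must lie in [0, 255]"),
                (0 < lo <= hi < 30.0, "focus_diameter_range must satisfy 0 < lo <= hi < 30 µm"),
                (self.n_foci >= 0, "n_foci must be >= 0"),
                (self.n_cysts >= 0, "n_cysts must be >= 0"),
                (0.0 < self.cyst_attenuation <= 1.0, "cyst_attenuation must lie in (0, 1]"),
                (self.speckle_contrast >= 0.0, "speckle_contrast must be >= 0"),
                (self.edi_depth_gain >= 1.0, "edi_depth_gain must be >= 1"),
                (0.0 < self.edi_inner_contrast <= 1.0, "edi_inner_contrast must lie in (0, 1]"),
                (0.0 < self.conv_depth_attenuation <= 1.0, "conv_depth_attenuation must lie in (0, 1]"),
            ],
        )
        means = [self.layer_depths[name][0] for name in INTERFACES]
        if not all(a < b for a, b in zip(means, means[1:])):
            raise ValueError("layer_depths mean depths must strictly increase in interface order")
        if means[-1] / self.axial_scale >= self.height_px:
            raise ValueError("choroid_scleral interface deeper than the image")

    @property
    def roi_width_px(self) -> int:
        return int(round(3000.0 / self.lateral_scale))


@dataclass
class GroundTruth:
    """Everything a parameter-recovery test needs, in the EDI frame."""

    layers: LayerModel
    #: injected foci as ``(x µm, z µm, diameter µm)`` (lateral, depth)
    foci: list[tuple[float, float, float]]
    #: foci rendered into the EDI image only (mode-effect injection)
    edi_extra_foci: list[tuple[float, float, float]]
    #: vessel-lumen pixels inside the central-3-mm choroidal ROI
    luminal_mask: np.ndarray
    true_luminal_fraction: float
    true_ezr: float
    edema_present: bool
    mode_shift: tuple[int, int]

    def to_json(self, path: str | Path, luminal_mask_path: str | Path | None = None) -> None:
        payload = {
            "axial_scale_um_per_px": self.layers.axial_scale,
            "lateral_scale_um_per_px": self.layers.lateral_scale,
            "layers_px": {k: v.tolist() for k, v in self.layers.depths.items()},
            "foci_um": [list(f) for f in self.foci],
            "edi_extra_foci_um": [list(f) for f in self.edi_extra_foci],
            "true_luminal_fraction": self.true_luminal_fraction,
            "true_ezr": self.true_ezr,
            "edema_present": self.edema_present,
            "mode_shift": list(self.mode_shift),
            "luminal_mask_png": str(luminal_mask_path) if luminal_mask_path else None,
        }
        Path(path).write_text(json.dumps(payload))
        if luminal_mask_path is not None:
            Image.fromarray(self.luminal_mask).convert("1").save(str(luminal_mask_path))


# ---------------------------------------------------------------------------
# scene construction helpers
# ---------------------------------------------------------------------------


def _waviness(rng: np.random.Generator, width: int) -> np.ndarray:
    """Smooth pseudo-anatomical undulation, normalised to max |w| = 1."""
    x = np.arange(width) / width
    w = np.zeros(width)
    for amp, (flo, fhi) in zip((1.0, 0.5, 0.25), ((0.5, 1.5), (1.5, 3.0), (3.0, 5.0))):
        f = rng.uniform(flo, fhi)
        phase = rng.uniform(0, 2 * np.pi)
        w += amp * rng.uniform(0.8, 1.2) * np.sin(2 * np.pi * f * x + phase)
    return w / np.max(np.abs(w))


def _layer_curves(spec: SceneSpec, w: np.ndarray) -> dict[str, np.ndarray]:
    """Interface depth curves (fractional canvas rows)."""
    curves = {}
    for name in INTERFACES:
        mean_um, amp_um = spec.layer_depths[name]
        curves[name] = (mean_um + amp_um * w) / spec.axial_scale
    return curves


def _stamp_ellipse(mask: np.ndarray, r0: float, c0: float, rr: float, rc: float) -> tuple[slice, slice]:
    """Set ``mask`` True inside an axis-aligned ellipse; returns the window."""
    h, w = mask.shape
    rlo = max(int(np.floor(r0 - rr)), 0)
    rhi = min(int(np.ceil(r0 + rr)) + 1, h)
    clo = max(int(np.floor(c0 - rc)), 0)
    chi = min(int(np.ceil(c0 + rc)) + 1, w)
    if rlo >= rhi or clo >= chi:
        return slice(0, 0), slice(0, 0)
    rows = np.arange(rlo, rhi)[:, None]
    cols = np.arange(clo, chi)[None, :]
    inside = ((rows - r0) / rr) ** 2 + ((cols - c0) / rc) ** 2 <= 1.0
    mask[rlo:rhi, clo:chi] |= inside
    return slice(rlo, rhi), slice(clo, chi)


class SceneBuilder:
    """Builds the shared noiseless canvas for one eye.

    The canvas is larger than the output frame by the magnitude of
    ``mode_shift`` so both mode crops are fully defined.
    """

    def __init__(self, spec: SceneSpec):
        spec.validate()
        self.spec = spec
        dr, dc = spec.mode_shift
        self.edi_origin = (max(dr, 0), max(dc, 0))
        self.conv_origin = (self.edi_origin[0] - dr, self.edi_origin[1] - dc)
        self.canvas_shape = (spec.height_px + abs(dr), spec.width_px + abs(dc))
        ss = np.random.SeedSequence(spec.seed)
        (self._ss_wav, self._ss_lumen, self._ss_cyst, self._ss_foci,
         self._ss_extra, self._ss_speckle, self._ss_acq) = ss.spawn(7)

    # -- geometry ----------------------------------------------------------
    def build(self) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
        """Return (EDI canvas, conventional canvas, ground truth).

        Canvases are float display-domain images *before* speckle.
        """
        spec = self.spec
        hc, wc = self.canvas_shape
        rng_w = np.random.default_rng(self._ss_wav)
        w = _waviness(rng_w, wc)
        curves = _layer_curves(spec, w)

        rows = np.arange(hc, dtype=float)[:, None]
        refl = spec.band_reflectivities
        ez_hw = spec.ez_band_halfwidth_um / spec.axial_scale
        rpe_hw = spec.rpe_band_halfwidth_um / spec.axial_scale
        ez_top = curves["EZ_center"] - ez_hw
        ez_bot = curves["EZ_center"] + ez_hw
        rpe_top = curves["RPE_center"] - rpe_hw
        rpe_bot = curves["RPE_center"] + rpe_hw

        conditions = [
            rows < curves["ILM"],
            rows < curves["RNFL_posterior"],
            rows < curves["ELM"],
            rows < ez_top,
            rows < ez_bot,
            rows < rpe_top,
            rows < rpe_bot,
            rows < curves["choroid_scleral"],
        ]
        values = [
            refl["vitreous"], refl["rnfl"], refl["inner_retina"],
            refl["outer_segments"], refl["ez"], refl["interdigitation"],
            refl["rpe"], refl["choroid_stroma"],
        ]
        scene = np.select(conditions, [np.full((hc, wc), v) for v in values],
                          default=refl["sclera"])

        # choroid band mask (anterior <= depth < scleral interface)
        choroid_band = (rows >= curves["choroid_anterior"]) & (rows < curves["choroid_scleral"])
        lumen_mask = self._pack_lumens(choroid_band, curves)
        scene[lumen_mask] = refl["choroid_lumen"]

        # cysts + sub-cyst attenuation (multiplicative on display values)
        atten = np.ones((hc, wc))
        cysts = self._place_cysts(curves)
        for (r0, c0, rr, rc) in cysts:
            cmask = np.zeros((hc, wc), dtype=bool)
            rsl, csl = _stamp_ellipse(cmask, r0, c0, rr, rc)
            # clip to the retina (cysts are intraretinal)
            band = (rows >= curves["RNFL_posterior"]) & (rows < curves["ELM"])
            cmask &= band
            scene[cmask] = spec.cyst_intensity
            # attenuate everything below the cyst's lower edge, per column
            if cmask.any():
                cols_hit = np.flatnonzero(cmask.any(axis=0))
                bottom = cmask.shape[0] - 1 - np.argmax(cmask[::-1][:, cols_hit], axis=0)
                for col, b in zip(cols_hit, bottom):
                    atten[b + 1:, col] *= spec.cyst_attenuation

        # hyperreflective foci (shared between modes)
        rng_foci = np.random.default_rng(self._ss_foci)
        foci = self._place_foci(rng_foci, curves, spec.n_foci, existing=[])
        self._render_foci(scene, foci)

        scene_atten = scene * atten

        edi = self._render_mode(scene_atten, curves, rows, "EDI")
        conv = self._render_mode(scene_atten, curves, rows, "conventional")

        # EDI-only extra foci: rendered after the mode transform so their
        # contrast is not affected by the inner-retina compression pivot
        # bookkeeping (they model extra *detections*, not extra anatomy).
        rng_extra = np.random.default_rng(self._ss_extra)
        extra = self._place_foci(rng_extra, curves, spec.edi_extra_foci_count,
                                 existing=foci)
        edi = edi.copy()
        self._render_foci(edi, extra)

        gt = self._ground_truth(curves, foci, extra, lumen_mask)
        return edi, conv, gt

    # -- sub-structures ----------------------------------------------------
    def _roi_cols_canvas(self) -> tuple[int, int]:
        spec = self.spec
        w = spec.roi_width_px
        start = spec.fovea_x - w // 2 + self.edi_origin[1]
        return start, start + w

    def _pack_lumens(self, choroid_band: np.ndarray, curves) -> np.ndarray:
        """Pack dark elliptical vessel lumens until the target luminal
        fraction is reached inside the central-3-mm choroidal ROI."""
        spec = self.spec
        rng = np.random.default_rng(self._ss_lumen)
        mask = np.zeros_like(choroid_band)
        if spec.luminal_fraction <= 0:
            return mask
        c0_roi, c1_roi = self._roi_cols_canvas()
        roi_band = choroid_band[:, c0_roi:c1_roi]
        roi_total = int(roi_band.sum())
        if roi_total == 0:
            raise ValueError("zero-thickness choroid: cannot place lumens")
        ant, scl = curves["choroid_anterior"], curves["choroid_scleral"]
        target = spec.luminal_fraction
        frac = 0.0
        for _ in range(4000):
            if frac >= target:
                break
            c = rng.uniform(0, mask.shape[1])
            col = min(int(c), mask.shape[1] - 1)
            r = rng.uniform(ant[col], scl[col])
            rr = rng.uniform(*spec.lumen_axial_radius_um) / spec.axial_scale
            rc = rng.uniform(*spec.lumen_lateral_radius_um) / spec.lateral_scale
            _stamp_ellipse(mask, r, c, rr, rc)
            mask &= choroid_band
            frac = mask[:, c0_roi:c1_roi].sum() / roi_total
        if abs(frac - target) > 0.02:
            raise ValueError(
                f"could not realise luminal_fraction {target:.2f} (got {frac:.3f})"
            )
        return mask

    def _place_cysts(self, curves) -> list[tuple[float, float, float, float]]:
        spec = self.spec
        rng = np.random.default_rng(self._ss_cyst)
        out = []
        c0_roi, c1_roi = self._roi_cols_canvas()
        for _ in range(spec.n_cysts):
            c = rng.uniform(c0_roi + 10, c1_roi - 10)
            col = min(int(c), len(curves["ELM"]) - 1)
            top, bot = curves["RNFL_posterior"][col], curves["ELM"][col]
            r = rng.uniform(top + 0.25 * (bot - top), bot - 0.15 * (bot - top))
            rr = rng.uniform(*spec.cyst_axial_radius_um) / spec.axial_scale
            rc = rng.uniform(*spec.cyst_lateral_radius_um) / spec.lateral_scale
            out.append((r, c, rr, rc))
        return out

    def _place_foci(
        self,
        rng: np.random.Generator,
        curves,
        count: int,
        existing: Sequence[tuple[float, float, float, float, float]],
    ) -> list[tuple[float, float, float, float, float]]:
        """Sequential rejection sampling of focus positions.

        Returns ``(row, col, diameter_um, rr_px, rc_px)`` tuples in canvas
        coordinates.  Sequential acceptance makes the first *k* foci of a
        scene a prefix of the first *k+1* (same seed), which underpins the
        detector-locality property tests.
        """
        spec = self.spec
        placed = list(existing)
        out = []
        c0_roi, c1_roi = self._roi_cols_canvas()
        min_sep = spec.focus_min_separation_um
        for i in range(count):
            for _attempt in range(400):
                d = rng.uniform(*spec.focus_diameter_range)
                rr = (d / 2.0) / spec.axial_scale
                rc = (d / 2.0) / spec.lateral_scale
                c = rng.uniform(c0_roi + rc + 3, c1_roi - rc - 3)
                col = min(int(c), len(curves["ELM"]) - 1)
                top = curves["RNFL_posterior"][col] + rr + 2
                bot = curves["ELM"][col] - rr - 2
                if bot <= top:
                    continue
                r = rng.uniform(top, bot)
                x_um = c * spec.lateral_scale
                z_um = r * spec.axial_scale
                ok = all(
                    np.hypot((p[1] * spec.lateral_scale) - x_um,
                             (p[0] * spec.axial_scale) - z_um) >= min_sep
                    for p in placed
                )
                if ok:
                    placed.append((r, c, d, rr, rc))
                    out.append((r, c, d, rr, rc))
                    break
            else:
                raise ValueError(f"could not place focus {i + 1}/{count}; band too crowded")
        return out

    def _render_foci(self, scene: np.ndarray, foci) -> None:
        """Render foci as Gaussian bumps (σ = radius/1.5), taking the
        pixelwise maximum so foci stay bright inside cysts."""
        spec = self.spec
        h, w = scene.shape
        for (r0, c0, _d, rr, rc) in foci:
            sr, sc = rr / 1.5, rc / 1.5
            rlo, rhi = max(int(r0 - 3 * sr), 0), min(int(r0 + 3 * sr) + 2, h)
            clo, chi = max(int(c0 - 3 * sc), 0), min(int(c0 + 3 * sc) + 2, w)
            rows = np.arange(rlo, rhi)[:, None]
            cols = np.arange(clo, chi)[None, :]
            bump = np.exp(-0.5 * (((rows - r0) / sr) ** 2 + ((cols - c0) / sc) ** 2))
            patch = scene[rlo:rhi, clo:chi]
            np.maximum(patch, patch + (spec.focus_intensity - patch) * bump, out=patch)

    def _render_mode(self, scene: np.ndarray, curves, rows, mode: str) -> np.ndarray:
        """Apply the mode-specific rendering transform (display domain)."""
        spec = self.spec
        out = scene.copy()
        rpe_bot = curves["RPE_center"] + spec.rpe_band_halfwidth_um / spec.axial_scale
        h = scene.shape[0]
        # depth ramp below the RPE band: 0 at the band's lower edge, 1 at the
        # image bottom
        ramp = np.clip((rows - rpe_bot) / np.maximum(h - rpe_bot, 1.0), 0.0, 1.0)
        if mode == "EDI":
            gain = 1.0 + (spec.edi_depth_gain - 1.0) * ramp
            out *= gain
            if spec.edi_inner_contrast < 1.0:
                inner = rows < curves["ELM"]
                pivot = spec.band_reflectivities["inner_retina"]
                out = np.where(inner, pivot + (out - pivot) * spec.edi_inner_contrast, out)
        else:
            gain = 1.0 - (1.0 - spec.conv_depth_attenuation) * ramp
            out *= gain
        return out

    # -- noise & cropping --------------------------------------------------
    def render_pair(self) -> tuple[BScanImage, BScanImage, GroundTruth]:
        spec = self.spec
        edi_canvas, conv_canvas, gt = self.build()
        if spec.speckle_contrast > 0:
            m = 1.0 / spec.speckle_contrast**2
            rng = np.random.default_rng(self._ss_speckle)
            g = rng.gamma(shape=m, scale=1.0 / m, size=self.canvas_shape)
            dd = _LOG_GAIN * np.log10(g)  # display-domain equivalent of the
            edi_canvas = edi_canvas + dd  # linear multiplicative field
            conv_canvas = conv_canvas + dd
            if spec.acq_noise_sigma > 0:
                ss_e, ss_c = self._ss_acq.spawn(2)
                edi_canvas = edi_canvas + np.random.default_rng(ss_e).normal(
                    0, spec.acq_noise_sigma, self.canvas_shape)
                conv_canvas = conv_canvas + np.random.default_rng(ss_c).normal(
                    0, spec.acq_noise_sigma, self.canvas_shape)

        def crop(canvas, origin):
            r0, c0 = origin
            return canvas[r0:r0 + spec.height_px, c0:c0 + spec.width_px]

        def finalize(canvas, mode):
            px = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
            return BScanImage(px, spec.axial_scale, spec.lateral_scale, mode)

        edi = finalize(crop(edi_canvas, self.edi_origin), "EDI")
        conv = finalize(crop(conv_canvas, self.conv_origin), "conventional")
        return edi, conv, gt

    def _ground_truth(self, curves, foci, extra, lumen_mask) -> GroundTruth:
        spec = self.spec
        r0, c0 = self.edi_origin
        depths = {
            name: curves[name][c0:c0 + spec.width_px] - r0 for name in INTERFACES
        }
        layers = LayerModel(depths, spec.axial_scale, spec.lateral_scale)
        layers.validate_order(strict=True)

        def to_um(items):
            return [
                ((c - c0) * spec.lateral_scale, (r - r0) * spec.axial_scale, d)
                for (r, c, d, _rr, _rc) in items
            ]

        # lumen mask restricted to the central-3-mm choroidal ROI, EDI frame
        cc0, cc1 = self._roi_cols_canvas()
        frame_mask = np.zeros((spec.height_px, spec.width_px), dtype=bool)
        crop = lumen_mask[r0:r0 + spec.height_px, c0:c0 + spec.width_px]
        roi_start, roi_stop = cc0 - c0, cc1 - c0
        frame_mask[:, roi_start:roi_stop] = crop[:, roi_start:roi_stop]

        rows = np.arange(spec.height_px, dtype=float)[:, None]
        choroid_roi = (
            (rows >= layers["choroid_anterior"])
            & (rows < layers["choroid_scleral"])
        )
        choroid_roi[:, :roi_start] = False
        choroid_roi[:, roi_stop:] = False
        total = int(choroid_roi.sum())
        true_frac = float(frame_mask.sum() / total) if total else 0.0

        refl = spec.band_reflectivities
        return GroundTruth(
            layers=layers,
            foci=to_um(foci),
            edi_extra_foci=to_um(extra),
            luminal_mask=frame_mask,
            true_luminal_fraction=true_frac,
            true_ezr=float(refl["ez"] / refl["rpe"]),
            edema_present=spec.n_cysts > 0,
            mode_shift=spec.mode_shift,
        )


def generate_pair(spec: SceneSpec) -> tuple[BScanImage, BScanImage, GroundTruth]:
    """Generate one co-located (EDI, conventional) pair with ground truth.

    Identical ``(spec, seed)`` yields bit-identical outputs.
    """
    return SceneBuilder(spec).render_pair()


# ---------------------------------------------------------------------------
# cohort-scale generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModeEffect:
    """Controls the injected EDI-vs-conventional rendering difference for a
    simulated cohort.  ``null()`` renders both modes identically (zero mode
    effect); ``hf_only`` adds EDI-only foci in edema eyes while keeping the
    rendering neutral."""

    edi_depth_gain: float = 1.25
    edi_inner_contrast: float = 0.85
    conv_depth_attenuation: float = 0.8
    extra_foci_me_mean: float = 0.0

    @classmethod
    def null(cls) -> "ModeEffect":
        return cls(1.0, 1.0, 1.0, 0.0)

    @classmethod
    def hf_only(cls, extra_foci_me_mean: float = 12.0) -> "ModeEffect":
        return cls(1.0, 1.0, 1.0, extra_foci_me_mean)


DEFAULT_PARAMETER_RANGES: dict = {
    "n_foci": (20, 120),
    "luminal_fraction": (0.60, 0.65, 0.70, 0.75),
    "ez_ratio": (0.60, 0.95),
    "n_cysts": (1, 4),
    "cyst_attenuation": (0.7, 0.9),
    "mode_shift": 3,
    "snr": (30.5, 35.0),
    "dr_fraction": 27 / 60,
}


@dataclass
class EyeRecordMeta:
    eye_id: str
    diagnosis: str
    edema_present: bool
    snr_edi: float
    snr_conv: float
    fovea_x: int


def render_cohort(
    n_eyes: int,
    edema_probability: float = 34 / 60,
    parameter_ranges: dict | None = None,
    seed: int = 0,
    mode_effect: ModeEffect | None = None,
    base_spec: SceneSpec | None = None,
) -> list[tuple[tuple[BScanImage, BScanImage], GroundTruth, EyeRecordMeta]]:
    """Draw a reproducible cohort of synthetic eyes.

    The number of edema eyes is fixed at ``round(edema_probability * n_eyes)``
    with a randomly permuted assignment, so the study's subgroup sizes are
    deterministic for a given seed.
    """
    if n_eyes < 1:
        raise ValueError("n_eyes must be >= 1")
    ranges = dict(DEFAULT_PARAMETER_RANGES)
    if parameter_ranges:
        ranges.update(parameter_ranges)
    for key in ("n_foci", "ez_ratio", "snr"):
        if not ranges[key]:
            raise ValueError(f"empty parameter range for {key!r}")
    base = base_spec if base_spec is not None else SceneSpec()

    ss = np.random.SeedSequence(seed)
    ss_assign, ss_draw = ss.spawn(2)
    rng = np.random.default_rng(ss_assign)
    n_edema = int(round(edema_probability * n_eyes))
    edema_flags = np.zeros(n_eyes, dtype=bool)
    edema_flags[rng.permutation(n_eyes)[:n_edema]] = True

    draw_rng = np.random.default_rng(ss_draw)
    eye_seeds = draw_rng.integers(0, 2**31 - 1, size=n_eyes)

    out = []
    for i in range(n_eyes):
        erng = np.random.default_rng(eye_seeds[i])
        edema = bool(edema_flags[i])
        refl = dict(base.band_reflectivities)
        ratio = erng.uniform(*ranges["ez_ratio"])
        refl["ez"] = ratio * refl["rpe"]
        shift_r = int(erng.integers(-ranges["mode_shift"], ranges["mode_shift"] + 1))
        shift_c = int(erng.integers(-ranges["mode_shift"], ranges["mode_shift"] + 1))
        n_cysts = int(erng.integers(ranges["n_cysts"][0], ranges["n_cysts"][1] + 1)) if edema else 0
        effect = mode_effect
        overrides = dict(
            band_reflectivities=refl,
            n_foci=int(erng.integers(ranges["n_foci"][0], ranges["n_foci"][1] + 1)),
            luminal_fraction=float(erng.choice(ranges["luminal_fraction"])),
            n_cysts=n_cysts,
            cyst_attenuation=float(erng.uniform(*ranges["cyst_attenuation"])),
            mode_shift=(shift_r, shift_c),
            seed=int(eye_seeds[i]),
        )
        if effect is not None:
            extra = 0
            if edema and effect.extra_foci_me_mean > 0:
                extra = int(erng.poisson(effect.extra_foci_me_mean))
            overrides.update(
                edi_depth_gain=effect.edi_depth_gain,
                edi_inner_contrast=effect.edi_inner_contrast,
                conv_depth_attenuation=effect.conv_depth_attenuation,
                edi_extra_foci_count=extra,
            )
        spec = replace(base, **overrides)
        edi, conv, gt = generate_pair(spec)
        snr_edi = float(erng.uniform(*ranges["snr"]))
        snr_conv = float(erng.uniform(*ranges["snr"]))
        meta = EyeRecordMeta(
            eye_id=f"eye{i:03d}",
            diagnosis="DR" if erng.random() < ranges["dr_fraction"] else "RVO",
            edema_present=edema,
            snr_edi=snr_edi,
            snr_conv=snr_conv,
            fovea_x=base.fovea_x,
        )
        edi = replace(edi, snr_score=snr_edi, id=f"{meta.eye_id}_edi")
        conv = replace(conv, snr_score=snr_conv, id=f"{meta.eye_id}_conv")
        out.append(((edi, conv), gt, meta))
    return out


def write_cohort(records, out_dir: str | Path) -> Path:
    """Write a cohort to disk: TIFF pairs, JSON sidecars, 1-bit PNG lumen
    masks and a CSV manifest.  Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["eye_id", "diagnosis", "edema", "edi_path", "conv_path",
             "layers_path", "snr_edi", "snr_conv", "fovea_x"]
        )
        for (edi, conv), gt, meta in records:
            stem = out_dir / meta.eye_id
            edi.to_tiff(f"{stem}_edi.tiff")
            conv.to_tiff(f"{stem}_conv.tiff")
            gt.layers.to_json(f"{stem}_layers.json")
            gt.to_json(f"{stem}_truth.json", luminal_mask_path=f"{stem}_lumens.png")
            writer.writerow(
                [meta.eye_id, meta.diagnosis, int(meta.edema_present),
                 f"{stem}_edi.tiff", f"{stem}_conv.tiff", f"{stem}_layers.json",
                 f"{meta.snr_edi:.2f}", f"{meta.snr_conv:.2f}", meta.fovea_x]
            )
    return manifest
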