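"""End-to-end orchestration: quantify both modes of every eye and build the
agreement report.

Per-eye order of operations is fixed: register the pair, histogram-match the
conventional scan to the EDI scan using the registered overlap, define all
ROIs on the EDI image, transfer them to the conventional frame, then quantify
hyperreflective foci, EZ reflectivity ratio and choroidal vascularity index
on each mode.  Eyes whose signal-to-noise score is not above 30 (best 35) are
excluded and listed with a reason.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cvi as cvi_mod
from . import ezr as ezr_mod
from . import hf as hf_mod
from .core import BiomarkerTriplet, BScanImage, LayerModel, Registration
from .preprocess import central_roi, match_histogram, register, transfer_roi
from .stats import PairedSample, summarize
from .synth import EyeRecordMeta, GroundTruth

SNR_GATE = 30.0
BIOMARKERS = ("hf", "ezr", "cvi")
SUBGROUPS = ("Overall", "With ME", "Without ME")


@dataclass(frozen=True)
class PipelineConfig:
    search_radius_px: int = 5
    hf_params: hf_mod.HFParams = field(default_factory=hf_mod.HFParams)
    ezr_params: ezr_mod.EZRParams = field(default_factory=ezr_mod.EZRParams)
    cvi_params: cvi_mod.CVIParams = field(default_factory=cvi_mod.CVIParams)
    icc_form: str = "agreement"
    quantile_estimator: str = "harrell-davis"


@dataclass
class CohortRecord:
    """One subject: co-located EDI/conventional pair plus segmentation."""

    eye_id: str
    diagnosis: str
    edema_present: bool
    edi: BScanImage
    conv: BScanImage
    layers: LayerModel  # EDI frame
    fovea_x: int
    ground_truth: GroundTruth | None = None


def record_from_synthetic(pair, gt: GroundTruth, meta: EyeRecordMeta) -> CohortRecord:
    edi, conv = pair
    return CohortRecord(
        eye_id=meta.eye_id,
        diagnosis=meta.diagnosis,
        edema_present=meta.edema_present,
        edi=edi,
        conv=conv,
        layers=gt.layers,
        fovea_x=meta.fovea_x,
        ground_truth=gt,
    )


def snr_exclusion_reason(record: CohortRecord) -> str | None:
    """The study's quality gate: both scans must score above 30 (of 35)."""
    bad = [
        f"{mode} snr={snr:g}"
        for mode, snr in (("EDI", record.edi.snr_score), ("conventional", record.conv.snr_score))
        if snr <= SNR_GATE
    ]
    if bad:
        return "SNR <= 30 (" + ", ".join(bad) + ")"
    return None


def _quantify_single(image, layers, lateral, band, chor, config) -> BiomarkerTriplet:
    foci = hf_mod.detect_foci(image, band, config.hf_params)
    ez = ezr_mod.compute_ezr(image, layers, lateral, config.ezr_params)
    lum = cvi_mod.binarize_choroid(image, chor, config.cvi_params)
    cv = cvi_mod.compute_cvi(lum, chor)
    return BiomarkerTriplet(hf_count=foci.count, ezr=ez.ezr, cvi=cv.cvi)


def quantify_eye(
    record: CohortRecord,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[BiomarkerTriplet, BiomarkerTriplet, Registration]:
    """Quantify one eye in both modes.

    Returns ``(without-EDI triplet, with-EDI triplet, registration)``.
    Raises if the record fails the SNR gate (use :func:`run_cohort` for
    gate-with-reporting behaviour).
    """
    reason = snr_exclusion_reason(record)
    if reason is not None:
        raise ValueError(f"record {record.eye_id!r} excluded: {reason}")

    reg = register(record.edi, record.conv, config.search_radius_px)
    dr, dc = reg.shift
    h, w = record.edi.shape
    # overlap of the two frames under the estimated shift, in each frame
    edi_overlap = np.zeros((h, w), dtype=bool)
    conv_overlap = np.zeros((h, w), dtype=bool)
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    edi_overlap[r0:r1, c0:c1] = True
    conv_overlap[r0 + dr:r1 + dr, c0 + dc:c1 + dc] = True
    conv_matched = match_histogram(
        record.conv, record.edi,
        source_mask=conv_overlap, reference_mask=edi_overlap,
    )

    lateral = central_roi(record.edi, record.fovea_x)
    band = hf_mod.hf_band_mask(record.layers, lateral)
    chor = cvi_mod.choroid_roi(record.layers, lateral)

    lateral_c = transfer_roi(lateral, reg)
    band_c = transfer_roi(band, reg)
    chor_c = transfer_roi(chor, reg)
    layers_c = record.layers.translate(dr, dc)

    with_edi = _quantify_single(record.edi, record.layers, lateral, band, chor, config)
    without_edi = _quantify_single(conv_matched, layers_c, lateral_c, band_c, chor_c, config)
    return without_edi, with_edi, reg


@dataclass
class CohortReport:
    agreement: pd.DataFrame
    differences: pd.DataFrame
    bland_altman: pd.DataFrame
    exclusions: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.agreement.to_csv(out / "agreement.csv", index=False)
        self.differences.to_csv(out / "differences.csv", index=False)
        self.bland_altman.to_csv(out / "bland_altman.csv", index=False)
        self.exclusions.to_csv(out / "exclusions.csv", index=False)


BIOMARKER_TITLES = {
    "hf": "Hyperreflective foci (n)",
    "ezr": "Ellipsoid zone reflectivity ratio (a.u.)",
    "cvi": "Choroidal vascularity index (a.u.)",
}


def run_cohort(
    records: list[CohortRecord],
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> CohortReport:
    """Quantify a cohort and emit the agreement table, per-eye differences
    and Bland–Altman plot data.  Deterministic given records and config."""
    included, excl_rows = [], []
    for rec in records:
        reason = snr_exclusion_reason(rec)
        if reason is None:
            included.append(rec)
        else:
            excl_rows.append({"eye_id": rec.eye_id, "reason": reason})
    if len(included) < 5:
        raise ValueError(f"need at least 5 includable records, got {len(included)}")

    diff_rows = []
    values: dict[str, dict[str, list[float]]] = {
        b: {"without": [], "with": []} for b in BIOMARKERS
    }
    meta_rows = []
    for rec in included:
        without, with_, reg = quantify_eye(rec, config)
        meta_rows.append(
            {"eye_id": rec.eye_id, "diagnosis": rec.diagnosis,
             "edema": rec.edema_present}
        )
        for b in BIOMARKERS:
            v0 = getattr(without, "hf_count" if b == "hf" else b)
            v1 = getattr(with_, "hf_count" if b == "hf" else b)
            values[b]["without"].append(float(v0))
            values[b]["with"].append(float(v1))
            diff_rows.append(
                {"eye_id": rec.eye_id, "biomarker": b, "diagnosis": rec.diagnosis,
                 "edema": rec.edema_present, "without_edi": v0, "with_edi": v1,
                 "difference": float(v1) - float(v0),
                 "pair_mean": (float(v0) + float(v1)) / 2.0}
            )
    labels = pd.DataFrame(meta_rows)
    edema = labels["edema"].to_numpy(dtype=bool)

    agree_rows, ba_rows = [], []
    for b in BIOMARKERS:
        sample = PairedSample(
            np.array(values[b]["without"]), np.array(values[b]["with"]), labels
        )
        for sub_name, mask in (
            ("Overall", np.ones(len(labels), dtype=bool)),
            ("With ME", edema),
            ("Without ME", ~edema),
        ):
            if mask.sum() < 3:
                continue
            s = summarize(
                sample, biomarker=BIOMARKER_TITLES[b], subgroup=sub_name,
                subgroup_mask=mask, icc_form=config.icc_form,
                quantile_estimator=config.quantile_estimator,
            )
            agree_rows.append(
                {"biomarker": s.biomarker, "subgroup": s.subgroup, "n": s.n,
                 "mean_without_edi": round(s.mean_sd_without[0], 6),
                 "sd_without_edi": round(s.mean_sd_without[1], 6),
                 "mean_with_edi": round(s.mean_sd_with[0], 6),
                 "sd_with_edi": round(s.mean_sd_with[1], 6),
                 "mean_difference": round(s.mean_difference, 6),
                 "p_value": round(s.p_value, 6) if np.isfinite(s.p_value) else s.p_value,
                 "test_used": s.test_used,
                 "icc": round(s.icc.icc, 6) if s.icc else np.nan,
                 "icc_ci_lower": round(s.icc.ci_lower, 6) if s.icc else np.nan,
                 "icc_ci_upper": round(s.icc.ci_upper, 6) if s.icc else np.nan,
                 "flags": "; ".join(s.flags)}
            )
            ba_rows.append(
                {"biomarker": b, "subgroup": sub_name, "center": s.loa.center,
                 "loa_lower": s.loa.lower, "loa_upper": s.loa.upper,
                 "method": s.loa.method, "n_outside": s.loa.n_outside}
            )

    report = CohortReport(
        agreement=pd.DataFrame(agree_rows),
        differences=pd.DataFrame(diff_rows),
        bland_altman=pd.DataFrame(ba_rows),
        exclusions=pd.DataFrame(excl_rows, columns=["eye_id", "reason"]),
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def plot_bland_altman(report: CohortReport, biomarker: str, path: str | Path) -> None:
    """Difference-vs-mean plot with LoA lines (one biomarker, overall)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = report.differences[report.differences["biomarker"] == biomarker]
    ba = report.bland_altman
    row = ba[(ba["biomarker"] == biomarker) & (ba["subgroup"] == "Overall")].iloc[0]
    fig, ax = plt.subplots(figsize=(5, 4))
    me = d["edema"].astype(bool)
    ax.scatter(d.loc[me, "pair_mean"], d.loc[me, "difference"],
               facecolors="white", edgecolors="k", label="with ME")
    ax.scatter(d.loc[~me, "pair_mean"], d.loc[~me, "difference"],
               color="tab:blue", label="without ME")
    ax.axhline(row["center"], color="k")
    for y in (row["loa_lower"], row["loa_upper"]):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xlabel("mean of modes")
    ax.set_ylabel("with EDI − without EDI")
    ax.set_title(BIOMARKER_TITLES.get(biomarker, biomarker))
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# manifest I/O (real-data or simulated-on-disk entry point)
# ---------------------------------------------------------------------------


def load_manifest(manifest_path: str | Path) -> list[CohortRecord]:
    """Read a cohort manifest CSV (columns: eye_id, diagnosis, edema,
    edi_path, conv_path, layers_path, snr_edi, snr_conv, fovea_x)."""
    records = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            layers = LayerModel.from_json(row["layers_path"])
            edi = BScanImage.from_tiff(
                row["edi_path"], axial_scale=layers.axial_scale,
                lateral_scale=layers.lateral_scale, mode="EDI",
                snr_score=float(row["snr_edi"]), id=f"{row['eye_id']}_edi",
            )
            conv = BScanImage.from_tiff(
                row["conv_path"], axial_scale=layers.axial_scale,
                lateral_scale=layers.lateral_scale, mode="conventional",
                snr_score=float(row["snr_conv"]), id=f"{row['eye_id']}_conv",
            )
            records.append(
                CohortRecord(
                    eye_id=row["eye_id"], diagnosis=row["diagnosis"],
                    edema_present=bool(int(row["edema"])), edi=edi, conv=conv,
                    layers=layers, fovea_x=int(row["fovea_x"]),
                )
            )
    return records
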