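"""File I/O: calibrated TIFF micrographs, trace/assay CSVs, ROI JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .density import Micrograph
from .fluoro import ROI
from .phantom import GroundTruth
from .teer import ElectroTrace

__all__ = [
    "write_micrograph",
    "read_micrograph",
    "write_ground_truth",
    "read_ground_truth",
    "traces_to_frame",
    "frame_to_traces",
    "read_rois",
]


def write_micrograph(path: str | Path, micro: Micrograph) -> None:
    """Two-channel TIFF with the pixel size in the resolution tags."""
    path = Path(path)
    ppu = 1.0 / micro.pixel_size_um  # pixels per micrometre
    tifffile.imwrite(
        path, micro.channels, photometric="minisblack",
        resolution=(ppu, ppu), resolutionunit="MICROMETER",
        metadata={"axes": "CYX", "PixelSizeUm": micro.pixel_size_um,
                  "SectionId": micro.section_id, "RoiIndex": micro.roi_index},
    )


def read_micrograph(
    path: str | Path, pixel_size_um: float | None = None
) -> Micrograph:
    """Read a two-channel TIFF; pixel size from metadata unless overridden."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim != 3 or data.shape[0] != 2:
        raise ValueError(f"{path} is not a 2-channel (C, Y, X) TIFF")
    px = pixel_size_um if pixel_size_um is not None else meta.get("PixelSizeUm")
    if px is None:
        raise ValueError("pixel size not in metadata; pass pixel_size_um")
    return Micrograph(
        channels=data, pixel_size_um=float(px),
        bit_depth=16 if data.dtype == np.uint16 else 8,
        section_id=str(meta.get("SectionId", path.stem)),
        roi_index=int(meta.get("RoiIndex", 0)),
    )


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    """Sidecar JSON of a phantom's construction truth (mask not stored)."""
    payload = {
        "centerline_length_um": truth.centerline_length_um,
        "in_band_nucleus_count": truth.in_band_nucleus_count,
        "nucleus_areas_um2": truth.nucleus_areas_um2,
        "true_density_per_um": truth.true_density_per_um,
        "placed_centroids": truth.placed_centroids.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def traces_to_frame(traces: list[ElectroTrace]) -> pd.DataFrame:
    """Long-format CSV-ready table of raw chamber readings."""
    rows = []
    for tr in traces:
        for reading in tr.readings:
            row = {
                "chamber_id": tr.chamber_id, "sex": tr.sex,
                "treatment": tr.treatment, "time_min": reading[0],
                "blank_resistance_ohm": tr.blank_resistance_ohm,
                "window_area_cm2": tr.window_area_cm2,
            }
            if len(reading) == 2:
                row["resistance_ohm"] = reading[1]
            else:
                row["potential_mV"], row["current_uA"] = reading[1], reading[2]
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_traces(frame: pd.DataFrame) -> list[ElectroTrace]:
    """Rebuild :class:`ElectroTrace` objects from the long-format table."""
    raw = "potential_mV" in frame.columns
    if not raw and "resistance_ohm" not in frame.columns:
        raise ValueError("need resistance_ohm or potential_mV/current_uA columns")
    traces = []
    for cid, sub in frame.groupby("chamber_id", sort=False):
        sub = sub.sort_values("time_min")
        if raw:
            readings = tuple(
                (float(t), float(v), float(i)) for t, v, i in
                zip(sub["time_min"], sub["potential_mV"], sub["current_uA"])
            )
        else:
            readings = tuple(
                (float(t), float(r)) for t, r in
                zip(sub["time_min"], sub["resistance_ohm"])
            )
        traces.append(ElectroTrace(
            chamber_id=str(cid),
            sex=str(sub["sex"].iloc[0]) if "sex" in sub else "",
            treatment=str(sub["treatment"].iloc[0]) if "treatment" in sub else "",
            readings=readings,
            blank_resistance_ohm=float(sub["blank_resistance_ohm"].iloc[0]),
            window_area_cm2=float(sub["window_area_cm2"].iloc[0]),
        ))
    return traces


def read_rois(path: str | Path, pixel_size_um: float) -> list[ROI]:
    """ROIs from JSON: ``[{"label": ..., "vertices": [[row, col], ...]}]``."""
    data = json.loads(Path(path).read_text())
    return [
        ROI(vertices=tuple((float(r), float(c)) for r, c in item["vertices"]),
            pixel_size_um=pixel_size_um, label=str(item.get("label", i)))
        for i, item in enumerate(data)
    ]
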