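"""File formats: multi-page TIFF stacks with JSON sidecars, CSV tables.

A FLIM stack is stored as a multi-page 16-bit TIFF (page k = time bin k)
next to a JSON sidecar carrying the acquisition configuration and any
simulation metadata.  Tabular outputs are plain CSV with fixed headers
so they join across pipeline stages on ``roi_id`` / ``cell_id``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .acquisition import AcquisitionConfig
from .fitting import FitResult
from .segmentation import CellRecord
from .simulate import FLIMStack, GroundTruth

__all__ = [
    "write_flim_stack",
    "read_flim_stack",
    "write_ground_truth",
    "read_ground_truth",
    "fit_records_frame",
    "write_fit_records",
    "read_fit_records",
    "write_label_image",
    "read_label_image",
]

FIT_CSV_COLUMNS = [
    "roi_id",
    "n_photons",
    "a1",
    "a2",
    "tau_free_ns",
    "tau_bound_ns",
    "tau_mean_ns",
    "chi2_reduced",
    "converged",
]


def write_flim_stack(stack: FLIMStack, tiff_path) -> Path:
    """Write the stack as multi-page uint16 TIFF plus a .json sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.counts.astype(np.uint16), photometric="minisblack")
    sidecar = {"acquisition": stack.acq.to_dict(), "meta": stack.meta}
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return tiff_path


def read_flim_stack(tiff_path) -> FLIMStack:
    tiff_path = Path(tiff_path)
    counts = tifffile.imread(tiff_path)
    sidecar = json.loads(tiff_path.with_suffix(".json").read_text())
    acq = AcquisitionConfig.from_dict(sidecar["acquisition"])
    return FLIMStack(counts, acq, meta=sidecar.get("meta", {}))


def write_ground_truth(gt: GroundTruth, csv_path) -> Path:
    csv_path = Path(csv_path)
    df = gt.table.copy()
    for col in ("cy", "cx", "a1_true", "tau_bound_true", "tau_mean_true"):
        df[col] = df[col].map(lambda v: f"{v:.4f}")
    df.to_csv(csv_path, index=False)
    return csv_path


def read_ground_truth(csv_path) -> GroundTruth:
    return GroundTruth(pd.read_csv(csv_path))


def fit_records_frame(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Flatten fitted CellRecords to the standard per-ROI table."""
    rows = []
    for rec in records:
        f: FitResult = rec.fit
        rows.append(
            {
                "roi_id": rec.cell_id,
                "n_photons": f.n_photons,
                "a1": f.a1,
                "a2": f.a2,
                "tau_free_ns": f.tau_free,
                "tau_bound_ns": f.tau_bound,
                "tau_mean_ns": f.tau_mean,
                "chi2_reduced": f.chi2_reduced,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows, columns=FIT_CSV_COLUMNS)


def write_fit_records(records: Sequence[CellRecord], csv_path) -> Path:
    csv_path = Path(csv_path)
    df = fit_records_frame(records)
    for col in ("a1", "a2", "tau_free_ns", "tau_bound_ns", "tau_mean_ns", "chi2_reduced"):
        df[col] = df[col].map(lambda v: f"{v:.6f}")
    df.to_csv(csv_path, index=False)
    return csv_path


def read_fit_records(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)


def write_label_image(labels: np.ndarray, tiff_path) -> Path:
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, labels.astype(np.uint16), photometric="minisblack")
    return tiff_path


def read_label_image(tiff_path) -> np.ndarray:
    return tifffile.imread(tiff_path).astype(np.int32)
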