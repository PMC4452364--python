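"""Reading and writing the package's on-disk formats.

Volumes travel as NIfTI-1 with mm voxel spacing; ground truth rides in a
JSON sidecar (sphere geometry, nominal TBR, acquisition and reconstruction
parameters, seed); measurement tables are tab-separated text; calibration
models are JSON documents mirroring :class:`~petbtv.calibration.CalibrationModel`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd

from petbtv.calibration import CalibrationModel, records_to_frame
from petbtv.phantom import (
    AcquisitionSpec,
    ImageVolume,
    PhantomSpec,
    ReconSpec,
    SphereSpec,
)
from petbtv.roi import MeasurementRecord


def save_volume(img: ImageVolume, path: str | Path) -> None:
    affine = np.diag(list(img.voxel_size) + [1.0])
    affine[:3, 3] = img.origin
    nib.save(nib.Nifti1Image(img.intensities.astype(np.float32), affine), str(path))


def load_volume(path: str | Path) -> ImageVolume:
    nii = nib.load(str(path))
    affine = nii.affine
    voxel = tuple(float(abs(affine[i, i])) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    return ImageVolume(np.asarray(nii.get_fdata(), dtype=float), voxel, origin)


def save_mask(mask: np.ndarray, like: ImageVolume, path: str | Path) -> None:
    """Write a boolean mask as a 0/1 NIfTI volume aligned with ``like``."""
    save_volume(like.copy_with(mask.astype(float)), path)


def save_truth_sidecar(
    path: str | Path,
    phantom: PhantomSpec,
    acquisition: AcquisitionSpec | None = None,
    recon: ReconSpec | None = None,
) -> None:
    doc = {
        "phantom": {
            "background_activity": phantom.background_activity,
            "tbr_nominal": phantom.tbr_nominal,
            "spheres": [
                {
                    "label": s.label,
                    "center": list(s.center),
                    "internal_diameter": s.internal_diameter,
                }
                for s in phantom.spheres
            ],
        }
    }
    if acquisition is not None:
        doc["acquisition"] = dataclasses.asdict(acquisition)
    if recon is not None:
        doc["recon"] = {
            "transaxial_fwhm": recon.transaxial_fwhm,
            "em_iterations": recon.em_iterations,
            "extras": dict(recon.extras),
        }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_truth_sidecar(
    path: str | Path,
) -> tuple[PhantomSpec, AcquisitionSpec | None, ReconSpec | None]:
    doc = json.loads(Path(path).read_text())
    p = doc["phantom"]
    phantom = PhantomSpec(
        spheres=tuple(
            SphereSpec(tuple(s["center"]), s["internal_diameter"], s["label"])
            for s in p["spheres"]
        ),
        background_activity=p["background_activity"],
        tbr_nominal=p["tbr_nominal"],
    )
    acq = AcquisitionSpec(**doc["acquisition"]) if "acquisition" in doc else None
    recon = ReconSpec(**doc["recon"]) if "recon" in doc else None
    return phantom, acq, recon


def save_records(
    records: Iterable[MeasurementRecord] | pd.DataFrame, path: str | Path
) -> None:
    frame = (
        records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    )
    frame.to_csv(path, sep="\t", index=False)


def load_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_model(model: CalibrationModel, path: str | Path) -> None:
    doc = {
        "scanner_model": model.scanner_model,
        "intercept": model.intercept,
        "coefficients": dict(model.coefficients),
        "selection_order": list(model.selection_order),
        "multiple_r2": model.multiple_r2,
        "adjusted_r2": model.adjusted_r2,
        "standardized_beta": dict(model.standardized_beta),
        "partial_r2": dict(model.partial_r2),
        "residual_sd": model.residual_sd,
        "shrinkage": model.shrinkage,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path: str | Path) -> CalibrationModel:
    doc = json.loads(Path(path).read_text())
    doc["selection_order"] = tuple(doc["selection_order"])
    return CalibrationModel(**doc)
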