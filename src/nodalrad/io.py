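"""Reading cohorts from disk: NIfTI volume/mask pairs plus a CSV manifest."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ManifestValidationError
from .preprocessing import ImageVolume

MANIFEST_COLUMNS = ["node_id", "patient_id", "label", "image_path", "mask_path"]


def read_nifti(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(np.asarray(img.dataobj, dtype=float), spacing, origin)


@dataclass
class NodeRecord:
    """Lazily loading handle on one manifest row."""

    node_id: str
    patient_id: str
    label: int
    image_path: Path
    mask_path: Path

    def load(self) -> tuple[ImageVolume, np.ndarray]:
        image = read_nifti(self.image_path)
        mask = read_nifti(self.mask_path).voxels.astype(bool)
        return image, mask


@dataclass
class CohortHandle:
    manifest_path: Path
    records: list[NodeRecord]

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)


def load_manifest(path: str | Path) -> CohortHandle:
    """Parse a manifest CSV into lazy node records (no image validation)."""
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ManifestValidationError(f"manifest missing columns: {missing}")
    base = path.parent
    records = []
    for _, row in table.iterrows():
        records.append(
            NodeRecord(
                node_id=str(row["node_id"]),
                patient_id=str(row["patient_id"]),
                label=int(row["label"]),
                image_path=base / str(row["image_path"]),
                mask_path=base / str(row["mask_path"]),
            )
        )
    return CohortHandle(manifest_path=path, records=records)


def validate_manifest(path: str | Path) -> CohortHandle:
    """Fully validate a manifest: files exist, masks nonempty, grids agree,
    labels binary.  Violations name the offending row/node."""
    handle = load_manifest(path)
    for i, rec in enumerate(handle.records):
        row = i + 2  # 1-based, after header
        if rec.label not in (0, 1):
            raise ManifestValidationError(
                f"row {row} (node {rec.node_id}): label {rec.label} not in {{0,1}}"
            )
        for p in (rec.image_path, rec.mask_path):
            if not p.exists():
                raise ManifestValidationError(
                    f"row {row} (node {rec.node_id}): missing file {p}"
                )
        image, mask = rec.load()
        if mask.shape != image.voxels.shape:
            raise ManifestValidationError(
                f"row {row} (node {rec.node_id}): image/mask grid mismatch"
            )
        if not mask.any():
            raise ManifestValidationError(
                f"row {row} (node {rec.node_id}): empty segmentation mask"
            )
    return handle
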