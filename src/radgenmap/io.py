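"""File-format helpers: NIfTI volumes/masks, TSV tables, BED segments."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .radiomics import BinaryMask, ImageVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_feature_table",
    "write_feature_table",
    "write_bed",
    "read_cytoband_bed",
]


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def write_volume(v: ImageVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(v.grid.astype(np.float32), _affine(v.spacing_mm)), str(path))


def read_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(np.asarray(img.dataobj, dtype=float), spacing)


def write_mask(m: BinaryMask, path: str | Path, spacing_mm=(1.0, 1.0, 1.0)) -> None:
    nib.save(nib.Nifti1Image(m.grid.astype(np.uint8), _affine(spacing_mm)), str(path))


def read_mask(path: str | Path) -> BinaryMask:
    img = nib.load(str(path))
    return BinaryMask(np.asarray(img.dataobj).astype(np.uint8))


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=True, index_label="patient_id")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="patient_id")


def write_bed(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, header=False)


def read_cytoband_bed(path: str | Path):
    """Cytoband fixture file: chrom, start, end, name (BED-like)."""
    from .synthetic import CytobandDef

    frame = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name"]
    )
    return [
        CytobandDef(r["name"], r["chrom"], int(r["start"]), int(r["end"]))
        for _, r in frame.iterrows()
    ]
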