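"""File formats: NIfTI volumes, TSV tables, HDF5 connectivity bundles.

Conventions: motion TSVs carry the six rigid-body columns with translations
in mm and rotations in radians; censor TSVs store (frame, fd_mm, keep);
connectivity bundles are one HDF5 file per subject per stream.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import ParcellationAtlas
from .connectivity import ConnectivityResult
from .preprocess import MOTION_COLUMNS, BoldRun, CensorMask, MotionParams

MOTION_HEADER = "# translations (trans_*) in mm; rotations (rot_*) in radians"


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------
def save_bold(run: BoldRun, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(run.data), run.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], run.tr_seconds))
    nib.save(img, path)
    return path


def load_bold(path, tr_seconds: float | None = None, run_id: str = "run-1",
              subject_id: str = "sub-01") -> BoldRun:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 0.8
    return BoldRun(
        data=data,
        tr_seconds=tr_seconds,
        run_id=run_id,
        subject_id=subject_id,
        affine=np.asarray(img.affine),
    )


def save_labels(labels: np.ndarray, affine: np.ndarray, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int32), affine), path)
    return path


def load_labels(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()).astype(np.int32), np.asarray(img.affine)


def assert_same_space(affine_a: np.ndarray, affine_b: np.ndarray, what: str = "volumes") -> None:
    if not np.allclose(affine_a, affine_b, atol=1e-6):
        raise ValueError(
            f"spatial mismatch between {what}: affines differ\n{affine_a}\nvs\n{affine_b}"
        )


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------
def save_motion(motion: MotionParams, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(MOTION_HEADER + "\n")
        motion.to_frame().to_csv(fh, sep="\t", index=False)
    return path


def load_motion(path) -> MotionParams:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"motion TSV {path} missing columns {missing}; expected {list(MOTION_COLUMNS)}"
        )
    return MotionParams(params=df[list(MOTION_COLUMNS)].to_numpy(float))


def save_censor(mask: CensorMask, path) -> Path:
    path = Path(path)
    mask.to_frame().to_csv(path, sep="\t", index=False)
    return path


def load_censor(path, threshold_mm: float = 0.2) -> CensorMask:
    df = pd.read_csv(path, sep="\t")
    mask = CensorMask(
        keep=df["keep"].to_numpy().astype(bool),
        fd_mm=df["fd_mm"].to_numpy(float),
        threshold_mm=threshold_mm,
        usable=False,
    )
    return mask


def save_parcel_table(atlas: ParcellationAtlas, path) -> Path:
    path = Path(path)
    atlas.roi_table.to_csv(path, sep="\t", index=False)
    return path


def load_parcel_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def validate_atlas_files(labels: np.ndarray, table: pd.DataFrame) -> None:
    """Cross-check a label volume against its ROI table."""
    labelled = np.unique(labels)
    labelled = labelled[labelled > 0]
    missing = np.setdiff1d(labelled, table["id"].to_numpy())
    if missing.size:
        raise ValueError(
            f"label volume ids missing from parcel table: {missing.tolist()}"
        )


# ---------------------------------------------------------------------------
# connectivity bundles (HDF5)
# ---------------------------------------------------------------------------
def save_connectivity(result: ConnectivityResult, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["subject_id"] = result.subject_id
        f.attrs["stream"] = result.stream
        f.attrs["n_motion_free"] = result.n_motion_free
        f.create_dataset("roi_ids", data=result.roi_ids)
        f.create_dataset("zmat", data=result.zmat)
        f.create_dataset("network_ts", data=result.network_ts)
        f.create_dataset("between_z", data=result.between_z)
        f.create_dataset("within_mean", data=result.within_mean)
        f.attrs["networks"] = json.dumps(list(result.networks))
        homo = result.homotopic.reset_index()
        f.create_dataset("homotopic_left_id", data=homo["left_id"].to_numpy())
        f.create_dataset("homotopic_right_id", data=homo["right_id"].to_numpy())
        f.create_dataset("homotopic_z", data=homo["z"].to_numpy())
        f.create_dataset("net_to_roi", data=result.net_to_roi.to_numpy())
    return path


def load_connectivity(path) -> ConnectivityResult:
    with h5py.File(path, "r") as f:
        networks = json.loads(f.attrs["networks"])
        roi_ids = f["roi_ids"][()]
        homo = pd.DataFrame(
            {
                "left_id": f["homotopic_left_id"][()],
                "right_id": f["homotopic_right_id"][()],
                "z": f["homotopic_z"][()],
            }
        ).set_index("left_id")
        net_to_roi = pd.DataFrame(
            f["net_to_roi"][()], columns=networks, index=pd.Index(roi_ids, name="roi_id")
        )
        return ConnectivityResult(
            subject_id=str(f.attrs["subject_id"]),
            stream=str(f.attrs["stream"]),
            roi_ids=roi_ids,
            zmat=f["zmat"][()],
            networks=networks,
            network_ts=f["network_ts"][()],
            between_z=f["between_z"][()],
            within_mean=f["within_mean"][()],
            homotopic=homo,
            net_to_roi=net_to_roi,
            n_motion_free=int(f.attrs["n_motion_free"]),
        )
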