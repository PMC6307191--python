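"""BOLD preprocessing: motion censoring, confound extraction, nuisance regression.

Inputs are assumed already motion-realigned and resampled to a common space;
this module consumes the realignment parameters, it does not estimate them.
The cleaning model per voxel is a single ordinary-least-squares fit removing
an intercept, six rigid-body motion parameters, eroded white-matter and CSF
mean signals, a facial soft-tissue signal, optionally the global (whole-brain
mean) signal, and a discrete-cosine basis spanning all frequencies outside
the 0.001-0.1 Hz connectivity band.  Frames adjacent to supra-threshold head
motion (framewise displacement > 0.2 mm) are flagged for removal downstream;
a subject is usable when at least 200 motion-free volumes survive across the
concatenated runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.ndimage
import scipy.signal

#: Motion parameter column order used in TSV files.  Translations are in mm,
#: rotations in radians (converted to mm at ``head_radius_mm`` for FD).
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

DEFAULT_FD_THRESHOLD_MM = 0.2
DEFAULT_MIN_VOLUMES = 200
DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_BAND_HZ = (0.001, 0.1)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class BoldRun:
    """One 4-D BOLD run (x, y, z, frame) with its repetition time."""

    data: np.ndarray
    tr_seconds: float
    run_id: str = "run-1"
    subject_id: str = "sub-01"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD run needs at least 2 frames")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclass
class MotionParams:
    """Per-frame rigid-body realignment parameters (n_frames x 6)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion parameters must be (n, 6), got {self.params.shape}")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.params, columns=list(MOTION_COLUMNS))


@dataclass
class CensorMask:
    """Keep/drop flags for one run, derived from framewise displacement."""

    keep: np.ndarray
    fd_mm: np.ndarray
    threshold_mm: float
    usable: bool

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        self.fd_mm = np.asarray(self.fd_mm, dtype=float)
        if self.keep.shape != self.fd_mm.shape:
            raise ValueError("keep and fd_mm must have the same length")

    @property
    def n_motion_free(self) -> int:
        return int(self.keep.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.keep.size),
                "fd_mm": self.fd_mm,
                "keep": self.keep.astype(int),
            }
        )


@dataclass
class ErodedMask:
    """Result of one-voxel erosion; ``empty`` flags a vanished mask."""

    mask: np.ndarray
    empty: bool


@dataclass
class ConfoundMatrix:
    """Frame x regressor nuisance matrix with named, centred columns."""

    values: np.ndarray
    names: list[str]
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("confound values/names mismatch")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)


@dataclass
class PreprocessedSubject:
    """Cleaned runs + per-run censor masks + the subject usability decision."""

    runs: list
    censor_masks: list
    usable: bool
    n_motion_free: int
    log: dict


# ---------------------------------------------------------------------------
# framewise displacement and censoring
# ---------------------------------------------------------------------------
def compute_framewise_displacement(
    motion: MotionParams | np.ndarray, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Power-style framewise displacement in mm.

    FD(t) = sum of absolute frame-to-frame differences of the 3 translations
    (mm) plus ``head_radius_mm`` times those of the 3 rotations (radians).
    FD(0) = 0 by convention: displacement is a property of transitions.
    """
    params = motion.params if isinstance(motion, MotionParams) else np.asarray(motion, float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion must be (n_frames, 6)")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    if not np.all(np.isfinite(params)):
        raise ValueError("motion parameters contain non-finite values")
    diffs = np.abs(np.diff(params, axis=0))
    fd = diffs[:, :3].sum(axis=1) + head_radius_mm * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def build_censor_mask(
    fd: np.ndarray,
    threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    min_volumes: int = DEFAULT_MIN_VOLUMES,
) -> CensorMask:
    """Flag frames adjacent to supra-threshold motion.

    FD(t) measures the transition between frames t-1 and t, so an excursion
    FD(t) > threshold drops both frames on either side of the motion event:
    t-1 and t.  The ``usable`` flag on a single run reflects ``min_volumes``
    for that run alone; subject-level usability over concatenated runs is
    decided by :func:`preprocess_subject`.
    """
    if threshold_mm <= 0:
        raise ValueError("threshold_mm must be positive")
    fd = np.asarray(fd, dtype=float)
    keep = np.ones(fd.size, dtype=bool)
    viol = np.flatnonzero(fd > threshold_mm)
    viol = viol[viol > 0]  # FD(0) is 0 by convention and has no preceding frame
    keep[viol] = False
    keep[viol - 1] = False
    mask = CensorMask(keep=keep, fd_mm=fd, threshold_mm=threshold_mm, usable=False)
    mask.usable = mask.n_motion_free >= min_volumes
    return mask


# ---------------------------------------------------------------------------
# masks and confounds
# ---------------------------------------------------------------------------
_FACE_STRUCTURE = scipy.ndimage.generate_binary_structure(3, 1)  # 6-neighbourhood


def erode_mask(mask: np.ndarray) -> ErodedMask:
    """One-voxel erosion: keep voxels whose full 6-neighbourhood is inside.

    Voxels on the array border are removed (the outside counts as background),
    so only voxels at least one voxel removed from the mask boundary survive.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    if not mask.any():
        raise ValueError("cannot erode an empty mask")
    eroded = scipy.ndimage.binary_erosion(mask, structure=_FACE_STRUCTURE, border_value=0)
    return ErodedMask(mask=eroded, empty=not eroded.any())


def _mean_series(data4d: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return data4d[mask, :].mean(axis=0)


def extract_confounds(
    run: BoldRun,
    masks: dict,
    motion: MotionParams,
    use_gsr: bool = False,
) -> ConfoundMatrix:
    """Assemble the nuisance matrix for one run.

    ``masks`` must provide ``wm``, ``csf``, ``face`` and ``brain`` binary
    volumes.  WM and CSF means are taken over one-voxel-eroded masks (an
    explicit error is raised if erosion eliminates one); the facial
    soft-tissue mean uses its mask unchanged; with ``use_gsr`` the mean over
    all in-brain voxels is appended.  All columns are centred.
    """
    if motion.n_frames != run.n_frames:
        raise ValueError(
            f"motion has {motion.n_frames} frames but run has {run.n_frames}"
        )
    columns: dict[str, np.ndarray] = {}
    for i, name in enumerate(MOTION_COLUMNS):
        columns[f"motion_{i + 1}"] = motion.params[:, i]
    for tissue in ("wm", "csf"):
        eroded = erode_mask(masks[tissue])
        if eroded.empty:
            raise ValueError(
                f"erosion eliminated the {tissue} mask; "
                "provide a mask at least 3 voxels thick"
            )
        columns[tissue] = _mean_series(run.data, eroded.mask)
    columns["face"] = _mean_series(run.data, np.asarray(masks["face"]).astype(bool))
    if use_gsr:
        columns["global"] = _mean_series(run.data, np.asarray(masks["brain"]).astype(bool))
    values = np.column_stack([v - np.mean(v) for v in columns.values()])
    return ConfoundMatrix(
        values=values,
        names=list(columns.keys()),
        normalization={"centered": True, "use_gsr": bool(use_gsr)},
    )


# ---------------------------------------------------------------------------
# nuisance regression + bandpass
# ---------------------------------------------------------------------------
def dct_basis_outside_band(
    n_frames: int, tr_seconds: float, band_hz: tuple[float, float] = DEFAULT_BAND_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete-cosine columns whose frequencies fall outside the pass band.

    Column k of the full DCT-II basis oscillates at f_k = k / (2 N TR).
    Returns (basis, frequencies) for 1 <= k <= N-1 with f_k outside
    [band_hz[0], band_hz[1]]; regressing these out implements the bandpass
    inside the same linear fit as the nuisance regression.
    """
    lo, hi = band_hz
    nyquist = 0.5 / tr_seconds
    if not (0 <= lo < hi <= nyquist):
        raise ValueError(f"band {band_hz} must lie within (0, Nyquist={nyquist:g})")
    k = np.arange(1, n_frames)
    freqs = k / (2.0 * n_frames * tr_seconds)
    out = (freqs < lo) | (freqs > hi)
    k = k[out]
    t = np.arange(n_frames)
    basis = np.cos(np.pi * np.outer(2 * t + 1, k) / (2.0 * n_frames))
    # unit-norm columns keep the design well scaled
    basis /= np.linalg.norm(basis, axis=0, keepdims=True)
    return basis, freqs[out]


def _name_collinear_columns(X: np.ndarray, names: list[str], rank: int) -> list[str]:
    _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    return [names[j] for j in sorted(piv[rank:])]


def regress_and_filter(
    run: BoldRun,
    confounds: ConfoundMatrix,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    mode: str = "dct",
    voxel_mask: np.ndarray | None = None,
) -> BoldRun:
    """Remove confounds and out-of-band frequency content in one OLS fit.

    Per voxel, ordinary least squares removes an intercept, every confound
    column and (``mode='dct'``) a discrete-cosine basis spanning all
    frequencies outside ``band_hz``; the residuals are returned.  Residuals
    are orthogonal to every regressor up to numerical precision.

    ``mode='butterworth'`` instead follows the regression (intercept +
    confounds only) with a zero-phase 2nd-order Butterworth bandpass; kept
    for comparison, it does not guarantee exact orthogonality.

    ``voxel_mask`` restricts the fit to a subset of voxels (others are
    zeroed), which is purely a speed optimisation.
    """
    T = run.n_frames
    if confounds.n_frames != T:
        raise ValueError(f"confounds have {confounds.n_frames} rows, run has {T} frames")
    if mode not in ("dct", "butterworth"):
        raise ValueError(f"unknown filter mode {mode!r}")

    # all-zero columns (e.g. motion parameters of a perfectly still subject)
    # cannot influence the fit; drop them instead of failing the rank check
    live = ~np.all(confounds.values == 0, axis=0)
    if not live.all():
        dropped = [n for n, keep in zip(confounds.names, live) if not keep]
        warnings.warn(f"dropping all-zero confound columns: {dropped}")
    names = ["intercept"] + [n for n, keep in zip(confounds.names, live) if keep]
    parts = [np.ones((T, 1)), confounds.values[:, live]]
    if mode == "dct":
        basis, freqs = dct_basis_outside_band(T, run.tr_seconds, band_hz)
        parts.append(basis)
        names += [f"dct_{f:.5f}Hz" for f in freqs]
    X = np.column_stack(parts)

    shape = run.data.shape
    if voxel_mask is not None:
        voxel_mask = np.asarray(voxel_mask, dtype=bool)
        Y = run.data[voxel_mask, :].T
    else:
        Y = run.data.reshape(-1, T).T

    # residuals via economic QR: exactly orthogonal to the design columns
    Q, Rm = scipy.linalg.qr(X, mode="economic")
    diag = np.abs(np.diag(Rm))
    if diag.min() <= 1e-10 * diag.max():
        rank = int(np.sum(diag > 1e-10 * diag.max()))
        bad = _name_collinear_columns(X, names, rank)
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    resid = Y - Q @ (Q.T @ Y)

    if mode == "butterworth":
        lo, hi = band_hz
        sos = scipy.signal.butter(
            2, [lo, hi], btype="bandpass", fs=1.0 / run.tr_seconds, output="sos"
        )
        resid = scipy.signal.sosfiltfilt(sos, resid, axis=0)

    if voxel_mask is not None:
        cleaned = np.zeros(shape)
        cleaned[voxel_mask, :] = resid.T
    else:
        cleaned = resid.T.reshape(shape)
    return BoldRun(
        data=cleaned,
        tr_seconds=run.tr_seconds,
        run_id=run.run_id,
        subject_id=run.subject_id,
        affine=run.affine,
    )


# ---------------------------------------------------------------------------
# subject-level driver
# ---------------------------------------------------------------------------
def preprocess_subject(
    runs: list,
    motion: list,
    masks: dict,
    use_gsr: bool = False,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    min_volumes: int = DEFAULT_MIN_VOLUMES,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
    filter_mode: str = "dct",
    voxel_mask: np.ndarray | None = None,
) -> PreprocessedSubject:
    """Run FD -> confounds -> regression+filter -> censoring for one subject.

    Censored frames are *flagged*, not deleted: regression and filtering see
    the full time series and the censor mask is applied at time-series
    extraction.  The subject is usable when the kept frames summed over all
    runs reach ``min_volumes``.
    """
    if len(runs) != len(motion):
        raise ValueError("runs and motion lists differ in length")
    cleaned, censors, run_logs = [], [], []
    for run, mot in zip(runs, motion):
        try:
            fd = compute_framewise_displacement(mot, head_radius_mm)
            cmask = build_censor_mask(fd, fd_threshold_mm, min_volumes)
            conf = extract_confounds(run, masks, mot, use_gsr=use_gsr)
            clean = regress_and_filter(
                run, conf, band_hz=band_hz, mode=filter_mode, voxel_mask=voxel_mask
            )
        except Exception as exc:
            raise RuntimeError(
                f"preprocessing failed for subject {run.subject_id!r} "
                f"run {run.run_id!r}: {exc}"
            ) from exc
        cleaned.append(clean)
        censors.append(cmask)
        run_logs.append(
            {
                "run_id": run.run_id,
                "n_frames": run.n_frames,
                "n_kept": cmask.n_motion_free,
                "mean_fd_mm": float(fd.mean()),
                "n_confounds": len(conf.names),
            }
        )
    total_kept = int(sum(c.n_motion_free for c in censors))
    usable = total_kept >= min_volumes
    for c in censors:  # subject-level decision overrides per-run flags
        c.usable = usable
    log = {
        "subject_id": runs[0].subject_id if runs else "",
        "use_gsr": bool(use_gsr),
        "fd_threshold_mm": fd_threshold_mm,
        "min_volumes": min_volumes,
        "n_motion_free": total_kept,
        "usable": usable,
        "runs": run_logs,
    }
    return PreprocessedSubject(
        runs=cleaned,
        censor_masks=censors,
        usable=usable,
        n_motion_free=total_kept,
        log=log,
    )
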