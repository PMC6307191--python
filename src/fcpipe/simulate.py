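"""Synthetic BOLD cohort generator with known ground truth.

Emulates the data structure of a three-group developmental cohort study
(LVCP: autism with low verbal/cognitive performance, IQ <= 79; HVCP: autism
with IQ >= 80; NT: neurotypical): two ~8.5-minute runs at TR = 800 ms,
block-structured network covariance across a mirror-symmetric cortical
parcellation, extra homotopic coupling for left-right mirror pairs, a shared
global-signal component, tissue confound signals (WM / CSF / facial soft
tissue), and group-dependent motion-spike rates.  Every generated quantity
(covariances, spike frames, global and confound series) is recorded in a
truth manifest so downstream stages can be tested for parameter recovery.

The signal model is a zero-mean multivariate normal over ROIs, temporally
coloured by a low-pass kernel so that power lies mainly below 0.1 Hz.  Units
are arbitrary (z-scale): only correlations matter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import NETWORKS_8, ParcellationAtlas
from .preprocess import BoldRun, MotionParams, compute_framewise_displacement

GROUPS = ("LVCP", "HVCP", "NT")

#: Cohort demographics: group sizes, age and composite-IQ means/SDs with
#: truncation ranges, and male fraction, matching the study sample
#: (n = 17 / 20 / 19; LVCP IQ 54 +/- 17.5 in [25, 77]; HVCP 106.9 +/- 13.6 in
#: [85, 130]; NT 111.8 +/- 13.1 in [85, 134]; ages 7-17).
GROUP_DEMOGRAPHICS: dict[str, dict] = {
    "LVCP": dict(n=17, age=(12.26, 3.34), iq=(54.0, 17.5), iq_range=(25.0, 77.0), male_frac=14 / 17),
    "HVCP": dict(n=20, age=(12.64, 2.87), iq=(106.85, 13.64), iq_range=(85.0, 130.0), male_frac=15 / 20),
    "NT": dict(n=19, age=(11.76, 2.61), iq=(111.76, 13.05), iq_range=(85.0, 134.0), male_frac=14 / 19),
}
AGE_RANGE = (7.0, 17.0)

#: Per-frame motion-spike rates chosen so expected motion-free volumes
#: reproduce the observed group ordering (LVCP ~630 < HVCP ~854 < NT ~884
#: out of 1240): each spike censors ~3 frames, retained fraction
#: ~ exp(-3 * rate).
DEFAULT_SPIKE_RATES: dict[str, float] = {"LVCP": 0.224, "HVCP": 0.124, "NT": 0.115}

#: Planted group effects reproducing the qualitative finding pattern at a
#: detectable effect size: LVCP within-network coupling reduced by 0.15 z in
#: default / salience / auditory / frontoparietal, and default <-> dorsal
#: attention between-network coupling raised by 0.15 z relative to NT.
#: HVCP shares the NT baseline.
DEFAULT_GROUP_EFFECTS: dict[str, dict] = {
    "LVCP": {
        "within_z_delta": {
            "default": -0.15,
            "salience": -0.15,
            "auditory": -0.15,
            "frontoparietal": -0.15,
        },
        "between_z_delta": {("default", "dorsal attention"): 0.15},
        "homotopic_z_delta": -0.10,
    }
}


# ---------------------------------------------------------------------------
# parameters and phenotypes
# ---------------------------------------------------------------------------
@dataclass
class SimParams:
    """All knobs of the generator; defaults are the study conditions.

    Amplitudes are fractions of the unit ROI-signal standard deviation.
    ``spike_rate`` is the expected number of supra-threshold motion events
    per frame, per group.  ``subject_sd`` is the between-subject SD of every
    coupling parameter on the Fisher-z scale.  ``iq_conn_slope`` > 0 plants
    connectivity that decreases with IQ (z offset of ``-slope`` per within-
    group SD of IQ) in the groups listed in ``iq_conn_groups``.
    """

    grid_shape: tuple[int, int, int] = (16, 18, 12)
    n_rois_per_hemisphere: int = 16
    network_labels: tuple[str, ...] = NETWORKS_8
    tr_seconds: float = 0.8
    n_frames_per_run: int = 620
    n_runs: int = 2
    within_z: dict[str, float] | float = 0.35
    between_z: np.ndarray | float = 0.0
    homotopic_z: float = 0.25
    global_amp: float = 0.5
    confound_amp: float = 0.15
    drift_mm: float = 0.05
    spike_rate: dict[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_SPIKE_RATES)
    )
    spike_dispersion: float = 3.0
    spike_fd_mm: float = 0.6
    noise_sd: float = 0.5
    subject_sd: float = 0.06
    iq_conn_slope: float = 0.0
    iq_conn_groups: tuple[str, ...] = ("LVCP",)
    voxel_size_mm: float = 3.0
    lowpass_hz: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny, nz = self.grid_shape
        if nx % 2 != 0:
            raise ValueError("grid first axis must be even so a mid-sagittal plane exists")
        if len(self.network_labels) != 8:
            raise ValueError("exactly 8 network labels are required")
        for name, value in [
            ("global_amp", self.global_amp),
            ("confound_amp", self.confound_amp),
            ("noise_sd", self.noise_sd),
            ("drift_mm", self.drift_mm),
            ("spike_fd_mm", self.spike_fd_mm),
            ("subject_sd", self.subject_sd),
        ]:
            if value < 0:
                raise ValueError(f"{name} must be non-negative")
        rates = self.spike_rate.values() if isinstance(self.spike_rate, dict) else [self.spike_rate]
        if any(r < 0 for r in rates):
            raise ValueError("spike rates must be non-negative")
        bz = self.between_z
        if isinstance(bz, np.ndarray):
            if bz.shape != (8, 8) or not np.allclose(bz, bz.T):
                raise ValueError("between_z must be a symmetric 8x8 array")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    # -- parameter views -------------------------------------------------
    def within_z_map(self) -> dict[str, float]:
        if isinstance(self.within_z, dict):
            return {n: float(self.within_z.get(n, 0.0)) for n in self.network_labels}
        return {n: float(self.within_z) for n in self.network_labels}

    def between_z_matrix(self) -> np.ndarray:
        if isinstance(self.between_z, np.ndarray):
            return self.between_z.astype(float)
        return np.full((8, 8), float(self.between_z))

    def spike_rate_for(self, group: str) -> float:
        if isinstance(self.spike_rate, dict):
            if group not in self.spike_rate:
                raise KeyError(f"no spike rate defined for group {group!r}")
            return float(self.spike_rate[group])
        return float(self.spike_rate)

    @property
    def run_minutes(self) -> float:
        return self.n_frames_per_run * self.tr_seconds / 60.0


@dataclass
class SubjectPhenotype:
    subject_id: str
    group: str
    age_years: float
    sex: str  # "M" or "F"
    iq_composite: float
    iq_verbal: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.group == "LVCP" and self.iq_composite > 79:
            raise ValueError("LVCP requires composite IQ <= 79")
        if self.group in ("HVCP", "NT") and self.iq_composite < 80:
            raise ValueError(f"{self.group} requires composite IQ >= 80")


@dataclass
class SyntheticSubject:
    """Generated runs + motion + masks + the ground truth that made them."""

    phenotype: SubjectPhenotype
    runs: list
    motion: list
    masks: dict
    truth: dict


@dataclass
class CovarianceSpec:
    """ROI covariance (unit diagonal) plus positive-definiteness bookkeeping."""

    matrix: np.ndarray
    repaired: bool = False
    repair_magnitude: float = 0.0


@dataclass
class Cohort:
    subjects: list
    atlas: ParcellationAtlas
    params: SimParams
    truth: dict

    def phenotype_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            p = s.phenotype
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "group": p.group,
                    "age_years": p.age_years,
                    "sex": p.sex,
                    "iq_composite": p.iq_composite,
                    "iq_verbal": p.iq_verbal,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geometry: parcellation and tissue masks
# ---------------------------------------------------------------------------
def grid_affine(grid_shape: tuple[int, int, int], voxel_size_mm: float) -> np.ndarray:
    """Voxel-to-world affine with x = 0 exactly between the two middle slices."""
    nx, ny, nz = grid_shape
    v = float(voxel_size_mm)
    affine = np.diag([v, v, v, 1.0])
    affine[:3, 3] = [-(nx / 2 - 0.5) * v, -(ny - 1) / 2 * v, -(nz - 1) / 2 * v]
    return affine


def _mask_regions(grid_shape: tuple[int, int, int]) -> dict:
    """Partition the grid: posterior WM/CSF slab, anterior face slab, GM core."""
    nx, ny, nz = grid_shape
    if ny < 12 or nz < 6 or nx < 4:
        raise ValueError(
            f"grid {grid_shape} too small: need nx >= 4, ny >= 12, nz >= 6"
        )
    return {
        "wm": (slice(None), slice(0, 4), slice(0, nz // 2)),
        "csf": (slice(None), slice(0, 4), slice(nz // 2, nz)),
        "face": (slice(None), slice(ny - 4, ny), slice(None)),
        "gm": (slice(None), slice(4, ny - 5), slice(None)),
        "brain": (slice(None), slice(0, ny - 5), slice(None)),
    }


def build_tissue_masks(params: SimParams) -> dict[str, np.ndarray]:
    """Disjoint rectangular WM / CSF / face blocks >= 3 voxels thick, plus the
    brain mask (GM core plus tissue slab; face excluded)."""
    regions = _mask_regions(params.grid_shape)
    masks = {}
    for name in ("wm", "csf", "face", "brain", "gm"):
        m = np.zeros(params.grid_shape, dtype=bool)
        m[regions[name]] = True
        masks[name] = m
    return masks


def build_symmetric_parcellation(params: SimParams) -> ParcellationAtlas:
    """Mirror-symmetric parcellation: 2x2x2-voxel ROI blocks on a lattice.

    Left-hemisphere ROIs (ids 1..n) are placed in raster order on a 2-voxel
    lattice inside the gray-matter core; right-hemisphere ROIs (ids n+1..2n)
    are their exact mirrors across the mid-sagittal plane.  Networks are
    assigned round-robin so every network has the same count per hemisphere.
    """
    if params.n_rois_per_hemisphere < 8:
        raise ValueError("need n_rois_per_hemisphere >= 8 so every network has an ROI")
    nx, ny, nz = params.grid_shape
    gm = _mask_regions(params.grid_shape)["gm"]
    y_lo, y_hi = gm[1].start, gm[1].stop
    x_sites = list(range(0, nx // 2 - 1, 2))
    y_sites = list(range(y_lo, y_hi - 1, 2))
    z_sites = list(range(0, nz - 1, 2))
    capacity = len(x_sites) * len(y_sites) * len(z_sites)
    if params.n_rois_per_hemisphere > capacity:
        counts = {"x": len(x_sites), "y": len(y_sites), "z": len(z_sites)}
        limiting = min(counts, key=counts.get)
        raise ValueError(
            f"grid {params.grid_shape} fits only {capacity} ROIs per hemisphere "
            f"(requested {params.n_rois_per_hemisphere}); the {limiting} axis is limiting"
        )

    sites = [(x, y, z) for z in z_sites for y in y_sites for x in x_sites]
    n = params.n_rois_per_hemisphere
    labels = np.zeros(params.grid_shape, dtype=np.int32)
    affine = grid_affine(params.grid_shape, params.voxel_size_mm)
    rows = []
    for k in range(n):
        x0, y0, z0 = sites[k]
        net = params.network_labels[k % len(params.network_labels)]
        lid, rid = k + 1, n + k + 1
        labels[x0 : x0 + 2, y0 : y0 + 2, z0 : z0 + 2] = lid
        xm = nx - 2 - x0  # mirror of the block start across the midline
        labels[xm : xm + 2, y0 : y0 + 2, z0 : z0 + 2] = rid
        for roi_id, hemi, xs in ((lid, "L", x0), (rid, "R", xm)):
            idx = np.argwhere(labels == roi_id)
            cent_vox = idx.mean(axis=0)
            cent = affine[:3, :3] @ cent_vox + affine[:3, 3]
            rows.append(
                {
                    "id": roi_id,
                    "name": f"{net.replace(' ', '_')}_{hemi}{k % len(params.network_labels) + 1}_{k // 8 + 1}",
                    "hemisphere": hemi,
                    "source_network": net,
                    "merged_network": net,
                    "x": cent[0],
                    "y": cent[1],
                    "z": cent[2],
                    "mirror_id": rid if hemi == "L" else lid,
                }
            )
    table = pd.DataFrame(rows).sort_values("id").reset_index(drop=True)
    return ParcellationAtlas(
        labels=labels,
        affine=affine,
        roi_table=table,
        network_merge_map={n_: n_ for n_ in params.network_labels} | {"none": "none"},
    )


# ---------------------------------------------------------------------------
# covariance
# ---------------------------------------------------------------------------
def _assemble_z_matrix(
    atlas: ParcellationAtlas,
    within_z: dict[str, float],
    between_z: np.ndarray,
    homotopic_z: float,
    network_order: tuple[str, ...],
) -> np.ndarray:
    nets = atlas.roi_table["merged_network"].to_numpy()
    net_idx = {name: i for i, name in enumerate(network_order)}
    n = len(nets)
    Z = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if nets[i] == nets[j]:
                Z[i, j] = within_z.get(nets[i], 0.0)
            else:
                Z[i, j] = between_z[net_idx[nets[i]], net_idx[nets[j]]]
    Z = Z + Z.T
    if homotopic_z and "mirror_id" in atlas.roi_table.columns:
        ids = atlas.roi_table["id"].to_numpy()
        pos = {rid: i for i, rid in enumerate(ids)}
        for i, mid in enumerate(atlas.roi_table["mirror_id"].to_numpy()):
            j = pos[mid]
            if i < j:
                Z[i, j] += homotopic_z
                Z[j, i] += homotopic_z
    return Z


def nearest_positive_definite(R: np.ndarray, eig_floor: float = 1e-6) -> tuple[np.ndarray, float]:
    """Eigenvalue-clipping repair to the nearest unit-diagonal PD matrix."""
    vals, vecs = np.linalg.eigh(R)
    clipped = np.clip(vals, eig_floor, None)
    fixed = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    return fixed, float(np.max(np.abs(fixed - R)))


def build_roi_covariance(
    params: SimParams,
    atlas: ParcellationAtlas,
    within_z: dict[str, float] | None = None,
    between_z: np.ndarray | None = None,
    homotopic_z: float | None = None,
) -> CovarianceSpec:
    """Target ROI covariance implied by the coupling parameters.

    Correlations are tanh of the target Fisher-z values: ``within_z`` on
    same-network cells, ``between_z`` on cross-network cells, plus
    ``homotopic_z`` on mirror pairs; unit diagonal.  If the assembled matrix
    is not positive definite it is repaired by eigenvalue clipping and the
    repair magnitude (max absolute correlation change) is reported.
    """
    missing = set(atlas.roi_table["merged_network"]) - set(params.network_labels) - {"none"}
    if missing:
        raise ValueError(f"atlas networks not in params.network_labels: {sorted(missing)}")
    wz = within_z if within_z is not None else params.within_z_map()
    bz = between_z if between_z is not None else params.between_z_matrix()
    hz = homotopic_z if homotopic_z is not None else params.homotopic_z
    Z = _assemble_z_matrix(atlas, wz, bz, hz, params.network_labels)
    if not np.all(np.isfinite(Z)):
        raise ValueError("coupling z-values must be finite (|r| < 1)")
    R = np.tanh(Z)
    np.fill_diagonal(R, 1.0)
    min_eig = float(np.linalg.eigvalsh(R).min())
    if min_eig > 1e-10:
        return CovarianceSpec(matrix=R)
    fixed, magnitude = nearest_positive_definite(R)
    return CovarianceSpec(matrix=fixed, repaired=True, repair_magnitude=magnitude)


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------
def simulate_motion(
    params: SimParams,
    group: str,
    rng: np.random.Generator | int,
    n_frames: int | None = None,
    fd_threshold_mm: float = 0.2,
    rate_multiplier: float = 1.0,
) -> tuple[MotionParams, dict]:
    """Smooth low-amplitude drift plus Poisson-placed one-frame spikes.

    A spike at frame t is a one-frame translation excursion of total
    magnitude ``spike_fd_mm`` (returning at t+1), so it produces two
    supra-threshold FD transitions.  ``rate_multiplier`` scales the group
    spike rate for one subject (subjects differ widely in how much they
    move; the cohort generator draws gamma multipliers so motion-free-volume
    counts show realistic between-subject spread).  Returns the motion
    series and a truth record with the spike insertion frames and the frames
    whose FD exceeds ``fd_threshold_mm``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    T = int(n_frames if n_frames is not None else params.n_frames_per_run)
    t = np.arange(T) * params.tr_seconds
    motion = np.zeros((T, 6))
    for p in range(6):
        amp = params.drift_mm if p < 3 else params.drift_mm / 50.0
        for _ in range(2):
            f = rng.uniform(0.003, 0.02)  # Hz, slow drift
            phase = rng.uniform(0, 2 * np.pi)
            motion[:, p] += 0.5 * amp * np.sin(2 * np.pi * f * t + phase)

    rate = params.spike_rate_for(group) * rate_multiplier
    n_spikes = rng.poisson(rate * T)
    spike_frames = np.array([], dtype=int)
    if n_spikes > 0 and T > 2:
        spike_frames = np.sort(rng.integers(1, T - 1, size=n_spikes))
        for frame in spike_frames:
            w = rng.dirichlet(np.ones(3)) * params.spike_fd_mm
            signs = rng.choice([-1.0, 1.0], size=3)
            motion[frame, :3] += signs * w  # excursion for exactly one frame

    fd = compute_framewise_displacement(motion)
    truth = {
        "spike_frames": spike_frames,
        "supra_threshold_frames": np.flatnonzero(fd > fd_threshold_mm),
        "fd_mm": fd,
    }
    return MotionParams(params=motion), truth


# ---------------------------------------------------------------------------
# BOLD signal synthesis
# ---------------------------------------------------------------------------
def _lowpass_colored(white: np.ndarray, tr_seconds: float, cutoff_hz: float) -> np.ndarray:
    """Low-pass colour white series (frames x channels) via an FFT filter.

    The same |H(f)| = (1 + (f/fc)^4)^(-1/2) kernel is applied to every
    channel, so cross-channel correlations are preserved in expectation;
    columns are rescaled by a common factor restoring unit marginal variance.
    """
    T = white.shape[0]
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    H = 1.0 / np.sqrt(1.0 + (freqs / cutoff_hz) ** 4)
    spec = np.fft.rfft(white, axis=0) * H[:, None]
    out = np.fft.irfft(spec, n=T, axis=0)
    # power retained by the filter (DC and Nyquist weights counted once)
    w = np.ones_like(freqs)
    w[0] = 0.5
    if T % 2 == 0:
        w[-1] = 0.5
    gain = np.sqrt((w * H**2).sum() / w.sum())
    return out / gain


def simulate_subject(
    params: SimParams,
    phenotype: SubjectPhenotype,
    atlas: ParcellationAtlas,
    covariance: CovarianceSpec | np.ndarray,
    seed: np.random.SeedSequence | int,
    masks: dict | None = None,
) -> SyntheticSubject:
    """Generate all runs, motion and masks for one subject.

    ROI series are drawn from a zero-mean multivariate normal with the given
    covariance and low-pass coloured; a shared global series (``global_amp``)
    is added to all in-brain voxels; ROI signals are painted onto their voxel
    blocks with white voxel noise; WM/CSF/face voxels carry their own
    confound series, which leak into gray matter at ``confound_amp``.
    Deterministic given the seed.
    """
    cov = covariance.matrix if isinstance(covariance, CovarianceSpec) else np.asarray(covariance)
    if cov.shape[0] != atlas.n_rois:
        raise ValueError(
            f"covariance dimension {cov.shape[0]} != ROI count {atlas.n_rois}"
        )
    if masks is None:
        masks = build_tissue_masks(params)
    seed = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    affine = grid_affine(params.grid_shape, params.voxel_size_mm)

    # gray voxels not claimed by an ROI still get noise so they are not flat
    roi_voxels = [np.flatnonzero((atlas.labels == rid).ravel()) for rid in atlas.roi_ids]
    brain_flat = np.flatnonzero(masks["brain"].ravel())
    gm_flat = np.flatnonzero(masks["gm"].ravel())
    tissue_flat = {k: np.flatnonzero(masks[k].ravel()) for k in ("wm", "csf", "face")}

    runs, motion_list = [], []
    truth_runs = []
    rngs = seed.spawn(params.n_runs + 1)
    subject_rng = np.random.default_rng(rngs[-1])
    if params.spike_dispersion > 0:
        k = params.spike_dispersion
        rate_multiplier = float(subject_rng.gamma(k, 1.0 / k))
    else:
        rate_multiplier = 1.0
    T = params.n_frames_per_run
    for r in range(params.n_runs):
        rng = np.random.default_rng(rngs[r])
        mot, mot_truth = simulate_motion(
            params, phenotype.group, rng, n_frames=T, rate_multiplier=rate_multiplier
        )
        roi_ts = _lowpass_colored(
            rng.standard_normal((T, atlas.n_rois)), params.tr_seconds, params.lowpass_hz
        ) @ L.T
        global_ts = _lowpass_colored(
            rng.standard_normal((T, 1)), params.tr_seconds, params.lowpass_hz
        )[:, 0]
        confound_ts = {
            k: _lowpass_colored(
                rng.standard_normal((T, 1)), params.tr_seconds, params.lowpass_hz
            )[:, 0]
            for k in ("wm", "csf", "face")
        }

        nvox = int(np.prod(params.grid_shape))
        flat = np.zeros((nvox, T))
        for vox, col in zip(roi_voxels, roi_ts.T):
            flat[vox, :] = col
        leak = params.confound_amp * (
            confound_ts["wm"] + confound_ts["csf"] + confound_ts["face"]
        )
        flat[gm_flat, :] += leak
        for k in ("wm", "csf", "face"):
            flat[tissue_flat[k], :] += confound_ts[k]
        flat[brain_flat, :] += params.global_amp * global_ts
        if params.noise_sd > 0:
            active = np.union1d(brain_flat, tissue_flat["face"])
            flat[active, :] += params.noise_sd * rng.standard_normal((active.size, T))

        runs.append(
            BoldRun(
                data=flat.reshape(*params.grid_shape, T),
                tr_seconds=params.tr_seconds,
                run_id=f"run-{r + 1}",
                subject_id=phenotype.subject_id,
                affine=affine,
            )
        )
        motion_list.append(mot)
        truth_runs.append(
            {
                "roi_ts": roi_ts,
                "global_ts": global_ts,
                "confound_ts": confound_ts,
                "spike_frames": mot_truth["spike_frames"],
                "supra_threshold_frames": mot_truth["supra_threshold_frames"],
                "fd_mm": mot_truth["fd_mm"],
            }
        )

    truth = {"covariance": cov, "runs": truth_runs, "spike_rate_multiplier": rate_multiplier}
    return SyntheticSubject(
        phenotype=phenotype, runs=runs, motion=motion_list, masks=masks, truth=truth
    )


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------
def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def sample_phenotype(group: str, index: int, rng: np.random.Generator) -> SubjectPhenotype:
    demo = GROUP_DEMOGRAPHICS[group]
    iq = _truncated_normal(rng, *demo["iq"], *demo["iq_range"])
    age = _truncated_normal(rng, *demo["age"], *AGE_RANGE)
    sex = "M" if rng.random() < demo["male_frac"] else "F"
    # verbal scores track composite closely (observed r ~ 0.95)
    verbal = float(np.clip(iq + rng.normal(0, 6.0), 20.0, 145.0))
    return SubjectPhenotype(
        subject_id=f"sub-{group.lower()}{index + 1:02d}",
        group=group,
        age_years=age,
        sex=sex,
        iq_composite=iq,
        iq_verbal=verbal,
    )


def _subject_coupling(
    params: SimParams,
    phenotype: SubjectPhenotype,
    effects: dict | None,
    rng: np.random.Generator,
) -> tuple[dict[str, float], np.ndarray, float]:
    """Per-subject coupling parameters: group deltas + between-subject jitter
    + optional IQ-linked uniform offset."""
    wz = params.within_z_map()
    bz = params.between_z_matrix().copy()
    hz = float(params.homotopic_z)
    group_fx = (effects or {}).get(phenotype.group, {})
    for net, d in group_fx.get("within_z_delta", {}).items():
        wz[net] = wz.get(net, 0.0) + d
    net_idx = {n: i for i, n in enumerate(params.network_labels)}
    for (a, b), d in group_fx.get("between_z_delta", {}).items():
        i, j = net_idx[a], net_idx[b]
        bz[i, j] += d
        bz[j, i] += d
    hz += group_fx.get("homotopic_z_delta", 0.0)

    sd = params.subject_sd
    if sd > 0:
        for net in wz:
            wz[net] += rng.normal(0, sd)
        jitter = rng.normal(0, sd, size=bz.shape)
        jitter = np.triu(jitter, 1)
        bz += jitter + jitter.T
        hz += rng.normal(0, sd)

    if params.iq_conn_slope != 0 and phenotype.group in params.iq_conn_groups:
        demo = GROUP_DEMOGRAPHICS[phenotype.group]
        offset = -params.iq_conn_slope * (phenotype.iq_composite - demo["iq"][0]) / demo["iq"][1]
        for net in wz:
            wz[net] += offset
        bz += offset
    return wz, bz, hz


def simulate_cohort(
    params: SimParams | None = None,
    group_sizes: dict[str, int] | None = None,
    group_effects: dict | str | None = "default",
    seed: int | None = None,
) -> Cohort:
    """Generate a full three-group cohort with a ground-truth manifest.

    ``group_effects='default'`` plants :data:`DEFAULT_GROUP_EFFECTS`;
    ``None`` (or ``{}``) produces a null cohort in which every group shares
    the same generating parameters.  ``group_sizes`` defaults to the study
    sample (17 / 20 / 19).
    """
    params = params if params is not None else SimParams()
    if group_effects == "default":
        group_effects = DEFAULT_GROUP_EFFECTS
    sizes = {g: GROUP_DEMOGRAPHICS[g]["n"] for g in GROUPS}
    if group_sizes:
        sizes.update(group_sizes)
    for g, n in sizes.items():
        if n < 2:
            raise ValueError(f"need at least 2 subjects per group, got {n} for {g}")

    root = np.random.SeedSequence(params.seed if seed is None else seed)
    atlas = build_symmetric_parcellation(params)
    masks = build_tissue_masks(params)
    pheno_rng = np.random.default_rng(root.spawn(1)[0])

    subjects = []
    truth_subjects = {}
    subject_seeds = np.random.SeedSequence(root.entropy, spawn_key=(1,)).spawn(
        sum(sizes.values())
    )
    k = 0
    for group in GROUPS:
        for i in range(sizes[group]):
            phenotype = sample_phenotype(group, i, pheno_rng)
            sub_seed = subject_seeds[k]
            k += 1
            coupling_rng = np.random.default_rng(
                np.random.SeedSequence(root.entropy, spawn_key=(2, k))
            )
            wz, bz, hz = _subject_coupling(params, phenotype, group_effects, coupling_rng)
            cov = build_roi_covariance(params, atlas, within_z=wz, between_z=bz, homotopic_z=hz)
            group_fx = (group_effects or {}).get(group, {})
            subj_params = params
            if "global_amp" in group_fx:
                subj_params = replace(params, global_amp=group_fx["global_amp"])
            subject = simulate_subject(subj_params, phenotype, atlas, cov, sub_seed, masks=masks)
            subject.truth["coupling"] = {
                "within_z": wz,
                "between_z": bz,
                "homotopic_z": hz,
                "cov_repaired": cov.repaired,
                "cov_repair_magnitude": cov.repair_magnitude,
            }
            subjects.append(subject)
            truth_subjects[phenotype.subject_id] = {
                "group": group,
                "within_z": {n: float(v) for n, v in wz.items()},
                "homotopic_z": float(hz),
                "n_spike_frames": [int(r["spike_frames"].size) for r in subject.truth["runs"]],
            }

    truth = {
        "seed": int(root.entropy) if root.entropy < 2**63 else None,
        "group_sizes": sizes,
        "planted_effects": group_effects or {},
        "subjects": truth_subjects,
    }
    return Cohort(subjects=subjects, atlas=atlas, params=params, truth=truth)
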