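"""ROI time-series extraction and connectivity summaries.

Time series are extracted per ROI (mean over labelled voxels) from cleaned
runs, restricted to motion-free frames, centred per run and concatenated in
run order.  Connectivity is the Pearson correlation between ROI series,
Fisher-transformed (z = atanh r).  Network-level summaries follow two
distinct conventions: within-network connectivity is the mean Fisher-z over
distinct ROI pairs inside a network, while between-network connectivity is
the Fisher-z of the correlation between the two networks' *mean* time series
(synchrony of network means, not a mean of pairwise values).  Homotopic
connectivity pairs every ROI with the contralateral ROI whose centroid is
nearest to the mirror image (x -> -x) of its own centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ParcellationAtlas


@dataclass
class RoiTimeSeries:
    """Kept-frames x ROIs matrix for one subject and one processing stream."""

    data: np.ndarray
    roi_ids: np.ndarray
    kept_indices: list
    subject_id: str = "sub-01"
    stream: str = "nogsr"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_ids = np.asarray(self.roi_ids, dtype=int)
        if self.data.shape[1] != self.roi_ids.size:
            raise ValueError("column count must equal ROI count")

    @property
    def n_motion_free(self) -> int:
        return self.data.shape[0]


@dataclass
class HomotopicPairs:
    """Directional nearest-mirror assignment for every ROI.

    ``table`` has one row per ROI (roi_id, partner_id, distance_mm, mutual);
    ``pairs`` lists one (left_id, right_id, distance_mm) triple per
    left-hemisphere ROI, the form used for group comparisons.
    """

    table: pd.DataFrame
    pairs: pd.DataFrame

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class ConnectivityResult:
    """All connectivity summaries for one subject and one stream."""

    subject_id: str
    stream: str
    roi_ids: np.ndarray
    zmat: np.ndarray
    networks: list
    network_ts: np.ndarray
    between_z: np.ndarray
    within_mean: np.ndarray
    homotopic: pd.DataFrame
    net_to_roi: pd.DataFrame
    n_motion_free: int

    def within_mean_map(self) -> dict:
        return dict(zip(self.networks, self.within_mean))

    def between_z_value(self, net_a: str, net_b: str) -> float:
        i, j = self.networks.index(net_a), self.networks.index(net_b)
        return float(self.between_z[i, j])

    def pairwise_z_values(self) -> np.ndarray:
        """All distinct off-diagonal Fisher-z values (upper triangle)."""
        iu = np.triu_indices_from(self.zmat, k=1)
        return self.zmat[iu]


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------
def extract_roi_timeseries(
    cleaned_runs: list,
    atlas: ParcellationAtlas,
    censor_masks: list,
    stream: str = "nogsr",
    center: bool = True,
    min_volumes: int = 200,
    require_usable: bool = True,
) -> RoiTimeSeries:
    """Mean ROI series over kept frames, centred per run, concatenated.

    Raises if any table ROI has no voxels in the label volume, or (when
    ``require_usable``) if fewer than ``min_volumes`` frames survive
    censoring across all runs.
    """
    missing = atlas.missing_in_volume()
    if missing.size:
        raise ValueError(f"ROIs absent from the label volume: {missing.tolist()}")
    if len(cleaned_runs) != len(censor_masks):
        raise ValueError("cleaned_runs and censor_masks differ in length")

    roi_ids = atlas.roi_ids
    flat_masks = [np.flatnonzero((atlas.labels == rid).ravel()) for rid in roi_ids]
    blocks, kept_indices = [], []
    for run, cmask in zip(cleaned_runs, censor_masks):
        if cmask.keep.size != run.n_frames:
            raise ValueError(
                f"censor mask length {cmask.keep.size} != run frames {run.n_frames}"
            )
        flat = run.data.reshape(-1, run.n_frames)
        kept = np.flatnonzero(cmask.keep)
        block = np.column_stack([flat[vox, :].mean(axis=0)[kept] for vox in flat_masks])
        if center and block.shape[0] > 0:
            block = block - block.mean(axis=0, keepdims=True)
        blocks.append(block)
        kept_indices.append(kept)

    data = np.vstack(blocks)
    total = data.shape[0]
    if require_usable and total < min_volumes:
        raise ValueError(
            f"subject not usable: {total} motion-free volumes < required {min_volumes}"
        )
    return RoiTimeSeries(
        data=data,
        roi_ids=roi_ids,
        kept_indices=kept_indices,
        subject_id=cleaned_runs[0].subject_id,
        stream=stream,
    )


# ---------------------------------------------------------------------------
# connectivity matrices
# ---------------------------------------------------------------------------
def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    return np.arctanh(r)


def fisher_connectivity(
    ts: RoiTimeSeries | np.ndarray, on_perfect: str = "error"
) -> np.ndarray:
    """ROI x ROI Fisher-z matrix (diagonal NaN).

    Columns with zero variance raise, naming the ROI.  Off-diagonal |r| = 1
    is degenerate (atanh diverges): policy ``'error'`` (default) raises,
    ``'inf'`` stores signed infinity.
    """
    data = ts.data if isinstance(ts, RoiTimeSeries) else np.asarray(ts, float)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 kept frames for a correlation")
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        ids = (
            ts.roi_ids[dead].tolist()
            if isinstance(ts, RoiTimeSeries)
            else dead.tolist()
        )
        raise ValueError(f"zero-variance ROI time series: {ids}")
    r = np.corrcoef(data, rowvar=False)
    off = ~np.eye(r.shape[0], dtype=bool)
    perfect = off & (np.abs(r) >= 1.0 - 1e-12)
    if perfect.any():
        if on_perfect == "error":
            i, j = np.argwhere(perfect)[0]
            raise ValueError(
                f"|r| = 1 between ROI columns {i} and {j}; degenerate duplicate series"
            )
        r = np.clip(r, -1.0, 1.0)
        z = np.where(perfect, np.sign(r) * np.inf, np.arctanh(np.where(off, r, 0.0)))
    else:
        z = np.arctanh(np.where(off, r, 0.0))
    np.fill_diagonal(z, np.nan)
    return z


def network_level(
    ts: RoiTimeSeries,
    atlas: ParcellationAtlas,
    zmat: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Network mean series, between-network synchrony, within-network means.

    Returns ``(network_ts, between_z, within_mean, networks)``.  ROIs with
    merged network 'none' are excluded.  Networks with a single member ROI
    have no within pair and yield NaN with a warning.
    """
    networks = atlas.networks
    unknown = set(atlas.roi_table["merged_network"]) - set(networks) - {"none"}
    if unknown:
        raise ValueError(f"unknown network labels: {sorted(unknown)}")
    if zmat is None:
        zmat = fisher_connectivity(ts)

    members = {n: atlas.network_members(n) for n in networks}
    net_ts = np.column_stack([ts.data[:, members[n]].mean(axis=1) for n in networks])
    r = np.corrcoef(net_ts, rowvar=False)
    off = ~np.eye(len(networks), dtype=bool)
    between_z = np.where(off, np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)), np.nan)

    within_mean = np.empty(len(networks))
    for k, n in enumerate(networks):
        idx = members[n]
        if idx.size < 2:
            warnings.warn(f"network {n!r} has a single ROI; within-network mean is NaN")
            within_mean[k] = np.nan
            continue
        sub = zmat[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        within_mean[k] = sub[iu].mean()
    return net_ts, between_z, within_mean, networks


# ---------------------------------------------------------------------------
# homotopic analysis
# ---------------------------------------------------------------------------
def homotopic_pairs(atlas: ParcellationAtlas) -> HomotopicPairs:
    """Nearest-mirror contralateral partner for every ROI.

    Mirrors each centroid across the mid-sagittal plane (x -> -x) and picks
    the contralateral ROI with minimum Euclidean centroid distance; ties
    break to the lower ROI id.  The assignment is directional; a ``mutual``
    flag records whether the partner maps back.
    """
    table = atlas.roi_table
    hemis = table["hemisphere"].to_numpy()
    if not (np.any(hemis == "L") and np.any(hemis == "R")):
        raise ValueError("both hemispheres must be non-empty for homotopic pairing")
    cents = atlas.centroids()
    ids = table["id"].to_numpy()
    midline = np.flatnonzero(cents[:, 0] == 0)
    if midline.size:
        warnings.warn(
            f"ROIs with centroid exactly on the midline: {ids[midline].tolist()}; "
            "assigned by the nearest-mirror rule regardless"
        )

    partner = np.empty(len(ids), dtype=int)
    dist = np.empty(len(ids))
    for i in range(len(ids)):
        mirrored = cents[i] * np.array([-1.0, 1.0, 1.0])
        contra = np.flatnonzero(hemis != hemis[i])
        d = np.linalg.norm(cents[contra] - mirrored, axis=1)
        # ties break to the lower ROI id
        order = np.lexsort((ids[contra], d))
        best = contra[order[0]]
        partner[i] = ids[best]
        dist[i] = d[order[0]]

    pos = {rid: i for i, rid in enumerate(ids)}
    mutual = np.array([partner[pos[partner[i]]] == ids[i] for i in range(len(ids))])
    full = pd.DataFrame(
        {"roi_id": ids, "partner_id": partner, "distance_mm": dist, "mutual": mutual}
    )
    left = full[hemis == "L"].rename(
        columns={"roi_id": "left_id", "partner_id": "right_id"}
    )
    return HomotopicPairs(table=full, pairs=left.reset_index(drop=True))


def homotopic_connectivity(
    zmat: np.ndarray, pairs: HomotopicPairs, roi_ids: np.ndarray
) -> pd.DataFrame:
    """Fisher-z of each left ROI with its mirrored partner.

    Returns a frame (left_id, right_id, z) indexed by left ROI id.
    """
    pos = {int(rid): i for i, rid in enumerate(np.asarray(roi_ids))}
    rows = []
    for _, row in pairs.pairs.iterrows():
        li, ri = pos[int(row["left_id"])], pos[int(row["right_id"])]
        rows.append(
            {"left_id": int(row["left_id"]), "right_id": int(row["right_id"]), "z": zmat[li, ri]}
        )
    return pd.DataFrame(rows).set_index("left_id")


# ---------------------------------------------------------------------------
# network-to-ROI maps
# ---------------------------------------------------------------------------
def network_to_roi(
    ts: RoiTimeSeries, atlas: ParcellationAtlas, network_name: str
) -> pd.DataFrame:
    """Fisher-z between one network's mean series and every ROI column.

    Member ROIs are included in the map and flagged.
    """
    if network_name not in atlas.networks:
        raise ValueError(f"unknown network {network_name!r}")
    members = atlas.network_members(network_name)
    mean_ts = ts.data[:, members].mean(axis=1)
    sd = ts.data.std(axis=0)
    if np.any(sd == 0) or mean_ts.std() == 0:
        raise ValueError("zero-variance series in network-to-ROI map")
    centred = ts.data - ts.data.mean(axis=0)
    m = mean_ts - mean_ts.mean()
    r = (centred * m[:, None]).sum(axis=0) / (
        np.linalg.norm(centred, axis=0) * np.linalg.norm(m)
    )
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    member_flag = np.zeros(ts.roi_ids.size, dtype=bool)
    member_flag[members] = True
    return pd.DataFrame({"roi_id": ts.roi_ids, "z": z, "member": member_flag})


# ---------------------------------------------------------------------------
# one-call summary
# ---------------------------------------------------------------------------
def compute_connectivity(
    ts: RoiTimeSeries, atlas: ParcellationAtlas
) -> ConnectivityResult:
    """Compute every connectivity summary for one subject/stream."""
    zmat = fisher_connectivity(ts)
    net_ts, between_z, within_mean, networks = network_level(ts, atlas, zmat=zmat)
    pairs = homotopic_pairs(atlas)
    homo = homotopic_connectivity(zmat, pairs, ts.roi_ids)
    maps = {}
    for net in networks:
        maps[net] = network_to_roi(ts, atlas, net)["z"].to_numpy()
    net_to_roi_df = pd.DataFrame(maps, index=pd.Index(ts.roi_ids, name="roi_id"))
    return ConnectivityResult(
        subject_id=ts.subject_id,
        stream=ts.stream,
        roi_ids=ts.roi_ids,
        zmat=zmat,
        networks=networks,
        network_ts=net_ts,
        between_z=between_z,
        within_mean=within_mean,
        homotopic=homo,
        net_to_roi=net_to_roi_df,
        n_motion_free=ts.n_motion_free,
    )
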