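"""Cortical parcellation atlas: label volume plus ROI table.

The atlas defines the nodes of every connectivity analysis.  It follows the
structure of the Gordon 333-parcel cortical scheme: each parcel has an id,
a hemisphere, a centroid in world (mm) coordinates, and a functional-network
assignment.  The twelve source networks are merged into eight analysis
networks (parcels labelled ``none`` are kept for ROI-level and homotopic
analyses but excluded from network-level summaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The eight analysis networks.
NETWORKS_8: tuple[str, ...] = (
    "auditory",
    "salience",
    "frontoparietal",
    "default",
    "dorsal attention",
    "ventral attention",
    "sensorimotor",
    "visual",
)

#: Merge map from the twelve source networks of the Gordon scheme onto the
#: eight analysis networks (cingulo-opercular joins salience, cinguloparietal
#: joins frontoparietal, retrosplenial-temporal joins default, the two
#: sensorimotor subdivisions are pooled).  ``none`` stays unassigned.
GORDON_12_TO_8: dict[str, str] = {
    "auditory": "auditory",
    "cinguloopercular": "salience",
    "salience": "salience",
    "frontoparietal": "frontoparietal",
    "cinguloparietal": "frontoparietal",
    "default": "default",
    "retrosplenialtemporal": "default",
    "dorsalattention": "dorsal attention",
    "ventralattention": "ventral attention",
    "sensorimotorhand": "sensorimotor",
    "sensorimotormouth": "sensorimotor",
    "visual": "visual",
    "none": "none",
}

_ROI_COLUMNS = [
    "id",
    "name",
    "hemisphere",
    "source_network",
    "merged_network",
    "x",
    "y",
    "z",
]


def _canon_network(label: str) -> str:
    """Normalise a network label: lowercase, drop separators."""
    return "".join(str(label).lower().split()).replace("-", "").replace("_", "")


@dataclass
class ParcellationAtlas:
    """Label volume + ROI table defining analysis nodes.

    Parameters
    ----------
    labels
        3-D integer array; 0 is background, positive values are ROI ids.
    affine
        4x4 voxel-to-world affine (NIfTI convention, world x increases to
        the right, the mid-sagittal plane is x = 0).
    roi_table
        One row per ROI with columns ``id, name, hemisphere, source_network,
        merged_network, x, y, z`` (centroids in world mm).  A ``mirror_id``
        column may be present for synthetic mirror-symmetric atlases.
    network_merge_map
        Source-network -> merged-network mapping used to build the table.
    """

    labels: np.ndarray
    affine: np.ndarray
    roi_table: pd.DataFrame
    network_merge_map: dict[str, str] = field(default_factory=lambda: dict(GORDON_12_TO_8))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def roi_ids(self) -> np.ndarray:
        return self.roi_table["id"].to_numpy()

    @property
    def n_rois(self) -> int:
        return len(self.roi_table)

    @property
    def networks(self) -> list[str]:
        """Merged networks present, excluding 'none', in canonical order."""
        present = set(self.roi_table["merged_network"]) - {"none"}
        ordered = [n for n in NETWORKS_8 if n in present]
        extras = sorted(present - set(ordered))
        return ordered + extras

    def centroids(self) -> np.ndarray:
        """(n_rois, 3) world-mm centroids in table order."""
        return self.roi_table[["x", "y", "z"]].to_numpy(dtype=float)

    def network_members(self, network: str) -> np.ndarray:
        """Column indices (table order) of ROIs in a merged network."""
        return np.flatnonzero((self.roi_table["merged_network"] == network).to_numpy())

    def voxel_mask(self, roi_id: int) -> np.ndarray:
        return self.labels == roi_id

    def validate(self) -> None:
        ids = self.roi_table["id"].to_numpy()
        if len(ids) == 0:
            raise ValueError("atlas ROI table is empty")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("atlas ROI ids are not unique")
        if not np.array_equal(np.sort(ids), np.arange(1, len(ids) + 1)):
            raise ValueError("atlas ROI ids must be contiguous 1..n")
        labelled = np.unique(self.labels)
        labelled = labelled[labelled > 0]
        missing = np.setdiff1d(labelled, ids)
        if missing.size:
            raise ValueError(
                f"label volume contains ids absent from the ROI table: {missing.tolist()}"
            )
        bad_hemi = set(self.roi_table["hemisphere"]) - {"L", "R"}
        if bad_hemi:
            raise ValueError(f"hemisphere labels must be L or R, got {sorted(bad_hemi)}")

    def missing_in_volume(self) -> np.ndarray:
        """Ids present in the table but absent from the label volume."""
        labelled = np.unique(self.labels)
        return np.setdiff1d(self.roi_ids, labelled[labelled > 0])


def merge_networks(source_labels, merge_map: dict[str, str] | None = None) -> list[str]:
    """Map source-network labels onto the eight merged analysis networks.

    Unknown labels raise ``KeyError`` listing the offenders.
    """
    merge_map = merge_map if merge_map is not None else GORDON_12_TO_8
    canon = {_canon_network(k): v for k, v in merge_map.items()}
    for net in NETWORKS_8:  # already-merged labels pass through unchanged
        canon.setdefault(_canon_network(net), net)
    out, unknown = [], []
    for lab in source_labels:
        key = _canon_network(lab)
        if key in canon:
            out.append(canon[key])
        else:
            unknown.append(str(lab))
    if unknown:
        raise KeyError(f"unknown source network labels: {sorted(set(unknown))}")
    return out


def read_parcel_table(path, merge_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a Gordon-style parcel table (TSV/CSV) into the ROI-table schema.

    Expects columns for parcel id, hemisphere, network and centroid x/y/z
    (case-insensitive; ``ParcelID/Hem/Community`` aliases accepted).  The
    source networks are merged 12 -> 8.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep)
    cols = {c.lower().strip(): c for c in raw.columns}

    def pick(*names):
        for n in names:
            if n in cols:
                return raw[cols[n]]
        raise KeyError(f"parcel table missing a column among {names}; has {list(raw.columns)}")

    table = pd.DataFrame(
        {
            "id": pick("id", "parcelid", "parcel_id").astype(int),
            "name": pick("name", "parcelid", "id").astype(str)
            if "name" in cols
            else pick("id", "parcelid").astype(str),
            "hemisphere": pick("hemisphere", "hem").astype(str).str.upper().str[0],
            "source_network": pick("network", "community", "source_network").astype(str),
            "x": pd.to_numeric(pick("x", "centroid_x")),
            "y": pd.to_numeric(pick("y", "centroid_y")),
            "z": pd.to_numeric(pick("z", "centroid_z")),
        }
    )
    table["merged_network"] = merge_networks(table["source_network"], merge_map)
    return table[_ROI_COLUMNS]
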