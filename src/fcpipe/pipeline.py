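"""End-to-end orchestration: simulate -> preprocess -> connect -> stats -> report.

A single :class:`RunConfig` (YAML-serialisable) fixes every parameter; its
defaults are the analysis defaults (FD threshold 0.2 mm, 200-volume
usability floor, 0.001-0.1 Hz band, both GSR streams).  One global seed fans
out to per-subject sub-seeds through a counter-based seed tree, so a cohort
is reproducible subject-by-subject regardless of ordering.  Stage outputs
are checksummed into a manifest; completed stages whose stored config hash
matches are loaded from disk instead of recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import ParcellationAtlas
from .connectivity import compute_connectivity, extract_roi_timeseries
from .io import (
    load_connectivity,
    save_censor,
    save_connectivity,
    save_labels,
    save_motion,
    save_parcel_table,
)
from .preprocess import preprocess_subject
from .simulate import SimParams, simulate_cohort
from .stats import (
    gsr_contrast,
    iq_connectivity_correlation,
    run_family_analyses,
    scalar_iq_correlation,
)

STREAM_MAP = {"on": ("gsr",), "off": ("nogsr",), "both": ("nogsr", "gsr")}


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    out_dir: str = "fcpipe_out"
    seed: int = 0
    fd_threshold_mm: float = 0.2
    min_volumes: int = 200
    band_hz: tuple[float, float] = (0.001, 0.1)
    gsr_mode: str = "both"
    atlas_source: str = "synthetic"
    filter_mode: str = "dct"
    group_sizes: dict | None = None
    group_effects: str = "default"  # "default" | "null"
    sim: dict = field(default_factory=dict)
    write_volumes: bool = False
    make_figures: bool = True

    def __post_init__(self) -> None:
        # normalise container types so serialisation round-trips compare equal
        self.band_hz = tuple(self.band_hz)
        self.sim = dict(self.sim)
        if "grid_shape" in self.sim:
            self.sim["grid_shape"] = tuple(self.sim["grid_shape"])
        if self.group_sizes is not None:
            self.group_sizes = dict(self.group_sizes)

    def validate(self) -> None:
        if self.fd_threshold_mm <= 0:
            raise ValueError("config.fd_threshold_mm: must be positive")
        if self.min_volumes < 1:
            raise ValueError("config.min_volumes: must be >= 1")
        lo, hi = self.band_hz
        if not 0 <= lo < hi:
            raise ValueError("config.band_hz: need 0 <= low < high")
        if self.gsr_mode not in STREAM_MAP:
            raise ValueError(f"config.gsr_mode: must be one of {sorted(STREAM_MAP)}")
        if self.atlas_source not in ("synthetic", "table"):
            raise ValueError("config.atlas_source: must be 'synthetic' or 'table'")
        if self.atlas_source == "table":
            raise ValueError(
                "config.atlas_source: simulation-driven runs require the synthetic "
                "atlas; external parcel tables are consumed by the connect stage"
            )
        if self.group_effects not in ("default", "null"):
            raise ValueError("config.group_effects: must be 'default' or 'null'")
        if self.filter_mode not in ("dct", "butterworth"):
            raise ValueError("config.filter_mode: must be 'dct' or 'butterworth'")
        SimParams(**self.sim)  # raises on bad simulation overrides

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_hz"] = list(self.band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "band_hz" in d:
            d["band_hz"] = tuple(d["band_hz"])
        if "sim" in d and d["sim"] and "grid_shape" in d["sim"]:
            d["sim"] = dict(d["sim"])
            d["sim"]["grid_shape"] = tuple(d["sim"]["grid_shape"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict
    usability: dict
    timing: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path


# ---------------------------------------------------------------------------
# checksums
# ---------------------------------------------------------------------------
def config_hash(config: RunConfig) -> str:
    """Hash of the scientifically relevant configuration (where outputs are
    written does not change what is computed)."""
    d = config.to_dict()
    d.pop("out_dir", None)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _hash_array(a: np.ndarray) -> str:
    a = np.ascontiguousarray(a)
    return hashlib.sha256(a.tobytes() + str(a.shape).encode()).hexdigest()


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=True).encode()).hexdigest()


def _sim_params(config: RunConfig) -> SimParams:
    return SimParams(**{**config.sim, "seed": config.seed})


def _stage_done(stage_dir: Path, h: str) -> dict | None:
    marker = stage_dir / "stage.json"
    if marker.exists():
        info = json.loads(marker.read_text())
        if info.get("config_hash") == h:
            return info
    return None


def _mark_done(stage_dir: Path, h: str, checksums: dict) -> dict:
    info = {"config_hash": h, "checksums": checksums}
    (stage_dir / "stage.json").write_text(json.dumps(info, indent=2, sort_keys=True))
    return info


# ---------------------------------------------------------------------------
# in-memory cohort analysis (no file I/O)
# ---------------------------------------------------------------------------
def analyze_cohort(
    cohort,
    streams: tuple[str, ...] = ("nogsr",),
    fd_threshold_mm: float = 0.2,
    min_volumes: int = 200,
    band_hz: tuple[float, float] = (0.001, 0.1),
    drop_unusable: bool = True,
) -> tuple[dict, pd.DataFrame]:
    """Preprocess + connectivity for every subject of a simulated cohort.

    Returns ``(bundles, design)`` where ``bundles[stream][subject_id]`` is a
    ConnectivityResult and ``design`` is the covariate table for usable
    subjects.  Only ROI voxels are cleaned (nothing else is read downstream).
    """
    voxel_mask = cohort.atlas.labels > 0
    bundles: dict[str, dict] = {s: {} for s in streams}
    rows = []
    for subject in cohort.subjects:
        sid = subject.phenotype.subject_id
        n_free = None
        for stream in streams:
            pp = preprocess_subject(
                subject.runs,
                subject.motion,
                subject.masks,
                use_gsr=(stream == "gsr"),
                fd_threshold_mm=fd_threshold_mm,
                min_volumes=min_volumes,
                band_hz=band_hz,
                voxel_mask=voxel_mask,
            )
            n_free = pp.n_motion_free
            if not pp.usable:
                if drop_unusable:
                    break
                raise ValueError(f"{sid} not usable ({pp.n_motion_free} volumes)")
            ts = extract_roi_timeseries(
                pp.runs, cohort.atlas, pp.censor_masks, stream=stream, min_volumes=min_volumes
            )
            bundles[stream][sid] = compute_connectivity(ts, cohort.atlas)
        else:
            rows.append(
                {
                    "subject_id": sid,
                    "group": subject.phenotype.group,
                    "age_years": subject.phenotype.age_years,
                    "sex": subject.phenotype.sex,
                    "iq_composite": subject.phenotype.iq_composite,
                    "n_motion_free": n_free,
                }
            )
    design = pd.DataFrame(rows).set_index("subject_id")
    return bundles, design


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------
def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages; resumable, deterministic for a fixed seed."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    h = config_hash(config)
    streams = STREAM_MAP[config.gsr_mode]
    stages: dict[str, dict] = {}
    timing: dict[str, float] = {}
    usability: dict[str, dict] = {}

    sim_dir, prep_dir = out / "simulate", out / "preprocess"
    conn_dir, stats_dir = out / "connect", out / "stats"
    for d in (sim_dir, prep_dir, conn_dir, stats_dir):
        d.mkdir(exist_ok=True)

    # ---- resume: if connectivity bundles are complete, skip upstream ----
    bundles: dict[str, dict] = {}
    design: pd.DataFrame | None = None
    conn_info = _stage_done(conn_dir, h)
    prep_info = _stage_done(prep_dir, h)
    sim_info = _stage_done(sim_dir, h)
    resumed = False
    if conn_info and prep_info and sim_info and (prep_dir / "design.tsv").exists():
        try:
            design = pd.read_csv(
                prep_dir / "design.tsv", sep="\t", index_col="subject_id",
                float_precision="round_trip",
            )
            for stream in streams:
                bundles[stream] = {
                    sid: load_connectivity(conn_dir / f"{sid}_{stream}.h5")
                    for sid in design.index
                }
            stages["simulate"] = sim_info
            stages["preprocess"] = prep_info
            stages["connect"] = conn_info
            usability = json.loads((prep_dir / "usability.json").read_text())
            resumed = True
        except (OSError, KeyError):
            bundles, design, resumed = {}, None, False

    if not resumed:
        # ---- simulate --------------------------------------------------
        t0 = time.perf_counter()
        params = _sim_params(config)
        effects = "default" if config.group_effects == "default" else None
        cohort = simulate_cohort(
            params, group_sizes=config.group_sizes, group_effects=effects, seed=config.seed
        )
        pheno = cohort.phenotype_table().set_index("subject_id")
        pheno.to_csv(sim_dir / "phenotypes.tsv", sep="\t")
        save_parcel_table(cohort.atlas, sim_dir / "parcels.tsv")
        save_labels(cohort.atlas.labels, cohort.atlas.affine, sim_dir / "parcellation.nii.gz")
        checks = {
            "phenotypes": _hash_df(pheno),
            "parcellation": _hash_array(cohort.atlas.labels),
        }
        for subject in cohort.subjects:
            sid = subject.phenotype.subject_id
            for r, mot in enumerate(subject.motion):
                save_motion(mot, sim_dir / f"{sid}_run-{r + 1}_motion.tsv")
            checks[sid] = _hash_array(
                np.concatenate([m.params.ravel() for m in subject.motion])
            )
            if config.write_volumes:
                from .io import save_bold

                for run in subject.runs:
                    save_bold(run, sim_dir / f"{sid}_{run.run_id}_bold.nii.gz")
        stages["simulate"] = _mark_done(sim_dir, h, checks)
        timing["simulate"] = time.perf_counter() - t0

        # ---- preprocess + connect (per stream) -------------------------
        t0 = time.perf_counter()
        masks = cohort.subjects[0].masks
        # confound means are extracted from the raw data before regression, so
        # only voxels read downstream (ROI blocks) need cleaning — unless the
        # cleaned volumes themselves are requested.
        if config.write_volumes:
            voxel_mask = masks["brain"] | masks["face"]
        else:
            voxel_mask = cohort.atlas.labels > 0
        prep_checks: dict[str, str] = {}
        conn_checks: dict[str, str] = {}
        design_rows = []
        for subject in cohort.subjects:
            sid = subject.phenotype.subject_id
            per_stream = {}
            for stream in streams:
                pp = preprocess_subject(
                    subject.runs,
                    subject.motion,
                    subject.masks,
                    use_gsr=(stream == "gsr"),
                    fd_threshold_mm=config.fd_threshold_mm,
                    min_volumes=config.min_volumes,
                    band_hz=config.band_hz,
                    filter_mode=config.filter_mode,
                    voxel_mask=voxel_mask,
                )
                per_stream[stream] = pp
            pp0 = per_stream[streams[0]]
            usability[sid] = {
                "usable": pp0.usable,
                "n_motion_free": pp0.n_motion_free,
                "group": subject.phenotype.group,
            }
            for r, cmask in enumerate(pp0.censor_masks):
                save_censor(cmask, prep_dir / f"{sid}_run-{r + 1}_censor.tsv")
            prep_checks[sid] = _hash_array(
                np.concatenate([c.keep for c in pp0.censor_masks])
            )
            if not pp0.usable:
                warnings.warn(
                    f"{sid} excluded: {pp0.n_motion_free} motion-free volumes "
                    f"< {config.min_volumes}"
                )
                continue
            design_rows.append(
                {
                    "subject_id": sid,
                    "group": subject.phenotype.group,
                    "age_years": subject.phenotype.age_years,
                    "sex": subject.phenotype.sex,
                    "iq_composite": subject.phenotype.iq_composite,
                    "n_motion_free": pp0.n_motion_free,
                }
            )
            for stream in streams:
                pp = per_stream[stream]
                ts = extract_roi_timeseries(
                    pp.runs,
                    cohort.atlas,
                    pp.censor_masks,
                    stream=stream,
                    min_volumes=config.min_volumes,
                )
                res = compute_connectivity(ts, cohort.atlas)
                bundles.setdefault(stream, {})[sid] = res
                save_connectivity(res, conn_dir / f"{sid}_{stream}.h5")
                conn_checks[f"{sid}_{stream}"] = _hash_array(
                    np.nan_to_num(res.zmat, nan=0.0)
                )
        design = pd.DataFrame(design_rows).set_index("subject_id")
        # full float precision so a resumed run sees bit-identical covariates
        design.to_csv(prep_dir / "design.tsv", sep="\t", float_format="%.17g")
        (prep_dir / "usability.json").write_text(json.dumps(usability, indent=2, sort_keys=True))
        prep_checks["design"] = _hash_df(design)
        stages["preprocess"] = _mark_done(prep_dir, h, prep_checks)
        stages["connect"] = _mark_done(conn_dir, h, conn_checks)
        timing["preprocess+connect"] = time.perf_counter() - t0

    # ---- stats ----------------------------------------------------------
    t0 = time.perf_counter()
    stats_info = _stage_done(stats_dir, h)
    if stats_info is None or not (stats_dir / "summary.json").exists():
        stats_checks: dict[str, str] = {}
        summary: dict = {"streams": list(streams)}
        for stream in streams:
            tables = run_family_analyses(bundles[stream], design, stream=stream)
            for name, table in tables.items():
                path = stats_dir / f"{stream}_{name}.tsv"
                table.table.to_csv(path, sep="\t", index=False)
                stats_checks[f"{stream}_{name}"] = _hash_df(table.table)
            summary[f"{stream}_flagged"] = {
                name: tables[name].flagged["effect"].tolist() for name in tables
            }
        # dimensional IQ analysis within the LVCP group
        sids = list(design.index)
        stream0 = streams[0]
        zmats = [np.nan_to_num(bundles[stream0][s].zmat, nan=0.0) for s in sids]
        lvcp = (design["group"] == "LVCP").to_numpy()
        if lvcp.sum() >= 3:
            rmat = iq_connectivity_correlation(
                zmats, design["iq_composite"].to_numpy(), subgroup=lvcp
            )
            np.savetxt(stats_dir / f"{stream0}_iq_pair_correlation.tsv", rmat, delimiter="\t")
            iu = np.triu_indices_from(rmat, k=1)
            summary["iq_pair_corr_negative_fraction"] = float(np.mean(rmat[iu] < 0))
            stats_checks["iq_pair_correlation"] = _hash_array(np.nan_to_num(rmat))
            first = bundles[stream0][sids[0]]
            k = first.networks.index("default")
            within_default = np.array([bundles[stream0][s].within_mean[k] for s in sids])
            summary["iq_vs_within_default"] = {}
            for g in ("LVCP", "HVCP", "NT"):
                sel = (design["group"] == g).to_numpy()
                r, p = scalar_iq_correlation(
                    within_default[sel], design["iq_composite"].to_numpy()[sel]
                )
                summary["iq_vs_within_default"][g] = {"r": r, "p": p}
        if set(streams) == {"gsr", "nogsr"}:
            rep = gsr_contrast(bundles["gsr"], bundles["nogsr"], design)
            summary["gsr_contrast"] = {
                "median_z": {f"{s}:{g}": v for (s, g), v in rep.median_z.items()},
                "sign_agreement": rep.sign_agreement,
                "shift": rep.shift,
            }
        (stats_dir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        stats_checks["summary"] = hashlib.sha256(
            (stats_dir / "summary.json").read_bytes()
        ).hexdigest()
        stages["stats"] = _mark_done(stats_dir, h, stats_checks)
    else:
        stages["stats"] = stats_info
    timing["stats"] = time.perf_counter() - t0

    # ---- report ----------------------------------------------------------
    if config.make_figures:
        t0 = time.perf_counter()
        from .report import make_report

        figures = make_report(out)
        stages["report"] = {
            "config_hash": h,
            "checksums": {p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in figures},
        }
        timing["report"] = time.perf_counter() - t0

    manifest = RunManifest(
        config_hash=h,
        version=__version__,
        stages=stages,
        usability=usability,
        timing=timing,
    )
    manifest.save(out / "manifest.json")
    return manifest
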