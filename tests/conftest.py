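"""Shared fixtures: small synthetic scenes generated at test time."""

import numpy as np
import pytest

import fcpipe as fp


@pytest.fixture(scope="session")
def small_params():
    """Reduced-scale generator settings used across unit tests."""
    return fp.SimParams(
        grid_shape=(12, 14, 8),
        n_rois_per_hemisphere=8,
        n_frames_per_run=300,
        n_runs=1,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_atlas(small_params):
    return fp.build_symmetric_parcellation(small_params)


@pytest.fixture(scope="session")
def small_cov(small_params, small_atlas):
    return fp.build_roi_covariance(small_params, small_atlas)


@pytest.fixture(scope="session")
def nt_phenotype():
    return fp.SubjectPhenotype(
        subject_id="sub-nt01", group="NT", age_years=11.0, sex="M", iq_composite=110.0
    )


@pytest.fixture(scope="session")
def small_subject(small_params, small_atlas, small_cov, nt_phenotype):
    return fp.simulate_subject(small_params, nt_phenotype, small_atlas, small_cov, seed=42)


@pytest.fixture(scope="session")
def clean_subject(small_params, small_atlas, nt_phenotype):
    """Noise-free subject: voxel signal is exactly the painted ROI series."""
    params = fp.SimParams(
        **{
            **small_params.__dict__,
            "noise_sd": 0.0,
            "global_amp": 0.0,
            "confound_amp": 0.0,
            "drift_mm": 0.0,
            "spike_rate": 0.0,
        }
    )
    cov = fp.build_roi_covariance(params, small_atlas)
    subject = fp.simulate_subject(params, nt_phenotype, small_atlas, cov, seed=7)
    return params, subject


def make_design(rng, n_per_group=(10, 10, 10), motion_by_group=(300.0, 400.0, 410.0)):
    """Covariate table shaped like the study design (used by stats tests)."""
    import pandas as pd

    rows = []
    for (g, n, nf) in zip(fp.GROUPS, n_per_group, motion_by_group):
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{g.lower()}{i:02d}",
                    "group": g,
                    "age_years": float(rng.uniform(7, 17)),
                    "sex": "M" if rng.random() < 0.75 else "F",
                    "n_motion_free": float(nf + rng.normal(0, 80)),
                }
            )
    return pd.DataFrame(rows).set_index("subject_id")
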