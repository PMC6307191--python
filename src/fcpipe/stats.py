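"""Covariate-adjusted group inference over connectivity summaries.

Group comparisons follow one scheme throughout: a three-group ANCOVA
(ordinary least squares of the summary on two group indicators plus age,
sex and number of motion-free volumes, with an F-test on the group
indicators) where all three groups are compared, and pooled-variance
two-sample t-tests for pairwise contrasts.  Multiple comparisons are
corrected with Benjamini-Hochberg FDR *within* each analysis family (8
networks; 28 network pairs; all ROIs; all homotopic pairs) — families are
never pooled across analyses.  Dimensional analysis correlates IQ with
connectivity within a subgroup.  The GSR contrast compares the group-
difference pattern between the regression streams with and without the
global-signal regressor.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .simulate import GROUPS

ALPHA = 0.05
DESIGN_COLUMNS = ("group", "age_years", "sex", "n_motion_free")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class AncovaResult:
    F: float
    p: float
    adjusted_means: dict
    contrasts: dict  # (group_a, group_b) -> (t, p); difference a - b
    n: int


@dataclass
class GroupStatTable:
    """Per-family inference table with its FDR bookkeeping.

    ``table`` rows carry effect label, group means, the statistic, raw p,
    BH q and the q < alpha significance flag; ``m`` is the family size over
    which the correction ran.
    """

    family: str
    stream: str
    table: pd.DataFrame
    m: int
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        t = self.table
        if "q" in t.columns and len(t):
            order = np.argsort(t["p"].to_numpy())
            q_sorted = t["q"].to_numpy()[order]
            if np.any(np.diff(q_sorted) < -1e-12):
                raise ValueError("q values must be monotone nondecreasing in p")
            if not np.array_equal(
                t["significant"].to_numpy(), (t["q"].to_numpy() <= self.alpha)
            ):
                raise ValueError("significance flags inconsistent with q threshold")

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


@dataclass
class GsrContrastReport:
    """Stream comparison: medians, sign agreement and median-difference shift."""

    median_z: dict  # (stream, group) -> median pairwise z
    sign_agreement: dict  # contrast -> fraction of cells agreeing in sign
    median_diff: dict  # (stream, contrast) -> median per-cell group difference
    shift: dict  # contrast -> median_diff[nogsr] - median_diff[gsr]


# ---------------------------------------------------------------------------
# design handling
# ---------------------------------------------------------------------------
def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing_cols:
        raise ValueError(f"design table missing columns: {missing_cols}")
    if design[list(DESIGN_COLUMNS)].isna().any().any():
        raise ValueError("design table has missing covariate values")
    counts = design["group"].value_counts()
    for g in GROUPS:
        if counts.get(g, 0) < 2:
            raise ValueError(f"need >= 2 subjects per group; {g} has {counts.get(g, 0)}")
    return design


def _ancova_design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Intercept + HVCP/NT indicators + centred age, binary sex, centred
    motion-free count.  LVCP is the reference level."""
    g = design["group"].to_numpy()
    sex_codes = pd.Categorical(design["sex"]).codes.astype(float)
    cols = {
        "intercept": np.ones(len(design)),
        "group_HVCP": (g == "HVCP").astype(float),
        "group_NT": (g == "NT").astype(float),
        "age_years": design["age_years"].to_numpy(float) - design["age_years"].mean(),
        "sex": sex_codes - sex_codes.mean(),
        "n_motion_free": design["n_motion_free"].to_numpy(float)
        - design["n_motion_free"].mean(),
    }
    names = list(cols.keys())
    X = np.column_stack(list(cols.values()))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns (constant after centring, or aliased)
        bad = [
            n
            for n, c in cols.items()
            if n != "intercept" and np.allclose(c, c.mean())
        ]
        raise ValueError(
            f"rank-deficient ANCOVA design (rank {rank} < {X.shape[1]}); "
            f"degenerate columns: {bad or 'aliased group/covariate columns'}"
        )
    return X, names


def ancova_three_group(values: Sequence[float], design: pd.DataFrame) -> AncovaResult:
    """Three-group comparison adjusted for age, sex and motion-free volumes.

    OLS of the summary on an intercept, two group indicators and the three
    covariates; the group effect is the 2-df F-test on the indicators, and
    pairwise contrasts are unprotected t-statistics from the same fit.
    Adjusted group means are evaluated at the covariate means.
    """
    design = validate_design(design)
    y = np.asarray(values, dtype=float)
    if y.size != len(design):
        raise ValueError("values and design rows differ in length")
    X, names = _ancova_design_matrix(design)
    fit = sm.OLS(y, X).fit()
    R = np.zeros((2, X.shape[1]))
    R[0, 1] = 1.0
    R[1, 2] = 1.0
    ftest = fit.f_test(R)
    b = fit.params
    adjusted = {"LVCP": b[0], "HVCP": b[0] + b[1], "NT": b[0] + b[2]}
    contrasts = {}
    for (a, bg), vec in {
        ("HVCP", "LVCP"): [0, 1, 0, 0, 0, 0],
        ("NT", "LVCP"): [0, 0, 1, 0, 0, 0],
        ("NT", "HVCP"): [0, -1, 1, 0, 0, 0],
    }.items():
        tt = fit.t_test(np.array(vec, dtype=float))
        contrasts[(a, bg)] = (
            float(np.asarray(tt.tvalue).squeeze()),
            float(np.asarray(tt.pvalue).squeeze()),
        )
    return AncovaResult(
        F=float(ftest.fvalue),
        p=float(ftest.pvalue),
        adjusted_means={k: float(v) for k, v in adjusted.items()},
        contrasts=contrasts,
        n=y.size,
    )


def two_group_ttest(
    values_a: Sequence[float], values_b: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample t-test (pooled variance by default), two-tailed."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if equal_var:
        pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
            a.size + b.size - 2
        )
        if pooled == 0:
            raise ValueError("zero pooled variance; t statistic undefined")
    res = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def fdr_bh(
    pvalues: Sequence[float], alpha: float = ALPHA, family: str = ""
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q values, flags at q < alpha)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError(f"empty p-value family {family!r}")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError(f"p values outside [0, 1] in family {family!r}")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


# ---------------------------------------------------------------------------
# family analyses
# ---------------------------------------------------------------------------
def _group_values(values: np.ndarray, groups: np.ndarray) -> dict:
    return {g: values[groups == g] for g in GROUPS}


def _vectorised_pooled_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance t for each column of (subjects x cells) matrices."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(pooled * (1 / na + 1 / nb))


def _finish_table(rows: list, family: str, stream: str, alpha: float) -> GroupStatTable:
    df = pd.DataFrame(rows)
    q, flags = fdr_bh(df["p"].to_numpy(), alpha=alpha, family=family)
    df["q"] = q
    df["significant"] = flags
    return GroupStatTable(family=family, stream=stream, table=df, m=len(df), alpha=alpha)


def run_family_analyses(
    results: Mapping[str, object],
    design: pd.DataFrame,
    stream: str = "nogsr",
    alpha: float = ALPHA,
) -> dict[str, GroupStatTable]:
    """All per-family group analyses for one processing stream.

    Families (each with its own FDR scope):

    - ``within_network`` — per-network mean within-network z, three-group
      ANCOVA, corrected over the 8 networks.
    - ``between_network_<contrast>`` — per network pair, synchrony of network
      mean series, pooled t-tests for LVCP vs NT and LVCP vs HVCP, corrected
      over the 28 pairs per contrast, with the covariate-GLM group F as a
      robustness check column.
    - ``default_to_roi`` — default-network-to-ROI z, LVCP vs NT, corrected
      over all ROIs.
    - ``homotopic_<contrast>`` — per mirror pair, LVCP vs HVCP and LVCP vs
      NT, corrected over all pairs per contrast.

    ``results`` maps subject id -> ConnectivityResult; ``design`` is indexed
    by subject id with group/age/sex/motion-free columns.
    """
    design = validate_design(design)
    missing = [sid for sid in design.index if sid not in results]
    if missing:
        raise ValueError(f"missing connectivity bundles for subjects: {missing}")
    subjects = list(design.index)
    groups = design["group"].to_numpy()
    first = results[subjects[0]]
    networks = first.networks
    out: dict[str, GroupStatTable] = {}

    # --- within-network (ANCOVA over 8 networks) -----------------------
    rows = []
    for k, net in enumerate(networks):
        vals = np.array([results[s].within_mean[k] for s in subjects])
        res = ancova_three_group(vals, design)
        by_group = _group_values(vals, groups)
        t_hl, p_hl = res.contrasts[("HVCP", "LVCP")]
        t_nl, p_nl = res.contrasts[("NT", "LVCP")]
        rows.append(
            {
                "effect": net,
                "mean_LVCP": by_group["LVCP"].mean(),
                "mean_HVCP": by_group["HVCP"].mean(),
                "mean_NT": by_group["NT"].mean(),
                "statistic": res.F,
                "stat_name": "F",
                "p": res.p,
                "t_HVCP_vs_LVCP": t_hl,
                "t_NT_vs_LVCP": t_nl,
            }
        )
    out["within_network"] = _finish_table(rows, "within_network", stream, alpha)

    # --- between-network (t-tests per contrast + GLM check) ------------
    net_pairs = list(combinations(range(len(networks)), 2))
    pair_vals = np.array(
        [[results[s].between_z[i, j] for (i, j) in net_pairs] for s in subjects]
    )
    for contrast in (("LVCP", "NT"), ("LVCP", "HVCP")):
        rows = []
        for c, (i, j) in enumerate(net_pairs):
            vals = pair_vals[:, c]
            t, p = two_group_ttest(vals[groups == contrast[0]], vals[groups == contrast[1]])
            glm = ancova_three_group(vals, design)
            by_group = _group_values(vals, groups)
            rows.append(
                {
                    "effect": f"{networks[i]}~{networks[j]}",
                    "mean_LVCP": by_group["LVCP"].mean(),
                    "mean_HVCP": by_group["HVCP"].mean(),
                    "mean_NT": by_group["NT"].mean(),
                    "statistic": t,
                    "stat_name": "t",
                    "p": p,
                    "glm_F": glm.F,
                    "glm_p": glm.p,
                }
            )
        name = f"between_network_{contrast[0].lower()}_vs_{contrast[1].lower()}"
        out[name] = _finish_table(rows, name, stream, alpha)

    # --- default-network-to-ROI (LVCP vs NT over all ROIs) --------------
    roi_ids = first.roi_ids
    map_vals = np.array([results[s].net_to_roi["default"].to_numpy() for s in subjects])
    a = map_vals[groups == "LVCP"]
    b = map_vals[groups == "NT"]
    tstats = _vectorised_pooled_t(a, b)
    df_t = a.shape[0] + b.shape[0] - 2
    pvals = 2 * scipy.stats.t.sf(np.abs(tstats), df_t)
    rows = [
        {
            "effect": int(rid),
            "mean_LVCP": a[:, c].mean(),
            "mean_HVCP": map_vals[groups == "HVCP"][:, c].mean(),
            "mean_NT": b[:, c].mean(),
            "statistic": tstats[c],
            "stat_name": "t",
            "p": pvals[c],
        }
        for c, rid in enumerate(roi_ids)
    ]
    out["default_to_roi"] = _finish_table(rows, "default_to_roi", stream, alpha)

    # --- homotopic pairs (t-tests per contrast over all pairs) ----------
    left_ids = first.homotopic.index.to_numpy()
    homo_vals = np.array(
        [results[s].homotopic["z"].to_numpy() for s in subjects]
    )
    for contrast in (("LVCP", "HVCP"), ("LVCP", "NT")):
        a = homo_vals[groups == contrast[0]]
        b = homo_vals[groups == contrast[1]]
        tstats = _vectorised_pooled_t(a, b)
        df_t = a.shape[0] + b.shape[0] - 2
        pvals = 2 * scipy.stats.t.sf(np.abs(tstats), df_t)
        rows = [
            {
                "effect": int(lid),
                "mean_LVCP": homo_vals[groups == "LVCP"][:, c].mean(),
                "mean_HVCP": homo_vals[groups == "HVCP"][:, c].mean(),
                "mean_NT": homo_vals[groups == "NT"][:, c].mean(),
                "statistic": tstats[c],
                "stat_name": "t",
                "p": pvals[c],
            }
            for c, lid in enumerate(left_ids)
        ]
        name = f"homotopic_{contrast[0].lower()}_vs_{contrast[1].lower()}"
        out[name] = _finish_table(rows, name, stream, alpha)
    return out


# ---------------------------------------------------------------------------
# dimensional IQ analysis
# ---------------------------------------------------------------------------
def iq_connectivity_correlation(
    zmats: Sequence[np.ndarray], iq: Sequence[float], subgroup: Sequence[bool] | None = None
) -> np.ndarray:
    """Pearson r between IQ and each ROI-pair z across subjects.

    Returns an ROI x ROI symmetric matrix of correlations (diagonal NaN).
    ``subgroup`` restricts to a boolean-selected subset (e.g. one group).
    """
    zs = np.asarray(zmats, dtype=float)
    iqv = np.asarray(iq, dtype=float)
    if subgroup is not None:
        sel = np.asarray(subgroup, dtype=bool)
        zs, iqv = zs[sel], iqv[sel]
    if zs.shape[0] < 3:
        raise ValueError(f"need >= 3 subjects for IQ correlation, got {zs.shape[0]}")
    if np.ptp(iqv) == 0:
        raise ValueError("IQ is constant; correlation undefined")
    n_roi = zs.shape[1]
    iu = np.triu_indices(n_roi, k=1)
    flat = zs[:, iu[0], iu[1]]  # subjects x pairs
    fc = flat - flat.mean(axis=0)
    ic = iqv - iqv.mean()
    denom = np.linalg.norm(fc, axis=0) * np.linalg.norm(ic)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (fc * ic[:, None]).sum(axis=0) / denom
    mat = np.full((n_roi, n_roi), np.nan)
    mat[iu] = r
    mat[(iu[1], iu[0])] = r
    return mat


def scalar_iq_correlation(values: Sequence[float], iq: Sequence[float]) -> tuple[float, float]:
    """Pearson r (and p) between IQ and a scalar connectivity summary."""
    v = np.asarray(values, float)
    iqv = np.asarray(iq, float)
    if v.size < 3:
        raise ValueError("need >= 3 subjects")
    if np.ptp(iqv) == 0:
        raise ValueError("IQ is constant; correlation undefined")
    res = scipy.stats.pearsonr(v, iqv)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# GSR / non-GSR pattern contrast
# ---------------------------------------------------------------------------
def gsr_contrast(
    results_gsr: Mapping[str, object],
    results_nogsr: Mapping[str, object],
    design: pd.DataFrame,
) -> GsrContrastReport:
    """Compare group-difference patterns between the GSR and non-GSR streams.

    Reports, per stream: the median pairwise connection z per group; the
    per-cell group-difference t-map sign agreement between streams; and the
    shift in the median LVCP-vs-comparison difference between streams
    (positive shift = the non-GSR stream shows a broader deficit).
    """
    design = validate_design(design)
    if set(results_gsr) != set(results_nogsr):
        raise ValueError("GSR and non-GSR streams cover different subjects")
    missing = [s for s in design.index if s not in results_gsr]
    if missing:
        raise ValueError(f"missing subjects in stream bundles: {missing}")
    subjects = list(design.index)
    groups = design["group"].to_numpy()

    streams = {"gsr": results_gsr, "nogsr": results_nogsr}
    pair_z = {
        name: np.array([res[s].pairwise_z_values() for s in subjects])
        for name, res in streams.items()
    }
    median_z = {
        (name, g): float(np.median(pz[groups == g]))
        for name, pz in pair_z.items()
        for g in GROUPS
    }

    contrasts = {"lvcp_vs_hvcp": ("LVCP", "HVCP"), "lvcp_vs_nt": ("LVCP", "NT")}
    sign_agreement, median_diff, shift = {}, {}, {}
    for cname, (ga, gb) in contrasts.items():
        tmaps = {}
        for sname, pz in pair_z.items():
            a, b = pz[groups == ga], pz[groups == gb]
            tmaps[sname] = _vectorised_pooled_t(a, b)
            median_diff[(sname, cname)] = float(
                np.median(a.mean(axis=0) - b.mean(axis=0))
            )
        agree = np.sign(tmaps["gsr"]) == np.sign(tmaps["nogsr"])
        both_zero = (tmaps["gsr"] == 0) & (tmaps["nogsr"] == 0)
        sign_agreement[cname] = float(np.mean(agree | both_zero))
        shift[cname] = median_diff[("nogsr", cname)] - median_diff[("gsr", cname)]
    return GsrContrastReport(
        median_z=median_z,
        sign_agreement=sign_agreement,
        median_diff=median_diff,
        shift=shift,
    )
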