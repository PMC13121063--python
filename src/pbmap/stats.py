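"""Region statistics across a lesion cohort.

The statistical workflow mirrors common dermato-oncology imaging practice:
per-lesion region means (inner tumor, junction, surrounding skin) of the
four functional maps (initial intensity AF0 and decay parameters A, tau, C)
are the observation units — pixels within a lesion are spatially
autocorrelated, so pixel-level tests would wildly overstate n.  Group
homogeneity of variance is checked with Levene's test (group-mean
centering), omnibus group differences with the rank-based Kruskal–Wallis
test, and pairwise contrasts with Dunn's test under Bonferroni adjustment.

Levene and Kruskal–Wallis are delegated to scipy.stats; Dunn's z-statistics
on pooled ranks (with tie correction) are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stack_io import ParameterMaps
from .regions import RegionLabels

__all__ = [
    "summarize_regions",
    "levene_test",
    "kruskal_wallis",
    "dunn_bonferroni",
    "run_group_analysis",
    "significance_stars",
]

PARAMETERS = ("AF0", "A", "tau", "C")
REGIONS = ("inner", "junction", "skin")
# core superpixels report as the "inner" tumor region
_REGION_FROM_DESIGNATION = {"core": "inner", "junction": "junction", "skin": "skin"}


def summarize_regions(maps: ParameterMaps, regions: RegionLabels,
                      lesion_id: str, group: str) -> pd.DataFrame:
    """Per-region means of AF0/A/tau/C for one lesion.

    Returns up to 12 tidy rows (3 regions x 4 parameters); means are over
    valid (fit-ok) pixels only, and a region left empty after validity
    masking is omitted with a warning.
    """
    import warnings

    rows = []
    for designation, region in _REGION_FROM_DESIGNATION.items():
        sel = regions.mask(designation) & maps.mask
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"lesion {lesion_id}: region {region!r} empty after "
                          "validity masking; row omitted", stacklevel=2)
            continue
        for param in PARAMETERS:
            rows.append({
                "lesion_id": lesion_id,
                "group": group,
                "region": region,
                "parameter": param,
                "mean": float(maps.map_by_name(param)[sel].mean()),
                "n_pixels": n,
            })
    return pd.DataFrame(rows, columns=["lesion_id", "group", "region",
                                       "parameter", "mean", "n_pixels"])


def _check_groups(groups: list[np.ndarray], min_per_group: int = 1) -> list[np.ndarray]:
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < min_per_group for g in groups):
        raise ValueError(f"every group needs at least {min_per_group} observations")
    return groups


def levene_test(groups: list[np.ndarray]) -> tuple[float, float]:
    """Levene's homogeneity-of-variance test with group-mean centering.

    Returns (W, p) where p comes from the F(k-1, N-k) reference
    distribution.  W is a one-way F statistic on the absolute deviations
    from the group means, so edge cases follow the F: equal constant
    spreads in every group give W = 0; zero within-group spread with
    unequal between-group spreads gives W = inf (p = 0); all deviations
    identically zero (every observation equals its group mean) leaves W
    undefined and is rejected.
    """
    groups = _check_groups(groups, min_per_group=2)
    devs = [np.abs(g - g.mean()) for g in groups]
    pooled = np.concatenate(devs)
    if np.all(pooled == 0):
        raise ValueError("zero within-group deviation spread in all groups; "
                         "Levene W undefined")
    within_ss = sum(float(((d - d.mean()) ** 2).sum()) for d in devs)
    between_ss = sum(d.size * (d.mean() - pooled.mean()) ** 2 for d in devs)
    if within_ss == 0:
        return (0.0, 1.0) if between_ss == 0 else (np.inf, 0.0)
    w, p = sps.levene(*groups, center="mean")
    return float(w), float(p)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis rank-sum H with tie correction; p from chi-square(k-1)."""
    groups = _check_groups(groups)
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.ptp(pooled) == 0:
        raise ValueError("all observations identical; H undefined after tie correction")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def dunn_bonferroni(groups: list[np.ndarray],
                    labels: list[str] | None = None) -> pd.DataFrame:
    """Dunn's pairwise post-hoc test on pooled ranks, Bonferroni-adjusted.

    For groups i, j with pooled-rank means R_i, R_j and sizes n_i, n_j,

        z_ij = (R_i - R_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    where T = sum(t^3 - t) over tie groups.  Raw two-sided p-values come
    from the standard normal; adjusted p = min(1, m * p) with
    m = k(k-1)/2 pairs.
    """
    groups = _check_groups(groups)
    k = len(groups)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    pooled = np.concatenate(groups)
    N = pooled.size
    if np.ptp(pooled) == 0:
        raise ValueError("all observations identical; Dunn z undefined")
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    idx = np.cumsum([0] + sizes)
    rank_means = [ranks[idx[i]:idx[i + 1]].mean() for i in range(k)]

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))

    m = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (rank_means[i] - rank_means[j]) / se
            p_raw = 2.0 * sps.norm.sf(abs(z))
            rows.append({
                "group_a": labels[i], "group_b": labels[j],
                "z": float(z), "p_raw": float(p_raw),
                "p_adj": float(min(1.0, m * p_raw)),
            })
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """Conventional ladder: *** p<0.001, ** p<0.01, * p<0.05, '' otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupAnalysisResult:
    """Tidy results bundle from :func:`run_group_analysis`.

    ``omnibus`` has one row per tested contrast (Kruskal–Wallis H, p, plus
    Levene W, p for the same samples); ``pairwise`` the Dunn–Bonferroni
    table with stars.
    """

    omnibus: pd.DataFrame
    pairwise: pd.DataFrame

    def pairwise_lookup(self, contrast: str, parameter: str, a: str, b: str) -> pd.Series:
        t = self.pairwise
        sel = t[(t.contrast == contrast) & (t.parameter == parameter)
                & (((t.group_a == a) & (t.group_b == b))
                   | ((t.group_a == b) & (t.group_b == a)))]
        if len(sel) != 1:
            raise KeyError(f"no unique pairwise row for {contrast}/{parameter}/{a} vs {b}")
        return sel.iloc[0]


def run_group_analysis(table: pd.DataFrame) -> GroupAnalysisResult:
    """Run the full cohort analysis on a region-summary table.

    For each parameter:

    1. within each lesion group, compare the inner / junction / skin region
       means across lesions (omnibus Kruskal–Wallis + Dunn pairwise);
    2. compare the inner-region means across lesion groups.

    Lesion-level means are the observation units.  Contrasts with fewer
    than 2 observations per cell are skipped with a warning.
    """
    import warnings

    omnibus_rows, pairwise_frames = [], []

    def one_contrast(contrast: str, parameter: str,
                     samples: list[np.ndarray], labels: list[str]) -> None:
        if len(samples) < 2 or any(len(s) < 2 for s in samples):
            warnings.warn(f"contrast {contrast}/{parameter} skipped: "
                          "fewer than 2 observations per cell", stacklevel=3)
            return
        try:
            h, p_kw = kruskal_wallis(samples)
        except ValueError as exc:
            warnings.warn(f"contrast {contrast}/{parameter} skipped: {exc}", stacklevel=3)
            return
        try:
            w_lev, p_lev = levene_test(samples)
        except ValueError:
            w_lev, p_lev = np.nan, np.nan
        omnibus_rows.append({"contrast": contrast, "parameter": parameter,
                             "H": h, "p_kw": p_kw, "levene_W": w_lev,
                             "p_levene": p_lev, "stars": significance_stars(p_kw)})
        pw = dunn_bonferroni(samples, labels=labels)
        pw.insert(0, "parameter", parameter)
        pw.insert(0, "contrast", contrast)
        pw["stars"] = pw["p_adj"].map(significance_stars)
        pairwise_frames.append(pw)

    groups = sorted(table["group"].unique())
    for parameter in PARAMETERS:
        sub = table[table.parameter == parameter]
        # (i) regions within each group
        for group in groups:
            gsub = sub[sub.group == group]
            regions = [r for r in REGIONS if (gsub.region == r).any()]
            samples = [gsub.loc[gsub.region == r, "mean"].to_numpy() for r in regions]
            one_contrast(f"regions_within_{group}", parameter, samples, list(regions))
        # (ii) inner region across groups
        isub = sub[sub.region == "inner"]
        present = [g for g in groups if (isub.group == g).any()]
        samples = [isub.loc[isub.group == g, "mean"].to_numpy() for g in present]
        if len(present) >= 2:
            one_contrast("inner_across_groups", parameter, samples, list(present))

    omnibus = pd.DataFrame(omnibus_rows, columns=["contrast", "parameter", "H",
                                                  "p_kw", "levene_W", "p_levene", "stars"])
    pairwise = (pd.concat(pairwise_frames, ignore_index=True) if pairwise_frames
                else pd.DataFrame(columns=["contrast", "parameter", "group_a",
                                           "group_b", "z", "p_raw", "p_adj", "stars"]))
    return GroupAnalysisResult(omnibus=omnibus, pairwise=pairwise)
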