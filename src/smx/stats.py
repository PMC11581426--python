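"""Region-comparison statistics for pulse-chase turnover fractions.

Input is a tidy per-mouse, per-region table of population fractions
(``mouse_id, region, frac_a_only, frac_b_only, frac_mixed``).  The module
summarizes regions (mean +/- SD over mice), runs a one-way fixed-effects
ANOVA across regions for a chosen fraction, locates the source of
significance with pairwise two-sample t-tests (pooled-variance Student by
default, Welch optional; raw p-values, Bonferroni alongside), and
correlates the regional mixed fraction against user-supplied protein
half-lives with Pearson's test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FRACTION_COLUMNS",
    "RegionSummary",
    "StatReport",
    "summarize_regions",
    "anova_regions",
    "posthoc_ttests",
    "halflife_correlation",
    "region_report",
]

FRACTION_COLUMNS = ("frac_a_only", "frac_b_only", "frac_mixed")


def _check_fractions(table: pd.DataFrame):
    for col in ("mouse_id", "region", *FRACTION_COLUMNS):
        if col not in table.columns:
            raise ValueError(f"fraction table missing column {col!r}")
    vals = table[list(FRACTION_COLUMNS)].to_numpy(float)
    bad = np.flatnonzero((vals < 0).any(axis=1) | (vals > 1).any(axis=1))
    if bad.size:
        raise ValueError(f"fractions outside [0, 1] at row(s) {bad.tolist()}")


@dataclass
class RegionSummary:
    region: str
    n_mice: int
    mean: dict                    # fraction column -> mean over mice
    sd: dict                      # fraction column -> SD (NaN for 1 mouse)


def summarize_regions(table: pd.DataFrame) -> list[RegionSummary]:
    """Per-region mean and SD of each population fraction across mice."""
    _check_fractions(table)
    out = []
    for region, grp in table.groupby("region", sort=False):
        vals = grp[list(FRACTION_COLUMNS)]
        sd = (vals.std(ddof=1) if len(grp) > 1
              else pd.Series(np.nan, index=vals.columns))
        out.append(RegionSummary(region=str(region), n_mice=len(grp),
                                 mean=vals.mean().to_dict(), sd=sd.to_dict()))
    return out


def _groups(table, fraction):
    if fraction not in FRACTION_COLUMNS:
        raise ValueError(f"fraction must be one of {FRACTION_COLUMNS}")
    return [grp[fraction].to_numpy(float)
            for _, grp in table.groupby("region", sort=False)]


def anova_regions(table: pd.DataFrame, fraction: str = "frac_mixed"):
    """One-way fixed-effects ANOVA of a fraction across regions.

    Returns ``(F, p)``.  The degenerate all-groups-identical case (zero
    between-group sum of squares) returns ``(0, 1)``.
    """
    _check_fractions(table)
    groups = _groups(table, fraction)
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 regions with >= 2 mice each")
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    tol = 1e-12 * max(1.0, float(np.sum(allv**2)))
    if ssb <= tol:          # no between-group signal (identical means)
        return 0.0, 1.0
    if ssw <= tol:          # perfectly separated constant groups
        return float("inf"), 0.0
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def posthoc_ttests(table: pd.DataFrame, fraction: str = "frac_mixed",
                   equal_var: bool = True, bonferroni: bool = False) -> pd.DataFrame:
    """Pairwise two-sample t-tests between regions for one fraction.

    Returns a symmetric p-value matrix (regions x regions, diagonal NaN).
    Raw p-values by default; ``bonferroni=True`` multiplies by the number
    of pairs (capped at 1).  ``equal_var=False`` selects Welch's test.
    Identical groups return p = 1.
    """
    _check_fractions(table)
    regions = list(dict.fromkeys(table["region"]))
    groups = {r: table.loc[table["region"] == r, fraction].to_numpy(float)
              for r in regions}
    n_pairs = len(regions) * (len(regions) - 1) // 2
    mat = pd.DataFrame(np.nan, index=regions, columns=regions)
    for i, r1 in enumerate(regions):
        for r2 in regions[i + 1:]:
            g1, g2 = groups[r1], groups[r2]
            import warnings as _warnings
            with _warnings.catch_warnings():
                # near-identical groups trip scipy's precision-loss warning;
                # the NaN fallback below handles that case explicitly
                _warnings.simplefilter("ignore", RuntimeWarning)
                res = sps.ttest_ind(g1, g2, equal_var=equal_var)
            p = float(res.pvalue)
            if np.isnan(p):  # zero variance in both groups
                p = 1.0 if np.isclose(g1.mean(), g2.mean()) else 0.0
            if bonferroni:
                p = min(1.0, p * n_pairs)
            mat.loc[r1, r2] = mat.loc[r2, r1] = p
    return mat


def halflife_correlation(mixed_fractions, half_lives):
    """Pearson correlation of regional mixed fraction vs protein half-life.

    ``mixed_fractions`` and ``half_lives`` are paired per-region values
    (>= 3 pairs); half-lives are user-supplied external measurements.
    Returns ``(R, p)`` with the two-sided p-value from the t transform at
    n - 2 degrees of freedom; zero variance in either vector returns
    ``(NaN, NaN)``.
    """
    x = np.asarray(mixed_fractions, float)
    y = np.asarray(half_lives, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired region values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class StatReport:
    """Bundle of the full regional analysis."""

    summaries: list
    anova_p: dict                 # fraction column -> p-value
    ttest_matrix: pd.DataFrame    # for the mixed fraction
    pearson: tuple | None = None  # (R, p) vs half-life, when supplied

    def to_dict(self):
        return {
            "regions": [{"region": s.region, "n_mice": s.n_mice,
                         "mean": s.mean, "sd": s.sd} for s in self.summaries],
            "anova_p": self.anova_p,
            "ttest_p_mixed": self.ttest_matrix.to_dict(),
            "pearson_mixed_vs_halflife":
                None if self.pearson is None else
                {"R": self.pearson[0], "p": self.pearson[1]},
        }


def region_report(table: pd.DataFrame, half_lives: dict | None = None,
                  equal_var: bool = True) -> StatReport:
    """Run the full regional comparison on a tidy fraction table.

    ``half_lives`` optionally maps region -> half-life (days); when given,
    the regional mean mixed fractions are correlated against them.
    """
    summaries = summarize_regions(table)
    anova_p = {frac: anova_regions(table, frac)[1] for frac in FRACTION_COLUMNS}
    tmat = posthoc_ttests(table, "frac_mixed", equal_var=equal_var)
    pearson = None
    if half_lives:
        regions = [s.region for s in summaries if s.region in half_lives]
        mixed = [next(s.mean["frac_mixed"] for s in summaries if s.region == r)
                 for r in regions]
        pearson = halflife_correlation(mixed, [half_lives[r] for r in regions])
    return StatReport(summaries=summaries, anova_p=anova_p,
                      ttest_matrix=tmat, pearson=pearson)
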