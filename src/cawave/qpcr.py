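"""UPR qPCR expression analysis: 2^-dCt quantification and group tests.

Relative expression of unfolded-protein-response marker genes (BiP,
Chop, S-Xbp1, or any panel) is quantified against the Gapdh reference
by the 2^-dCt method, normalised to the mean of an unexposed control
group, and summarised per gene.  The per-sample Chop/S-Xbp1 ratio
indexes the balance of the UPR between its proapoptotic (CHOP) and
prohomeostatic (spliced Xbp1) arms; the reference gene cancels in the
ratio.

Quality control and statistics mirror common qPCR practice:

* samples with inadequate reference-gene signal (Gapdh Ct > 24) are
  excluded outright;
* a univariate adaptation of the ROUT robust-outlier procedure
  (median / RSDR residuals, two-tailed t p-values, Benjamini-Hochberg
  at FDR q = 1%) removes outliers in one pass;
* group comparisons are dispatched on per-group Shapiro-Wilk normality:
  Student's t (2 normal groups), Mann-Whitney (2 non-normal groups),
  or one-way ANOVA with Dunnett's comparisons against the control
  (> 2 groups).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: reference-gene quality cut: samples with Gapdh Ct above this are invalid
GAPDH_CT_MAX = 24.0
REFERENCE_GENE = "Gapdh"


@dataclass
class QpcrSample:
    """One animal's Ct values across genes."""

    animal_id: str
    group: str
    ct: dict  # gene -> Ct
    sex: str | None = None

    def __post_init__(self):
        if any(v <= 0 for v in self.ct.values()):
            raise ValueError("Ct values must be positive")

    @property
    def valid(self) -> bool:
        ref = self.ct.get(REFERENCE_GENE)
        return ref is not None and ref <= GAPDH_CT_MAX


@dataclass(frozen=True)
class OutlierParams:
    """FDR level and guard for ROUT-style outlier removal."""

    q: float = 0.01
    min_group_size: int = 5

    def __post_init__(self):
        if not 0 < self.q < 0.5:
            raise ValueError("q must lie in (0, 0.5)")


def samples_from_frame(df: pd.DataFrame) -> list[QpcrSample]:
    """Build samples from a long table (animal_id, group, [sex], gene, ct)."""
    out = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=False):
        sex = sub["sex"].iloc[0] if "sex" in sub else None
        out.append(
            QpcrSample(
                animal_id=str(animal),
                group=str(group),
                sex=sex,
                ct=dict(zip(sub["gene"], sub["ct"])),
            )
        )
    return out


def relative_expression(samples, gene: str, log=None) -> pd.DataFrame:
    """Per-sample relative expression ``2**-(Ct_gene - Ct_Gapdh)``.

    Invalid samples (Gapdh Ct > 24) and samples missing either Ct are
    excluded; exclusion reasons are appended to ``log`` when given.
    Returns a table with columns animal_id, group, expression.
    """
    rows = []
    for s in samples:
        if not s.valid:
            if log is not None:
                log.append(f"{s.animal_id}: excluded (Gapdh Ct > {GAPDH_CT_MAX} or missing)")
            continue
        if gene not in s.ct:
            if log is not None:
                log.append(f"{s.animal_id}: excluded for {gene} (missing Ct)")
            continue
        dct = s.ct[gene] - s.ct[REFERENCE_GENE]
        rows.append((s.animal_id, s.group, 2.0 ** (-dct)))
    return pd.DataFrame(rows, columns=["animal_id", "group", "expression"])


def fold_vs_control(expr: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Normalise expressions to the control-group mean.

    Adds a ``fold`` column; by construction the control group's folds
    average to exactly 1.
    """
    ctl = expr.loc[expr["group"] == control_group, "expression"]
    if len(ctl) == 0:
        raise ValueError(f"control group {control_group!r} is empty")
    out = expr.copy()
    out["fold"] = out["expression"] / ctl.mean()
    return out


def chop_xbp1_ratio(samples, chop: str = "Chop", xbp1: str = "S-Xbp1",
                    log=None) -> pd.DataFrame:
    """Per-sample ratio of Chop to S-Xbp1 relative expression.

    The Gapdh term cancels, so the ratio equals ``2**-(Ct_chop -
    Ct_xbp1)``; it is computed from the relative expressions so the
    same QC applies.
    """
    e_chop = relative_expression(samples, chop, log=log).set_index("animal_id")
    e_xbp = relative_expression(samples, xbp1, log=log).set_index("animal_id")
    common = e_chop.index.intersection(e_xbp.index)
    out = pd.DataFrame(
        {
            "group": e_chop.loc[common, "group"],
            "ratio": e_chop.loc[common, "expression"] / e_xbp.loc[common, "expression"],
        }
    ).reset_index()
    return out


def rout_outliers(values, params: OutlierParams = OutlierParams()):
    """Univariate ROUT-style outlier removal.

    Robust center = median; robust scale = RSDR, the 68.27th percentile
    of the absolute residuals with the small-sample correction
    ``n/(n-1)``.  Each point gets a two-tailed p-value from a
    t-distribution on its studentized residual; Benjamini-Hochberg at
    FDR level ``q`` flags outliers, removed in a single pass.  Groups
    below ``min_group_size`` are returned untouched.

    Returns ``(kept, removed)`` as arrays.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < params.min_group_size:
        return values, np.array([])
    resid = values - np.median(values)
    rsdr = np.percentile(np.abs(resid), 68.27) * n / (n - 1)
    if rsdr == 0:
        return values, np.array([])
    p = 2.0 * stats.t.sf(np.abs(resid) / rsdr, df=n - 1)
    flagged = multipletests(p, alpha=params.q, method="fdr_bh")[0]
    return values[~flagged], values[flagged]


@dataclass
class GroupComparison:
    """Report of one group-comparison dispatch."""

    test: str  # "t", "mann-whitney", "anova+dunnett"
    statistic: float
    pvalue: float
    n_per_group: dict
    normal_per_group: dict
    dunnett: pd.DataFrame | None = None  # per-treatment statistic & p


def compare_groups(values_by_group: dict, control: str | None = None,
                   alpha_normality: float = 0.05) -> GroupComparison:
    """Normality-dispatched comparison of 2 or more groups.

    Two groups: Student's two-tailed t if every group passes
    Shapiro-Wilk at ``alpha_normality``, else Mann-Whitney.  More than
    two groups: one-way ANOVA with Dunnett's post hoc comparisons
    against ``control``.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(v) < 3 for v in groups.values()):
        raise ValueError("every group needs n >= 3")
    normal = {}
    for k, v in groups.items():
        if np.ptp(v) == 0:
            normal[k] = False  # degenerate: Shapiro undefined, treat as non-normal
        else:
            normal[k] = stats.shapiro(v).pvalue > alpha_normality
    ns = {k: len(v) for k, v in groups.items()}

    if len(groups) == 2:
        a, b = groups.values()
        if all(normal.values()):
            res = stats.ttest_ind(a, b)
            return GroupComparison("t", float(res.statistic), float(res.pvalue), ns, normal)
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return GroupComparison("mann-whitney", float(res.statistic), float(res.pvalue),
                               ns, normal)

    if control is None or control not in groups:
        raise ValueError("a control group label is required for > 2 groups")
    res = stats.f_oneway(*groups.values())
    treatments = [k for k in groups if k != control]
    dn = stats.dunnett(*[groups[k] for k in treatments], control=groups[control])
    dunnett_df = pd.DataFrame(
        {"group": treatments, "statistic": dn.statistic, "pvalue": dn.pvalue}
    )
    return GroupComparison("anova+dunnett", float(res.statistic), float(res.pvalue),
                           ns, normal, dunnett=dunnett_df)


def panel_analysis(
    samples,
    genes,
    control_group: str,
    outliers: OutlierParams | None = OutlierParams(),
) -> pd.DataFrame:
    """Per-gene fold-change summary with per-gene two-tailed t-tests.

    For every gene: relative expression, fold vs the control mean, and
    a two-tailed Student's t comparing the 2^-dCt values of each
    non-control group against control (run per gene, no cross-gene
    correction).  ROUT outlier removal is applied per group when
    ``outliers`` is given.  Returns one row per (gene, group).
    """
    rows = []
    for gene in genes:
        expr = relative_expression(samples, gene)
        if outliers is not None:
            kept_parts = []
            for g, sub in expr.groupby("group", sort=False):
                kept, _ = rout_outliers(sub["expression"].to_numpy(), outliers)
                kept_parts.append(pd.DataFrame({"group": g, "expression": kept}))
            expr = pd.concat(kept_parts, ignore_index=True)
        expr = fold_vs_control(expr, control_group)
        ctl = expr.loc[expr["group"] == control_group, "expression"].to_numpy()
        for g, sub in expr.groupby("group", sort=False):
            vals = sub["expression"].to_numpy()
            if g == control_group or len(vals) < 3 or len(ctl) < 3:
                pval = np.nan
            else:
                pval = float(stats.ttest_ind(vals, ctl).pvalue)
            rows.append(
                (gene, g, len(vals), float(sub["fold"].mean()),
                 float(sub["fold"].std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
                 pval)
            )
    return pd.DataFrame(rows, columns=["gene", "group", "n", "fold_mean", "fold_sem", "p"])
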