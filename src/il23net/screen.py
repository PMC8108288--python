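"""Paired nonparametric screening of secreted-protein panels and DE lists.

The workhorse contrast compares each analyte between two culture conditions
within donors: fold-changes are per-donor ratios (averaged arithmetically
across donors), significance comes from the paired Wilcoxon signed-rank
test, and multiplicity is handled by Benjamini-Hochberg across the analytes
of a contrast.  An analyte passes the screen when both the fold-change and
the adjusted-p thresholds are met.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ode import EPSILON


@dataclass
class ScreenResult:
    """Per-analyte screen statistics and the pass set."""

    table: pd.DataFrame  # columns: analyte, mean_fc, p, p_adj, passed
    fc_threshold: float
    alpha: float

    @property
    def passed(self) -> list[str]:
        return self.table.loc[self.table["passed"], "analyte"].tolist()


def validate_panel(panel: pd.DataFrame) -> None:
    """Reject malformed tidy panels (duplicate wells, negative values)."""
    required = {"donor_id", "condition_id", "analyte", "concentration_pg_ml"}
    missing = required - set(panel.columns)
    if missing:
        raise ValueError(f"panel lacks columns {sorted(missing)}")
    if (panel["concentration_pg_ml"] < 0).any():
        raise ValueError("concentrations must be >= 0")
    dup = panel.duplicated(["donor_id", "condition_id", "analyte"])
    if dup.any():
        raise ValueError("duplicate (donor, condition, analyte) entries")


def paired_fold_changes(
    panel: pd.DataFrame,
    ref: str,
    test: str,
    floor: float = EPSILON,
) -> pd.DataFrame:
    """Per-donor test/ref concentration ratios and their mean per analyte.

    Reference concentrations are floored at the detection limit before
    division.  The summary is the mean of per-donor ratios (not the ratio
    of mean concentrations).  Donors missing either condition are dropped
    with a warning; returns a frame with columns ``analyte``, ``mean_fc``,
    ``n_donors`` plus the per-donor ratio matrix in ``.attrs['ratios']``.
    """
    validate_panel(panel)
    wide = panel.pivot_table(
        index=["analyte", "donor_id"], columns="condition_id",
        values="concentration_pg_ml", aggfunc="first",
    )
    for cond in (ref, test):
        if cond not in wide.columns:
            raise ValueError(f"condition {cond!r} absent from panel")
    pair = wide[[ref, test]].dropna()
    dropped = len(wide) - len(pair)
    if dropped:
        warnings.warn(f"dropped {dropped} donor/analyte pairs missing a condition")
    if pair.empty:
        raise ValueError(f"no donor has both {ref!r} and {test!r}")
    ratios = pair[test] / np.maximum(pair[ref], floor)
    ratio_mat = ratios.unstack("analyte")
    out = pd.DataFrame(
        {
            "analyte": ratio_mat.columns,
            "mean_fc": ratio_mat.mean(axis=0).to_numpy(),
            "n_donors": ratio_mat.notna().sum(axis=0).to_numpy(),
        }
    ).reset_index(drop=True)
    out.attrs["ratios"] = ratio_mat
    return out


def wilcoxon_paired(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 25
) -> tuple[float, bool]:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are discarded; the exact null distribution is used for
    n <= ``exact_max_n`` without ties, otherwise the normal approximation
    with tie and continuity correction.  Returns ``(p, degenerate)`` where
    degenerate marks the all-differences-zero case (p = 1 by convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        return 1.0, True
    if d.size < 3:
        # too few informative pairs for any rejection at usual alpha
        return 1.0, True
    has_ties = len(np.unique(np.abs(d))) < d.size
    if d.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    return float(res.pvalue), False


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_induced(
    panel: pd.DataFrame,
    ref: str,
    test: str,
    fc_threshold: float = 4.0,
    alpha: float = 0.05,
) -> ScreenResult:
    """Induced-secretion screen: fold-change and BH-adjusted paired Wilcoxon.

    An analyte passes iff mean per-donor fold-change >= ``fc_threshold``
    and BH-adjusted p < ``alpha``, with BH applied across all analytes of
    the contrast.
    """
    fc = paired_fold_changes(panel, ref, test)
    ratio_mat = fc.attrs["ratios"]
    n_min = int(ratio_mat.notna().sum(axis=0).min())
    if n_min < 3:
        raise ValueError("screen needs >= 3 paired donors per analyte")
    wide = panel.pivot_table(
        index=["analyte", "donor_id"], columns="condition_id",
        values="concentration_pg_ml", aggfunc="first",
    )[[ref, test]].dropna()
    pvals = []
    for analyte in fc["analyte"]:
        sub = wide.xs(analyte, level="analyte")
        p, _ = wilcoxon_paired(sub[test].to_numpy(), sub[ref].to_numpy())
        pvals.append(p)
    fc["p"] = pvals
    fc["p_adj"] = bh_adjust(pvals)
    fc["passed"] = (fc["mean_fc"] >= fc_threshold) & (fc["p_adj"] < alpha)
    return ScreenResult(table=fc, fc_threshold=fc_threshold, alpha=alpha)


def de_screen(
    expr: pd.DataFrame,
    groups: pd.Series,
    ref: str,
    test: str,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    paired: bool = False,
) -> pd.DataFrame:
    """Gene-wise differential-expression screen on log2-scale expression.

    Same logic as the secretome screen applied per gene: fold-change
    (2^(mean log2 difference)), rank test (paired Wilcoxon when ``paired``
    and sample orders correspond, else Mann-Whitney), BH across genes.
    Returns a frame with ``log2_fc``, ``p``, ``p_adj``, ``direction``
    (up/down/ns).
    """
    groups = groups.reindex(expr.columns)
    for level in (ref, test):
        if not (groups == level).any():
            raise ValueError(f"contrast level {level!r} absent")
    a = expr.loc[:, (groups == ref).to_numpy()]
    b = expr.loc[:, (groups == test).to_numpy()]
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    pvals = np.ones(expr.shape[0])
    for i in range(expr.shape[0]):
        xa, xb = a.iloc[i].to_numpy(), b.iloc[i].to_numpy()
        if paired:
            if xa.size != xb.size:
                raise ValueError("paired contrast requires equal group sizes")
            pvals[i], _ = wilcoxon_paired(xb, xa)
        else:
            if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
                pvals[i] = 1.0
            else:
                pvals[i] = stats.mannwhitneyu(
                    xb, xa, alternative="two-sided"
                ).pvalue
    out = pd.DataFrame(
        {"log2_fc": log2fc, "p": pvals, "p_adj": bh_adjust(pvals)},
        index=expr.index,
    )
    thr = np.log2(fc_threshold)
    sig = out["p_adj"] < alpha
    out["direction"] = np.where(
        sig & (out["log2_fc"] >= thr), "up",
        np.where(sig & (out["log2_fc"] <= -thr), "down", "ns"),
    )
    return out
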