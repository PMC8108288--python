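"""Coexpression-module detection, eigengenes, and signature partitioning.

A reduced weighted gene correlation network analysis (WGCNA): signed
adjacency ((1 + r)/2)^power, topological-overlap dissimilarity,
average-linkage clustering cut at a fixed height, modules below a size
floor left unassigned.  Module eigengenes (first principal component of
the standardised module submatrix) are correlated with sample traits, and
a monocyte signature is partitioned by which of the inflammatory-cytokine
and lymphocyte-differentiation eigengenes each gene tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .screen import bh_adjust

PARTITION_CLASSES = ("inflammatory_only", "both", "lymphoid_only", "unassigned")


@dataclass
class ModuleSet:
    """Gene-to-module assignment with per-module eigengenes."""

    labels: pd.Series  # gene -> module name ("unassigned" allowed)
    eigengenes: pd.DataFrame  # samples x modules, unit norm per column
    sizes: dict[str, int] = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.columns]

    def genes_in(self, module: str) -> list[str]:
        return self.labels.index[self.labels == module].tolist()


def eigengene(expr: pd.DataFrame, genes: list[str]) -> pd.Series:
    """First principal component of the standardised module submatrix.

    Unit norm across samples, sign-oriented so the mean correlation with
    the module's genes is non-negative.  ``expr`` is genes x samples.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("module needs >= 2 genes")
    sub = expr.loc[genes].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    if np.all(sd == 0):
        raise ValueError("all module genes constant; eigengene undefined")
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant genes from module")
        sub, sd = sub[keep], sd[keep]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    # first right singular vector = leading PC over samples
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eg = vt[0]
    if np.mean(z @ eg) < 0:  # orient towards the module
        eg = -eg
    eg = eg / np.linalg.norm(eg)
    return pd.Series(eg, index=expr.columns)


def _tom_dissimilarity(adj: np.ndarray) -> np.ndarray:
    """Unsigned topological-overlap dissimilarity of an adjacency matrix."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    L = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    tom = (L + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return 1.0 - tom


def detect_modules(
    expr: pd.DataFrame,
    soft_power: float = 6.0,
    min_module_size: int = 30,
    cut_height: float = 0.7,
    top_n_variance: int | None = None,
) -> ModuleSet:
    """Reduced WGCNA module detection on a genes x samples matrix.

    Signed adjacency ((1 + cor)/2)^soft_power, TOM dissimilarity,
    average-linkage hierarchical clustering cut at ``cut_height`` (on the
    cophenetic distance), clusters below ``min_module_size`` merged into
    ``"unassigned"``.  Modules are named M1, M2, ... by decreasing size.
    """
    if expr.shape[1] < 20:
        raise ValueError("module detection needs >= 20 samples")
    if top_n_variance is not None:
        var = expr.var(axis=1)
        expr = expr.loc[var.sort_values(ascending=False).index[:top_n_variance]]
    sd = expr.std(axis=1, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"dropping {int((sd == 0).sum())} constant genes")
        expr = expr.loc[sd > 0]
    genes = expr.index.tolist()
    cor = np.corrcoef(expr.to_numpy(dtype=float))
    adj = ((1.0 + cor) / 2.0) ** soft_power
    diss = _tom_dissimilarity(adj)
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")

    labels = pd.Series("unassigned", index=genes, dtype=object)
    counts = pd.Series(raw).value_counts()
    big = counts[counts >= min_module_size].index.tolist()
    big.sort(key=lambda c: -counts[c])
    for rank, cl in enumerate(big, start=1):
        labels[np.asarray(raw) == cl] = f"M{rank}"

    egs, sizes = {}, {}
    for m in sorted({l for l in labels if l != "unassigned"},
                    key=lambda s: int(s[1:])):
        member = labels.index[labels == m].tolist()
        egs[m] = eigengene(expr, member)
        sizes[m] = len(member)
    eig = pd.DataFrame(egs, index=expr.columns) if egs else pd.DataFrame(
        index=expr.columns)
    return ModuleSet(labels=labels, eigengenes=eig, sizes=sizes)


def module_trait_correlation(
    moduleset: ModuleSet, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each numeric trait.

    Binary traits must be coded 0/1.  BH adjustment is applied across all
    module x trait tests; constant traits are reported with NaN r/p.
    """
    rows = []
    for m in moduleset.modules:
        eg = moduleset.eigengenes[m].to_numpy()
        for trait in traits.columns:
            t = pd.to_numeric(traits[trait], errors="coerce").to_numpy(dtype=float)
            if np.nanstd(t) == 0:
                rows.append((m, trait, np.nan, np.nan))
                continue
            ok = ~np.isnan(t)
            r, p = stats.pearsonr(eg[ok], t[ok])
            rows.append((m, trait, r, p))
    out = pd.DataFrame(rows, columns=["module", "trait", "r", "p"])
    mask = out["p"].notna()
    out["p_adj"] = np.nan
    out.loc[mask, "p_adj"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


def partition_signature(
    signature_genes: list[str],
    expr: pd.DataFrame,
    eigengene_infl: pd.Series,
    eigengene_lymph: pd.Series,
    alpha: float = 0.05,
    r_min: float = 0.3,
) -> pd.DataFrame:
    """Three-way partition of signature genes by eigengene correlation.

    A gene "correlates" with an eigengene iff r >= r_min and BH-adjusted
    p < alpha (BH across signature genes x 2 eigengenes).  Classes:
    inflammatory_only, both, lymphoid_only, unassigned.  Genes absent from
    ``expr`` are reported with class ``"missing"`` and NaN statistics.
    """
    present = [g for g in signature_genes if g in expr.index]
    absent = [g for g in signature_genes if g not in expr.index]
    if absent:
        warnings.warn(f"{len(absent)} signature genes absent from expression")
    rows = {}
    pvals = []
    for g in present:
        x = expr.loc[g].to_numpy(dtype=float)
        stats_g = {}
        for name, eg in (("infl", eigengene_infl), ("lymph", eigengene_lymph)):
            if np.std(x) == 0:
                r, p = 0.0, 1.0
            else:
                r, p = stats.pearsonr(x, eg.reindex(expr.columns).to_numpy())
            stats_g[f"r_{name}"] = r
            stats_g[f"p_{name}"] = p
            pvals.append(p)
        rows[g] = stats_g
    padj = bh_adjust(pvals) if pvals else np.array([])
    out = pd.DataFrame.from_dict(rows, orient="index")
    if not out.empty:
        out["p_adj_infl"] = padj[0::2]
        out["p_adj_lymph"] = padj[1::2]
        hit_i = (out["r_infl"] >= r_min) & (out["p_adj_infl"] < alpha)
        hit_l = (out["r_lymph"] >= r_min) & (out["p_adj_lymph"] < alpha)
        out["class"] = np.select(
            [hit_i & hit_l, hit_i, hit_l],
            ["both", "inflammatory_only", "lymphoid_only"],
            default="unassigned",
        )
    for g in absent:
        out.loc[g, "class"] = "missing"
    return out.reindex([g for g in signature_genes if g in out.index])
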