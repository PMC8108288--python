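"""Condition-specific marker derivation from labelled single-cell counts.

Defines the reproducible surrogate for curating an IL-10-regulated
monocyte signature: a gene belongs to the signature of a target condition
iff, against *every* other condition, it clears a BH-adjusted rank-sum
test, a fold-change floor, and a minimum detection fraction in the target
condition's cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .screen import bh_adjust


@dataclass
class ConditionMarkerResult:
    """Per-gene contrast statistics and the derived signature."""

    table: pd.DataFrame  # per gene: log2fc_vs_*, p_adj_vs_*, detect_frac, specific
    target: str
    fc_threshold: float
    alpha: float
    min_detect_frac: float

    @property
    def signature(self) -> list[str]:
        return self.table.index[self.table["specific"]].tolist()


def normalize_counts(X: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """Counts-per-``scale`` per cell followed by log1p."""
    X = np.asarray(X, dtype=float)
    depth = X.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    return np.log1p(X / depth * scale)


def condition_marker_genes(
    adata: ad.AnnData,
    target: str,
    condition_key: str = "condition",
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    min_detect_frac: float = 0.1,
) -> ConditionMarkerResult:
    """Genes specific to ``target`` versus every other condition.

    Counts are depth-normalised (counts-per-10k, log1p) before testing.
    Per contrast: two-sided Mann-Whitney rank-sum p (BH-adjusted across
    genes within the contrast) and log2 fold-change of mean normalised
    expression with a pseudocount of 1.  A gene is flagged specific iff it
    passes p_adj < alpha and log2fc >= log2(fc_threshold) in *all*
    contrasts and is detected in >= ``min_detect_frac`` of target cells.
    """
    labels = adata.obs[condition_key].astype(str)
    conditions = labels.unique().tolist()
    if target not in conditions:
        raise ValueError(f"target condition {target!r} absent from labels")
    others = [c for c in conditions if c != target]
    if not others:
        raise ValueError("need >= 2 conditions")

    X = adata.X
    X = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
    norm = normalize_counts(X)
    tmask = (labels == target).to_numpy()
    tgt = norm[tmask]
    detect_frac = (X[tmask] > 0).mean(axis=0)

    table = pd.DataFrame(index=adata.var_names)
    table["detect_frac"] = detect_frac
    ok_all = detect_frac >= min_detect_frac
    thr = np.log2(fc_threshold)
    mean_t = np.expm1(tgt).mean(axis=0)
    for other in others:
        omask = (labels == other).to_numpy()
        oth = norm[omask]
        mean_o = np.expm1(oth).mean(axis=0)
        log2fc = np.log2((mean_t + 1.0) / (mean_o + 1.0))
        pvals = np.ones(norm.shape[1])
        for gi in range(norm.shape[1]):
            a, b = tgt[:, gi], oth[:, gi]
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                continue  # identical constant distributions: p = 1
            pvals[gi] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        padj = bh_adjust(pvals)
        table[f"log2fc_vs_{other}"] = log2fc
        table[f"p_vs_{other}"] = pvals
        table[f"p_adj_vs_{other}"] = padj
        ok_all = ok_all & (padj < alpha) & (log2fc >= thr)
    table["specific"] = ok_all
    return ConditionMarkerResult(
        table=table, target=target, fc_threshold=fc_threshold,
        alpha=alpha, min_detect_frac=min_detect_frac,
    )


def write_gmt(path, set_name: str, description: str, genes: list[str]) -> None:
    """Emit a one-line GMT gene-set file."""
    with open(path, "w") as fh:
        fh.write("\t".join([set_name, description, *genes]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file into {set name: gene list}."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                sets[parts[0]] = parts[2:]
    return sets
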