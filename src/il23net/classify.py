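"""Per-gene AUPRC evaluation of signature subsets.

Each gene is a single-feature classifier (higher expression predicts the
positive class); performance is the area under the precision-recall curve
in its average-precision form, the random baseline is the positive-class
prevalence, and subsets from the signature partition are compared by
rank tests on their per-gene AUPRC distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .screen import bh_adjust


def gene_auprc(scores, labels) -> float:
    """Average precision of one score vector against binary labels.

    Step-wise AP: sum over positives, in descending score order, of the
    precision at that rank, divided by the number of positives.  Tied
    scores are treated as one block (the block's positives all receive the
    precision at the block's end), so constant scores yield the prevalence.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order].astype(float)
    # block boundaries: last index of each tied-score run
    boundary = np.nonzero(np.diff(s))[0]
    ends = np.append(boundary, s.size - 1)
    tp = np.cumsum(y)[ends]
    n_at = ends + 1.0
    precision = tp / n_at
    block_pos = np.diff(np.concatenate([[0.0], tp]))
    return float(np.sum(precision * block_pos) / n_pos)


def random_baseline(labels) -> float:
    """Prevalence of the positive class: the chance-level AUPRC."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("labels must be non-empty")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return float(np.mean(y))


def compare_subsets(
    auprc_by_subset: dict[str, np.ndarray], min_genes: int = 2
) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests on per-gene AUPRC lists.

    Subsets with fewer than ``min_genes`` genes are excluded with a
    warning; BH adjustment across the tested pairs.
    """
    usable = {}
    for name, vals in auprc_by_subset.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < min_genes:
            warnings.warn(f"subset {name!r} has < {min_genes} genes; excluded")
            continue
        usable[name] = vals
    names = sorted(usable)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = usable[a], usable[b]
            if np.all(va[:, None] == vb[None, :]):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(va, vb,
                                             alternative="two-sided").pvalue)
            rows.append((a, b, float(np.median(va)), float(np.median(vb)), p))
    out = pd.DataFrame(
        rows, columns=["subset_a", "subset_b", "median_a", "median_b", "p"]
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out


@dataclass
class PartitionEvaluation:
    per_gene: pd.DataFrame  # gene, subset, task, auprc, baseline
    comparisons: pd.DataFrame  # subset_a, subset_b, task, p, p_adj


def evaluate_partition(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    partition: pd.DataFrame,
    tasks: dict[str, str] | None = None,
) -> PartitionEvaluation:
    """Per-gene AUPRC for each task, grouped and compared by partition class.

    ``partition`` is the frame from
    :func:`il23net.deconv.partition_signature` (index = genes, column
    ``class``).  ``tasks`` maps task name -> metadata column holding binary
    or {CD, control}-style labels; defaults to diagnosis (CD positive) and
    anti-TNF non-response.  Tasks whose labels are missing are skipped with
    a notice.
    """
    if tasks is None:
        tasks = {"diagnosis": "diagnosis", "nonresponse": "nonresponder"}
    genes = [g for g in partition.index
             if partition.loc[g, "class"] != "missing" and g in expr.index]

    per_gene_rows = []
    comp_frames = []
    for task, col in tasks.items():
        if col not in metadata.columns:
            warnings.warn(f"metadata lacks column {col!r}; task {task!r} skipped")
            continue
        raw = metadata[col].reindex(expr.columns)
        if raw.dtype == object:
            pos = "CD" if "CD" in set(raw) else sorted(set(raw))[0]
            y = (raw == pos).to_numpy().astype(int)
        else:
            y = raw.to_numpy().astype(int)
        if len(set(y)) < 2:
            warnings.warn(f"task {task!r} has one class; skipped")
            continue
        baseline = random_baseline(y)
        by_subset: dict[str, list[float]] = {}
        for g in genes:
            ap = gene_auprc(expr.loc[g].to_numpy(dtype=float), y)
            subset = partition.loc[g, "class"]
            per_gene_rows.append((g, subset, task, ap, baseline))
            by_subset.setdefault(subset, []).append(ap)
        comp = compare_subsets({k: np.array(v) for k, v in by_subset.items()})
        comp.insert(2, "task", task)
        comp_frames.append(comp)

    per_gene = pd.DataFrame(
        per_gene_rows, columns=["gene", "subset", "task", "auprc", "baseline"]
    )
    comparisons = (
        pd.concat(comp_frames, ignore_index=True)
        if comp_frames
        else pd.DataFrame(columns=["subset_a", "subset_b", "task",
                                   "median_a", "median_b", "p", "p_adj"])
    )
    if not comparisons.empty:
        comparisons["p_adj"] = bh_adjust(comparisons["p"].to_numpy())
    return PartitionEvaluation(per_gene=per_gene, comparisons=comparisons)
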