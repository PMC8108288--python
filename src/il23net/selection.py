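"""Candidate-edge screening, configuration enumeration, AIC ranking and
edge weighting for the monocyte cytokine network.

The model-selection space is the power set of an a-priori admissible edge
set: an ordered cytokine pair (j -> i) is admissible only if a donor-paired
Wilcoxon contrast of analyte i between conditions differing solely in the
addition or blockade of j survives Benjamini-Hochberg FDR correction.
Every admissible-edge subset is fitted with the ODE model and ranked by
AIC; edge weights of a chosen configuration are normalised
leave-one-edge-out AIC increments, and in-silico mediation quantifies how
much of a perturbation's effect on a target travels through a given node.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ode
from .ode import (
    ALL_NODES,
    EPSILON,
    MODELLED_NODES,
    Condition,
    FitResult,
    ModelParams,
    NetworkConfig,
)
from .screen import bh_adjust, validate_panel, wilcoxon_paired


@dataclass
class CandidateEdge:
    source: str
    target: str
    sign: int
    p: float
    p_adj: float
    admissible: bool
    contrast: tuple[str, str] | None = None  # (ref, test) condition names


@dataclass
class CandidateEdgeSet:
    """Screened directed edges; the a-priori admissible model space."""

    edges: list[CandidateEdge]
    mandatory: frozenset[tuple[str, str, int]] = frozenset()
    alpha: float = 0.05

    def admissible_edges(self) -> list[tuple[str, str, int]]:
        return sorted(
            (e.source, e.target, e.sign) for e in self.edges if e.admissible
        )

    @property
    def n_admissible(self) -> int:
        return sum(e.admissible for e in self.edges)

    @staticmethod
    def from_edges(edges, mandatory=()) -> "CandidateEdgeSet":
        """Build an already-admissible candidate set (e.g. from ground truth)."""
        return CandidateEdgeSet(
            edges=[CandidateEdge(s, t, g, 0.0, 0.0, True) for s, t, g in edges],
            mandatory=frozenset(tuple(e) for e in mandatory),
        )


def _perturbation_contrasts(conditions: list[Condition]):
    """Yield (source j, ref, test, kind) for condition pairs differing only
    by one addition or one single-ligand blockade of j."""
    def key(c: Condition):
        return (c.stimulus, frozenset(c.additions), c.blocked_ligands())

    for ref, test in itertools.permutations(conditions, 2):
        kr, kt = key(ref), key(test)
        if kr[0] != kt[0]:
            continue
        added = kt[1] - kr[1]
        blocked = kt[2] - kr[2]
        if len(added) == 1 and kr[1] == kt[1] - added and kr[2] == kt[2]:
            (j, _dose), = added
            yield j, ref, test, "addition"
        elif len(blocked) == 1 and kr[2] == kt[2] - blocked and kr[1] == kt[1]:
            (j,) = blocked
            yield j, ref, test, "blockade"


def screen_candidate_edges(
    panel: pd.DataFrame,
    conditions: list[Condition],
    alpha: float = 0.05,
    mandatory=(),
) -> CandidateEdgeSet:
    """FDR-screened candidate edges from donor-paired perturbation contrasts.

    For each ordered pair (j, i): find a condition pair differing only by
    addition (preferred) or blockade of j, run the paired Wilcoxon on
    analyte i across it, and BH-adjust across all tested pairs.  Sign is
    +1 when adding j raises i (equivalently blocking j lowers it).  Pairs
    with no available contrast are untested and inadmissible.
    """
    validate_panel(panel)
    wide = panel.pivot_table(
        index=["analyte", "donor_id"], columns="condition_id",
        values="concentration_pg_ml", aggfunc="first",
    )
    contrasts: dict[str, tuple[Condition, Condition, str]] = {}
    for j, ref, test, kind in _perturbation_contrasts(conditions):
        # additions take precedence: cleaner single-node perturbations
        if j not in contrasts or (kind == "addition" and contrasts[j][2] != "addition"):
            contrasts[j] = (ref, test, kind)

    rows = []
    for j in ALL_NODES:
        if j not in contrasts:
            continue
        ref, test, kind = contrasts[j]
        for i in MODELLED_NODES:
            if i == j:
                continue
            sub = wide.xs(i, level="analyte")[[ref.name, test.name]].dropna()
            if len(sub) < 3:
                continue
            x, y = sub[test.name].to_numpy(), sub[ref.name].to_numpy()
            p, _ = wilcoxon_paired(x, y)
            delta = np.median(np.log(np.maximum(x, EPSILON))
                              - np.log(np.maximum(y, EPSILON)))
            direction = 1 if delta > 0 else -1
            sign = direction if kind == "addition" else -direction
            rows.append((j, i, sign, p, (ref.name, test.name)))

    padj = bh_adjust([r[3] for r in rows]) if rows else np.array([])
    edges = [
        CandidateEdge(j, i, s, p, pa, bool(pa < alpha), contrast=ct)
        for (j, i, s, p, ct), pa in zip(rows, padj)
    ]
    return CandidateEdgeSet(
        edges=edges, mandatory=frozenset(tuple(e) for e in mandatory), alpha=alpha
    )


# ---------------------------------------------------------------------------
# configuration enumeration


class ConfigurationSpace:
    """Lazy enumeration over admissible-edge subsets.

    ``total_configurations`` is computed analytically (2^E - 1 in the
    unconstrained case); iterating a space with E above ``hard_cap`` free
    edges and no ``max_edges`` bound is refused.
    """

    def __init__(self, cand: CandidateEdgeSet, max_edges: int | None = None,
                 hard_cap: int = 24):
        self.admissible = cand.admissible_edges()
        self.mandatory = sorted(cand.mandatory)
        for e in self.mandatory:
            if e not in self.admissible:
                raise ValueError(f"mandatory edge {e} is not admissible")
        self.optional = [e for e in self.admissible if e not in cand.mandatory]
        self.max_edges = max_edges
        self.hard_cap = hard_cap
        if not self.admissible:
            raise ValueError("no admissible edges to enumerate")

    @property
    def n_admissible(self) -> int:
        return len(self.admissible)

    @property
    def total_configurations(self) -> int:
        """Number of configurations, counted without enumeration."""
        E, m = len(self.optional), len(self.mandatory)
        if self.max_edges is None:
            total = 1 << E  # all optional subsets
            return total - 1 if m == 0 else total  # non-empty overall
        budget = self.max_edges - m
        if budget < 0:
            return 0
        total = sum(math.comb(E, r) for r in range(0, min(budget, E) + 1))
        return total - 1 if m == 0 else total

    def __iter__(self):
        E = len(self.optional)
        if self.max_edges is None and E > self.hard_cap:
            raise ValueError(
                f"refusing to enumerate 2^{E} configurations; set max_edges "
                f"or reduce the admissible set (hard cap {self.hard_cap})"
            )
        max_r = E if self.max_edges is None else max(
            0, min(E, self.max_edges - len(self.mandatory)))
        for r in range(0, max_r + 1):
            for subset in itertools.combinations(self.optional, r):
                edges = set(subset) | set(self.mandatory)
                if not edges:
                    continue
                yield NetworkConfig(edges)


def enumerate_configurations(
    cand: CandidateEdgeSet, max_edges: int | None = None, hard_cap: int = 24
) -> ConfigurationSpace:
    """Configuration space over the admissible edges (see
    :class:`ConfigurationSpace`)."""
    return ConfigurationSpace(cand, max_edges=max_edges, hard_cap=hard_cap)


# ---------------------------------------------------------------------------
# AIC ranking


@dataclass
class ModelRanking:
    """Fitted configurations sorted by ascending AIC."""

    results: list[FitResult]
    search: str
    n_failed: int = 0

    @property
    def best(self) -> FitResult:
        return self.results[0]

    def table(self) -> pd.DataFrame:
        best_aic = self.results[0].aic
        return pd.DataFrame(
            {
                "config": [repr(r.config) for r in self.results],
                "n_edges": [len(r.config) for r in self.results],
                "rss": [r.rss for r in self.results],
                "k": [r.k for r in self.results],
                "aic": [r.aic for r in self.results],
                "delta_aic": [r.aic - best_aic for r in self.results],
            }
        )


def rank_models(
    cand: CandidateEdgeSet,
    panel: pd.DataFrame,
    conditions: list[Condition],
    search: str = "exhaustive",
    mode: str = "steady_state",
    max_edges: int | None = None,
    n_restarts: int = 1,
    seed: int = 0,
    hard_cap: int = 24,
) -> ModelRanking:
    """Fit every candidate configuration and rank by AIC.

    ``exhaustive`` visits the full admissible power set (requires E within
    the hard cap); ``greedy`` is forward-backward stepwise by delta-AIC for
    larger spaces.  Failed fits are ranked last.
    """
    start_cache: dict = {}  # per-node collocation solutions shared by configs

    def fit_one(config):
        return ode.fit(config, panel, conditions, mode=mode,
                       n_restarts=n_restarts, seed=seed,
                       start_cache=start_cache)

    results, n_failed = [], 0
    if search == "exhaustive":
        space = enumerate_configurations(cand, max_edges=max_edges,
                                         hard_cap=hard_cap)
        for config in space:
            try:
                results.append(fit_one(config))
            except Exception as exc:
                n_failed += 1
                warnings.warn(f"fit failed for {config!r}: {exc}")
    elif search == "greedy":
        results_by_cfg: dict[frozenset, FitResult] = {}

        def fit_cached(edges: frozenset):
            if edges not in results_by_cfg:
                results_by_cfg[edges] = fit_one(NetworkConfig(edges))
            return results_by_cfg[edges]

        admissible = cand.admissible_edges()
        current = frozenset(cand.mandatory) or None
        # forward start: best single edge if no mandatory set
        if current is None:
            singles = [(fit_cached(frozenset({e})).aic, frozenset({e}))
                       for e in admissible]
            current = min(singles)[1]
        improved = True
        while improved:
            improved = False
            cur_aic = fit_cached(current).aic
            moves = []
            for e in admissible:
                if e not in current:
                    moves.append(current | {e})
            for e in current:
                if e not in cand.mandatory and len(current) > 1:
                    moves.append(current - {e})
            for cfg in moves:
                if fit_cached(cfg).aic < cur_aic - 1e-12:
                    current, cur_aic = cfg, fit_cached(cfg).aic
                    improved = True
        results = list(results_by_cfg.values())
    else:
        raise ValueError(f"unknown search {search!r}")

    if not results:
        raise RuntimeError("no configuration could be fitted")
    results.sort(key=lambda r: (r.aic, len(r.config)))
    return ModelRanking(results=results, search=search, n_failed=n_failed)


# ---------------------------------------------------------------------------
# edge weights


def edge_weights(
    config: NetworkConfig,
    panel: pd.DataFrame,
    conditions: list[Condition],
    mode: str = "steady_state",
    n_restarts: int = 1,
    seed: int = 0,
    method: str = "delta_aic",
) -> dict[tuple[str, str, int], float]:
    """Relative contribution of each edge to model fit.

    Each edge is removed in turn and the reduced configuration refitted;
    the raw weight is the (clipped-at-zero) increase in AIC — or in RSS
    with ``method='delta_rss'`` — and weights are normalised to sum to 1.
    A single-edge configuration gets weight 1 by convention.
    """
    edges = config.sorted_edges()
    if len(edges) == 1:
        return {edges[0]: 1.0}
    full = ode.fit(config, panel, conditions, mode=mode,
                   n_restarts=n_restarts, seed=seed)
    raw = {}
    for e in edges:
        reduced = ode.fit(config.without(e), panel, conditions, mode=mode,
                          n_restarts=n_restarts, seed=seed)
        if method == "delta_aic":
            raw[e] = max(0.0, reduced.aic - full.aic)
        elif method == "delta_rss":
            raw[e] = max(0.0, reduced.rss - full.rss)
        else:
            raise ValueError(f"unknown method {method!r}")
    total = sum(raw.values())
    if total == 0:
        # no edge individually matters; report a flat profile
        return {e: 1.0 / len(edges) for e in edges}
    return {e: v / total for e, v in raw.items()}


# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    total_effect: float
    direct_effect: float
    mediated_effect: float
    baseline_value: float
    perturbed_value: float

    @property
    def mediated_fraction(self) -> float:
        if self.total_effect == 0:
            return 0.0
        return self.mediated_effect / self.total_effect


def mediation_analysis(
    config: NetworkConfig,
    params: ModelParams,
    baseline: Condition,
    perturbed: Condition,
    target: str,
    mediator: str,
    mode: str = "steady_state",
) -> MediationResult:
    """Decompose a perturbation's effect on ``target`` through ``mediator``.

    Total effect is the endpoint change of the target between the perturbed
    and baseline conditions.  The direct effect repeats the perturbation
    with the mediator clamped to its baseline endpoint; the mediated effect
    is the remainder.
    """
    if mediator not in MODELLED_NODES:
        raise ValueError(f"mediator {mediator!r} is not a modelled node")
    base_add = dict(baseline.additions)
    pert_add = dict(perturbed.additions)
    changed = {c for c in set(base_add) | set(pert_add)
               if base_add.get(c) != pert_add.get(c)}
    changed |= baseline.blocked_ligands() ^ perturbed.blocked_ligands()
    if mediator in changed:
        raise ValueError("cannot clamp the perturbed node itself")

    c0 = ode.simulate(config, params, baseline, mode=mode)
    c1 = ode.simulate(config, params, perturbed, mode=mode)
    total = c1[target] - c0[target]
    clamped = ode.simulate(config, params, perturbed, mode=mode,
                           clamp={mediator: c0[mediator]})
    direct = clamped[target] - c0[target]
    return MediationResult(
        total_effect=total,
        direct_effect=direct,
        mediated_effect=total - direct,
        baseline_value=c0[target],
        perturbed_value=c1[target],
    )
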