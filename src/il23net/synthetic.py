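"""Synthetic generators for every input the pipeline consumes.

Three generators emulate the study's data layers from known ground truth,
so each downstream stage has a parameter-recovery surface:

* donor-paired multi-analyte cytokine panels from an ODE ground-truth
  network (multiplicative lognormal noise, shared per-donor scale);
* bulk tissue cohorts with latent coexpression-module factors coupled to
  diagnosis and anti-TNF response labels through a logistic link;
* condition-labelled single-cell negative-binomial count matrices with an
  8-cluster structure and planted condition-specific genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from . import ode
from .ode import (
    ALL_NODES,
    EPSILON,
    MODELLED_NODES,
    Condition,
    ModelParams,
    NetworkConfig,
)

# ---------------------------------------------------------------------------
# cytokine panel generator


@dataclass
class GroundTruthNetwork:
    """Latent regulatory structure behind a simulated supernatant panel.

    ``edges`` are (source, target, sign, strength) with strength >= 0.
    ``basal``/``stimulated`` are per-node production rates (pg/mL/h),
    ``degradation`` per-node decay (1/h), ``half_saturation`` shared K
    (pg/mL).
    """

    edges: list[tuple[str, str, int, float]]
    basal: dict[str, float]
    stimulated: dict[str, float]
    degradation: dict[str, float] = field(
        default_factory=lambda: {n: 1.0 for n in MODELLED_NODES}
    )
    half_saturation: float = 100.0

    def __post_init__(self):
        for src, dst, sign, w in self.edges:
            if src == dst:
                raise ValueError("no self-edges")
            if src not in ALL_NODES or dst not in MODELLED_NODES:
                raise ValueError(f"unknown edge {src}->{dst}")
            if sign not in (1, -1) or w < 0:
                raise ValueError("sign must be +-1 and strength >= 0")
        if any(v < 0 for v in self.basal.values()):
            raise ValueError("basal rates must be >= 0")
        if any(v <= 0 for v in self.degradation.values()):
            raise ValueError("degradation must be > 0")

    def config(self) -> NetworkConfig:
        return NetworkConfig({(s, d, g) for s, d, g, _ in self.edges})

    def params(self) -> ModelParams:
        return ModelParams(
            basal=dict(self.basal),
            stimulated=dict(self.stimulated),
            degradation=dict(self.degradation),
            edge_strength={(s, d, g): w for s, d, g, w in self.edges},
            half_saturation=self.half_saturation,
        )


def default_ground_truth() -> GroundTruthNetwork:
    """The reference 4-edge core used across the analyses.

    IL-10 inhibits IL-23 and IL-1a (negative feedback), IL-1b activates
    IL-23, and IFN-g suppresses IL-10 — the qualitative core of the
    monocyte circuit under LPS.  The IL-1b edge is strong because IL-1
    signalling is essential for IL-23 production: blocking IL-1R1 should
    collapse, not merely reduce, the IL-23 endpoint.
    """
    return GroundTruthNetwork(
        edges=[
            ("IL10", "IL23", -1, 8.0),
            ("IL1B", "IL23", 1, 20.0),
            ("IL10", "IL1A", -1, 4.0),
            ("IFNG", "IL10", -1, 3.0),
        ],
        basal={"TNF": 2.0, "IL1A": 1.5, "IL1B": 2.0, "IL6": 3.0,
               "IL10": 1.0, "IL23": 1.0},
        stimulated={"TNF": 500.0, "IL1A": 80.0, "IL1B": 300.0, "IL6": 800.0,
                    "IL10": 60.0, "IL23": 30.0},
    )


@dataclass
class CohortSpec:
    """Design of a donor-paired stimulation panel."""

    n_donors: int = 28
    conditions: list[Condition] = field(default_factory=ode.default_condition_panel)
    noise_sd: float = 0.25
    donor_effect_sd: float = 0.3
    seed: int = 0
    sim_mode: str = "steady_state"

    def __post_init__(self):
        if self.n_donors < 2:
            raise ValueError("paired design needs n_donors >= 2")
        if self.noise_sd < 0 or self.donor_effect_sd < 0:
            raise ValueError("noise scales must be >= 0")


def simulate_cohort_panel(
    net: GroundTruthNetwork, spec: CohortSpec
) -> pd.DataFrame:
    """Tidy donor-paired panel: model endpoint x donor scale x lognormal noise.

    Columns: ``donor_id``, ``condition_id``, ``analyte``,
    ``concentration_pg_ml``.  A per-donor multiplicative factor shared across
    conditions realises the paired design; measurement noise is
    multiplicative lognormal per well.
    """
    config, params = net.config(), net.params()
    base = ode.simulate_many(config, params, spec.conditions, mode=spec.sim_mode)
    rng = np.random.default_rng(spec.seed)
    donor_fx = np.exp(rng.normal(0.0, spec.donor_effect_sd, size=spec.n_donors))
    rows = []
    n_c, n_a = base.shape
    for d in range(spec.n_donors):
        noise = np.exp(rng.normal(0.0, spec.noise_sd, size=(n_c, n_a)))
        vals = base * donor_fx[d] * noise
        for ci, cond in enumerate(spec.conditions):
            for ai, analyte in enumerate(MODELLED_NODES):
                rows.append((f"D{d + 1:03d}", cond.name, analyte, vals[ci, ai]))
    return pd.DataFrame(
        rows, columns=["donor_id", "condition_id", "analyte", "concentration_pg_ml"]
    )


# ---------------------------------------------------------------------------
# tissue cohort generator


@dataclass
class ModuleSpec:
    """One planted coexpression module driven by a latent factor."""

    n_genes: int
    loading_mean: float = 1.0
    loading_sd: float = 0.2


@dataclass
class TissueCohortSpec:
    """Design of a synthetic intestinal-biopsy expression cohort.

    Two latent factors (inflammatory-cytokine and lymphocyte-differentiation
    module activity) drive planted gene modules.  Strata shift the
    inflammatory factor; diagnosis and anti-TNF non-response labels are
    drawn from a logistic link on that factor with the stated log-odds
    effect sizes.  Signature genes carry explicit (inflammatory, lymphoid)
    loadings.
    """

    n_per_stratum: dict[str, int] = field(
        default_factory=lambda: {"control": 60, "CD_noninflamed": 60, "CD_inflamed": 80}
    )
    modules: dict[str, ModuleSpec] = field(
        default_factory=lambda: {
            "inflammatory": ModuleSpec(80),
            "lymphoid": ModuleSpec(80),
        }
    )
    n_noise_genes: int = 200
    stratum_shift: dict[str, float] = field(
        default_factory=lambda: {"control": -1.0, "CD_noninflamed": 0.0,
                                 "CD_inflamed": 1.2}
    )
    diagnosis_effect: float = 2.0  # log-odds per unit inflammatory factor
    nonresponse_effect: float = 1.5
    signature_genes: list[tuple[str, float, float]] = field(default_factory=list)
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if any(n < 2 for n in self.n_per_stratum.values()):
            raise ValueError("strata sizes must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_stratum.values())


def default_signature_genes(
    n_infl: int = 10, n_both: int = 10, n_lymph: int = 10, loading: float = 1.0
) -> list[tuple[str, float, float]]:
    """Planted monocyte-signature genes: inflammatory-only, dual, lymphoid-only."""
    genes = [(f"SIG_INFL{i + 1:02d}", loading, 0.0) for i in range(n_infl)]
    genes += [(f"SIG_BOTH{i + 1:02d}", 0.7 * loading, 0.7 * loading)
              for i in range(n_both)]
    genes += [(f"SIG_LYMPH{i + 1:02d}", 0.0, loading) for i in range(n_lymph)]
    return genes


def simulate_tissue_cohort(
    spec: TissueCohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genes x samples log2 expression plus sample metadata.

    Returns ``(expr, meta)``; ``meta`` has ``stratum``, ``inflamed``,
    ``diagnosis`` (CD / control), ``nonresponder`` (anti-TNF) and the latent
    factors (for validation only).
    """
    rng = np.random.default_rng(spec.seed)
    strata = [s for s, n in spec.n_per_stratum.items() for _ in range(n)]
    n = len(strata)
    shift = np.array([spec.stratum_shift.get(s, 0.0) for s in strata])
    f_infl = rng.normal(0.0, 1.0, n) + shift
    f_lymph = rng.normal(0.0, 1.0, n)
    factors = {"inflammatory": f_infl, "lymphoid": f_lymph}

    gene_rows, names = [], []

    def add_gene(name, load_infl, load_lymph):
        if name in seen:
            raise ValueError(f"duplicate gene name {name!r}")
        seen.add(name)
        base = load_infl * f_infl + load_lymph * f_lymph
        gene_rows.append(base + rng.normal(0.0, spec.noise_sd, n))
        names.append(name)

    seen: set[str] = set()
    module_of: dict[str, str] = {}
    for mod_name, mspec in spec.modules.items():
        f = factors.get(mod_name)
        if f is None:
            raise ValueError(f"module {mod_name!r} has no latent factor")
        loadings = rng.normal(mspec.loading_mean, mspec.loading_sd, mspec.n_genes)
        for gi, lam in enumerate(loadings):
            gname = f"{mod_name.upper()}_G{gi + 1:03d}"
            add_gene(gname, lam if mod_name == "inflammatory" else 0.0,
                     lam if mod_name == "lymphoid" else 0.0)
            module_of[gname] = mod_name
    for gname, li, ll in spec.signature_genes:
        add_gene(gname, li, ll)
    for gi in range(spec.n_noise_genes):
        add_gene(f"NOISE_G{gi + 1:04d}", 0.0, 0.0)

    samples = [f"S{i + 1:03d}" for i in range(n)]
    expr = pd.DataFrame(np.array(gene_rows), index=names, columns=samples)

    def draw_labels(effect):
        p = 1.0 / (1.0 + np.exp(-(effect * f_infl)))
        return rng.random(n) < p

    meta = pd.DataFrame(
        {
            "stratum": strata,
            "inflamed": [s == "CD_inflamed" for s in strata],
            "diagnosis": np.where(draw_labels(spec.diagnosis_effect), "CD", "control"),
            "nonresponder": draw_labels(spec.nonresponse_effect),
            "factor_inflammatory": f_infl,
            "factor_lymphoid": f_lymph,
        },
        index=samples,
    )
    return expr, meta


# ---------------------------------------------------------------------------
# single-cell generator


@dataclass
class ClusterSpec:
    """One monocyte cluster: elevated genes and condition mixture weights."""

    name: str
    condition_weights: dict[str, float]
    elevated_genes: dict[str, float] = field(default_factory=dict)  # gene -> fold


@dataclass
class SingleCellSpec:
    """Design of a condition-labelled single-cell count matrix.

    Cells of each condition are drawn from clusters according to that
    condition's mixture weights; counts are negative binomial around
    cluster x gene means (Poisson in the infinite-dispersion limit).
    Planted condition-specific genes are elevated only in clusters
    exclusive to their designated condition.
    """

    n_genes: int = 400
    clusters: list[ClusterSpec] = field(default_factory=list)
    n_cells: dict[str, int] = field(
        default_factory=lambda: {"Ctrl": 250, "LPS": 250, "LPS+aIL10R": 250}
    )
    dispersion: float = 2.0
    baseline_mean: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for cond in self.n_cells:
            total = sum(c.condition_weights.get(cond, 0.0) for c in self.clusters)
            if self.clusters and abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"cluster weights for condition {cond!r} sum to {total}, not 1"
                )
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0 (use np.inf for Poisson)")


def default_single_cell_spec(
    n_planted: int = 35, planted_fold: float = 12.0, seed: int = 0, **kw
) -> SingleCellSpec:
    """Eight-cluster design: three shared clusters, two LPS-emergent, three
    emerging only under combined LPS and IL-10R blockade; ``n_planted``
    blockade-specific genes elevated in the latter."""
    planted = {f"PLANT{i + 1:02d}": planted_fold for i in range(n_planted)}
    lps_genes = {f"LPSG{i + 1:02d}": 8.0 for i in range(20)}
    clusters = [
        ClusterSpec("C1", {"Ctrl": 0.5, "LPS": 0.3, "LPS+aIL10R": 0.2}),
        ClusterSpec("C2", {"Ctrl": 0.3, "LPS": 0.2, "LPS+aIL10R": 0.1}),
        ClusterSpec("C3", {"Ctrl": 0.2, "LPS": 0.1, "LPS+aIL10R": 0.1}),
        ClusterSpec("C4", {"Ctrl": 0.0, "LPS": 0.2, "LPS+aIL10R": 0.0},
                    dict(list(lps_genes.items())[:10])),
        ClusterSpec("C5", {"Ctrl": 0.0, "LPS": 0.2, "LPS+aIL10R": 0.0},
                    dict(list(lps_genes.items())[10:])),
        ClusterSpec("C6", {"Ctrl": 0.0, "LPS": 0.0, "LPS+aIL10R": 0.2},
                    {g: f for g, f in list(planted.items())}),
        ClusterSpec("C7", {"Ctrl": 0.0, "LPS": 0.0, "LPS+aIL10R": 0.2},
                    {g: f for g, f in list(planted.items())}),
        ClusterSpec("C8", {"Ctrl": 0.0, "LPS": 0.0, "LPS+aIL10R": 0.2},
                    {g: f for g, f in list(planted.items())}),
    ]
    return SingleCellSpec(clusters=clusters, seed=seed, **kw)


def simulate_single_cells(spec: SingleCellSpec) -> ad.AnnData:
    """Cell x gene counts with per-cell condition (and cluster) labels."""
    rng = np.random.default_rng(spec.seed)
    named = {g for c in spec.clusters for g in c.elevated_genes}
    n_extra = max(0, spec.n_genes - len(named))
    genes = sorted(named) + [f"BG{i + 1:04d}" for i in range(n_extra)]
    if len(set(genes)) != len(genes):
        raise ValueError("gene names collide; avoid BG-prefixed elevated genes")
    gidx = {g: i for i, g in enumerate(genes)}
    # heterogeneous baselines, reproducible across conditions
    base = spec.baseline_mean * rng.lognormal(0.0, 0.5, len(genes))

    cluster_means = []
    for c in spec.clusters:
        mu = base.copy()
        for g, fold in c.elevated_genes.items():
            mu[gidx[g]] *= fold
        cluster_means.append(mu)

    X, conds, clusts = [], [], []
    for cond, n_cells in spec.n_cells.items():
        weights = np.array(
            [c.condition_weights.get(cond, 0.0) for c in spec.clusters]
        )
        assignment = rng.choice(len(spec.clusters), size=n_cells, p=weights)
        for ci in assignment:
            mu = cluster_means[ci]
            if np.isinf(spec.dispersion):
                counts = rng.poisson(mu)
            else:
                th = spec.dispersion
                counts = rng.negative_binomial(th, th / (th + mu))
            X.append(counts)
            conds.append(cond)
            clusts.append(spec.clusters[ci].name)

    X = np.asarray(X, dtype=np.int64)
    obs = pd.DataFrame(
        {"condition": conds, "cluster": clusts},
        index=[f"cell{i + 1:05d}" for i in range(X.shape[0])],
    )
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
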