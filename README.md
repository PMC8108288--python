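# il23net

Inference of the monocyte IL-23 regulatory circuit and deconvolution of an
IL-10-regulated inflammatory-monocyte gene signature, as a tested, fully
synthetic-data-driven analysis pipeline.

## The scientific problem

IL-23 drives pathogenic Th17 responses in inflammatory bowel disease, and
monocytes are its main cellular source. IL-10 signalling acts as the brake:
blocking the IL-10 receptor during LPS stimulation of PBMC unleashes IL-23
secretion, and IL-1α/IL-1β are essential positive drivers. This package
re-implements the two bespoke computations behind that biology:

1. **Cytokine network inference.** Donor-paired supernatant panels
   (stimulation ± recombinant cytokine additions ± ligand/receptor
   blockades) are modelled with an ODE system over the monocyte cytokines
   {TNF, IL-1α, IL-1β, IL-6, IL-10, IL-23}, with IFN-γ as an exogenous
   input. Each node obeys

   dC_i/dt = β_i(cond) · Π₍j→i,+₎ (1 + w·h(C̃_j)) · Π₍j→i,−₎ 1/(1 + w·h(C̃_j)) − δ_i·C_i,  h(C) = C/(K + C)

   Candidate regulatory edges are screened by FDR-corrected paired Wilcoxon
   contrasts, every admissible edge subset is enumerated (2^E − 1
   configurations), each configuration is fitted by least squares on log10
   endpoint concentrations, and models are ranked by
   AIC = n·ln(RSS/n) + 2k. Edge weights of the winning model are
   normalised leave-one-edge-out ΔAIC; in-silico mediation (clamping a
   node at its unperturbed level) separates direct from mediated effects —
   e.g. IFN-γ amplifies IL-1α *through* IL-10 suppression but can amplify
   IL-23 independently of IL-10.

2. **Signature deconvolution.** A monocyte gene signature specific to
   combined LPS + anti-IL-10R stimulation is derived from
   condition-labelled single-cell counts (rank-sum + fold-change +
   detection filters against every other condition). In bulk intestinal
   transcriptomes, coexpression modules are detected WGCNA-style (signed
   adjacency ((1+r)/2)^β, topological overlap, average-linkage cut), and
   each signature gene is classified by whether it correlates with the
   inflammatory-cytokine eigengene, the lymphocyte-differentiation
   eigengene, or both. Subsets are then compared as single-gene
   classifiers by AUPRC (baseline = class prevalence) for CD diagnosis and
   anti-TNF non-response.

All inputs are produced by the `il23net.synthetic` generators from known
ground truth, so every stage has a parameter-recovery test surface; no
external data are downloaded.

## Worked example

```python
from il23net import ode, selection, synthetic

net = synthetic.default_ground_truth()            # 4-edge circuit
conditions = ode.default_condition_panel()        # 16 culture conditions
panel = synthetic.simulate_cohort_panel(
    net, synthetic.CohortSpec(n_donors=20, conditions=conditions,
                              noise_sd=0.1, donor_effect_sd=0.3, seed=3))

cand = selection.screen_candidate_edges(panel, conditions, alpha=0.05)
print(cand.n_admissible)                          # 6
rank = selection.rank_models(cand, panel, conditions, search="exhaustive")
print(rank.best.config)
# NetworkConfig(IFNG-|IL10, IL10-|IL1A, IL10-|IL23, IL1B->IL23)
```

The screen admits the four true edges plus two indirect IFN-γ effects
(IFN-γ→IL-1α, IFN-γ→IL-23); AIC ranking over all 63 configurations prunes
the indirect ones at this noise level, recovering the planted circuit.
Simulating the fitted best model reproduces the blockade phenotypes: the
IL-23 endpoint rises ~4-fold under anti-IL-10R and falls by ~94% under
anti-IL-1R1.

The full analysis is laid out as numbered drivers:

```
analysis/01_simulate_cohort_panel.py   # ground truth -> donor-paired panel
analysis/02_secretome_screen.py        # fc>=4 + BH-Wilcoxon induced analytes
analysis/03_network_inference.py       # edge screen -> enumeration -> AIC -> weights
analysis/04_mediation_analysis.py      # IFN-g effects through IL-10
analysis/05_single_cell_signature.py   # 35-gene blockade-specific signature
analysis/06_tissue_deconvolution.py    # modules, eigengenes, partition
analysis/07_signature_prediction.py    # per-gene AUPRC, subset comparison
```

Each script prints what it found and writes its tables under `results/`.

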