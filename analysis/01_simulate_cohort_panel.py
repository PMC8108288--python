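#!/usr/bin/env python
"""Simulate the donor-paired PBMC stimulation/blockade cytokine panel.

Generates the reference 4-edge ground-truth monocyte network (IL-10 -| IL-23,
IL-1b -> IL-23, IL-10 -| IL-1a, IFN-g -| IL-10), simulates endpoint
supernatant concentrations for 28 donors across the 16-condition
stimulation/addition/blockade panel with lognormal measurement noise and a
shared per-donor scale, and writes the tidy panel plus the ground truth.
"""

import json
from pathlib import Path

from il23net import ode, synthetic

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

net = synthetic.default_ground_truth()
conditions = ode.default_condition_panel()
spec = synthetic.CohortSpec(n_donors=28, conditions=conditions,
                            noise_sd=0.25, donor_effect_sd=0.3, seed=101)
panel = synthetic.simulate_cohort_panel(net, spec)
panel.to_csv(OUT / "cytokine_panel.tsv", sep="\t", index=False)

(OUT / "ground_truth_network.json").write_text(json.dumps({
    "edges": [{"source": s, "target": t, "sign": g, "strength": w}
              for s, t, g, w in net.edges],
    "basal_pg_ml_h": net.basal,
    "stimulated_pg_ml_h": net.stimulated,
    "degradation_per_h": net.degradation,
    "half_saturation_pg_ml": net.half_saturation,
    "cohort": {"n_donors": spec.n_donors, "noise_sd": spec.noise_sd,
               "donor_effect_sd": spec.donor_effect_sd, "seed": spec.seed},
}, indent=2))

wide = panel.pivot_table(index="condition_id", columns="analyte",
                         values="concentration_pg_ml", aggfunc="mean")
wide = wide.reindex([c.name for c in conditions])
print(f"panel: {spec.n_donors} donors x {len(conditions)} conditions x "
      f"{panel['analyte'].nunique()} analytes -> {OUT / 'cytokine_panel.tsv'}")
print("\nmean concentration (pg/mL) per condition:")
print(wide.round(1).to_string())
print("\nIL-23 rises under anti-IL-10R and collapses under anti-IL-1R1, "
      "the hallmark of IL-10 negative feedback with essential IL-1 drive.")
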