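#!/usr/bin/env python
"""In-silico mediation: which IFN-g effects run through IL-10?

Using the ground-truth model, decompose the effect of adding IFN-g on each
downstream cytokine into the part mediated by IL-10 (removed when IL-10 is
clamped to its unperturbed level) and the direct remainder.  A variant
network with an explicit IFN-g -> IL-23 edge shows the contrasting case of
an IL-10-independent amplification.
"""

from pathlib import Path

import pandas as pd

from il23net import selection, synthetic
from il23net.ode import Condition

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

baseline = Condition("LPS", stimulus="LPS")
perturbed = Condition("LPS+IFNG", stimulus="LPS", additions=(("IFNG", 1e4),))

gt = synthetic.default_ground_truth()
variant = synthetic.GroundTruthNetwork(
    edges=[("IL10", "IL23", -1, 8.0), ("IL1B", "IL23", 1, 20.0),
           ("IL10", "IL1A", -1, 4.0), ("IFNG", "IL10", -1, 1.0),
           ("IFNG", "IL23", 1, 6.0)],
    basal=gt.basal, stimulated=gt.stimulated,
)

rows = []
for net_name, net, target in [("core", gt, "IL1A"), ("core", gt, "IL23"),
                              ("direct_ifng_il23", variant, "IL23")]:
    res = selection.mediation_analysis(
        net.config(), net.params(), baseline=baseline, perturbed=perturbed,
        target=target, mediator="IL10")
    rows.append({
        "network": net_name, "target": target, "mediator": "IL10",
        "total_effect_pg_ml": res.total_effect,
        "direct_effect_pg_ml": res.direct_effect,
        "mediated_effect_pg_ml": res.mediated_effect,
        "mediated_fraction": res.mediated_fraction,
    })
table = pd.DataFrame(rows)
table.to_csv(RESULTS / "mediation.tsv", sep="\t", index=False)
print(table.round(3).to_string(index=False))
print(
    "\nIn the core network every IFN-g effect travels through IL-10 "
    "suppression (mediated fraction ~1).  Adding a direct IFN-g -> IL-23 "
    "edge leaves most of the IL-23 amplification intact when IL-10 is "
    "clamped: IFN-g amplifies IL-1a via IL-10, but can amplify IL-23 "
    "independently of it."
)
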