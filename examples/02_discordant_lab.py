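"""Diagnosing a discordant lab.

Scenario S2 is identical to S1 except that lab 2 is degraded: half of its
genuine signals are irreproducible (pi1|1 drops from 0.8 to 0.5), its
reproducible signals are noisier (sigma 1.4 vs 1.0) and less correlated
(rho 0.7 vs 0.9).  A standard IDR analysis that pools all four replicates
sees only "worse data".  The nested model localises the problem: the fitted
lab-2 parameters shift, the lab-2 idr_within selections shrink sharply,
while the between-lab selections barely move.

Run with:  python examples/02_discordant_lab.py  (~15 s)
"""

import numpy as np

from nestedidr import (
    compute_scores,
    fit,
    make_pseudo_data,
    scenario_preset,
    select_at_level,
    simulate_dataset,
    standard_idr,
)

ALPHA = 0.05

for name in ("S1", "S2"):
    cfg = scenario_preset(name, n=5000, seed=20240802)
    x, truth = simulate_dataset(cfg)
    res = fit(x)
    z = make_pseudo_data(x, res.params)
    scores = compute_scores(z, res.params, x.design)
    idra = standard_idr(x)

    n_between = select_at_level(scores.idr_between, ALPHA).size
    n_within = [
        select_at_level(scores.idr_within[:, l], ALPHA).size
        for l in range(x.design.L)
    ]
    n_idra = select_at_level(idra.scores, ALPHA).size

    p = res.params
    print(f"\n=== scenario {name} ===")
    print(
        "fitted lab quality:  "
        + "   ".join(
            f"lab {l + 1}: pi1|1={p.pi11[l]:.2f} sigma={p.sigma11[l]:.2f} rho={p.rho11[l]:.2f}"
            for l in range(x.design.L)
        )
    )
    print(f"selections at alpha={ALPHA}:")
    print(f"  idr_between (nested)       : {n_between}")
    for l, c in enumerate(n_within):
        print(f"  idr_within, lab {l + 1}          : {c}")
    print(f"  standard IDR, all replicates: {n_idra}")
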