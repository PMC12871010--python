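"""Small repeated-simulation study comparing methods.

Runs a scaled-down version of the evaluation study (n=1500 candidates,
5 datasets per scenario) for the nested model, pooled standard IDR and the
classical rank-combination baselines, and prints mean AUC for recovering
the replicable-signal label and the mean number of selections at each
control level.  The full-scale study behind the headline numbers is
reproduced by scripts/acceptance.py.

Run with:  python examples/03_method_comparison.py  (~2 min)
"""

from nestedidr import run_scenario_study
from nestedidr.evaluate import DEFAULT_CUTOFFS
from nestedidr.simulate import scenario_preset

METHODS = ("nestedidr", "idra", "rankprod", "fisher", "stouffer")

for name in ("S1", "S4"):
    cfg = scenario_preset(name, n=1500)
    report = run_scenario_study(cfg, n_reps=5, seed=20240803, methods=METHODS)
    print(f"\n=== scenario {name} (5 reps, n=1500) ===")
    print("mean AUC (replicable vs not):")
    for m, s in report.auc_summary().items():
        print(f"  {m:10s} {s['mean']:.4f}  (sd {s['sd']:.4f})")
    print(f"mean selections at alpha={DEFAULT_CUTOFFS}:")
    for key, counts in report.mean_selection().items():
        print(f"  {key:14s} " + "  ".join(f"{c:7.1f}" for c in counts))
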