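"""Estimate the pipeline's false-detection rate under a simulated null.

A small version of the robustness check: several replicate studies in which
no individual differences exist by construction; any flagged participant is a
false detection. The acceptance script runs the full 23-group version.
"""

from idionet import MissingnessSpec, StudyDesign, run_null_simulation

res = run_null_simulation(
    n_groups=6,
    design=StudyDesign(n_days=28, beeps_per_day=5),
    missing=MissingnessSpec(0.18),
    reps=5,
    seed=1,
)
for rec in res.per_rep:
    print(
        f"rep {rec.rep}: {rec.n_flagged}/{rec.n_total} participants "
        f"falsely flagged ({100 * rec.proportion:.1f}%)"
    )
print(f"mean false-detection rate: {100 * res.mean_rate:.2f}% "
      f"(MC se {100 * res.mc_se:.2f} pp)")
# A small rate shows the AIC comparison is conservative: with ~115 observed
# beeps per person it rarely buys the free model's 57 extra parameters per
# member when the members truly share one network.
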