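"""Relate composite coherence to the seven cognitive components.

Generates a patient cohort whose composite coherence is a known linear
function of three components (phonological production B=0.132, semantic
processing B=0.101, verbal fluency B=0.08 plus noise), then fits the staged
regression ledger: Model 1 core language, Model 2 + connected speech,
Model 3 + executive functions, Model 4 + executive interactions, and the
executive-only model. The fitted coefficients should recover the planted
values, and executive functions alone should explain ~nothing.
"""

from cohmap import GeneratorConfig, make_component_scores, staged_regressions
from cohmap.behavioural_stats import executive_only_regression

cfg = GeneratorConfig(seed=2)
comps, coherence, truth = make_component_scores(cfg, mode="forward")
print("planted coefficients:", truth.coefficients, "\n")

for res in staged_regressions(coherence, comps):
    sig = [p for p in res.predictors if res.p_values[p] < 0.001]
    print(f"{res.label}: R^2 = {res.r_squared:.3f} "
          f"(delta {res.delta_r_squared if res.delta_r_squared is not None else 0:+.3f}), "
          f"significant: {', '.join(sig) if sig else 'none'}")
    for p in sig:
        print(f"      B({p}) = {res.coefficients[p]:+.3f}")

ex = executive_only_regression(coherence, comps)
print(f"\nexecutive-only: R^2 = {ex.r_squared:.4f} -> executive functions "
      "alone do not predict coherence in this cohort.")
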