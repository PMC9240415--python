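"""Score a synthetic discourse cohort for global coherence.

Generates transcripts for 20 controls and 46 patients across the three
discourse tasks, scores every response against the control-derived prototype
vector of its task (leave-one-out for controls), and prints per-group means,
deficit counts (scores below control mean - 1.5 SD), and the 2x3 mixed
ANOVA. Expect patients clearly below controls on every task and the
procedural task easiest for both groups.
"""

from cohmap import (GeneratorConfig, make_corpus_and_space, make_transcripts,
                    mixed_anova, score_cohort)
from cohmap.coherence import deficit_table

cfg = GeneratorConfig(seed=1)
_, space = make_corpus_and_space(cfg)
records, _ = make_transcripts(cfg)
scores = score_cohort(records, space)

summary = scores.groupby(["task", "group"])["global_coherence"].agg(
    ["mean", "std"]).round(3)
print(summary, "\n")

flagged = deficit_table(scores)
counts = flagged[flagged["group"] == "patient"].groupby("task")["deficit"].sum()
print("patients flagged with a coherence deficit, per task:")
print(counts.to_string(), "\n")

effects, contrasts = mixed_anova(scores)
for e in effects:
    print(f"{e.effect:>14s}: F({e.df[0]:.0f},{e.df[1]:.0f}) = {e.F:.2f}, "
          f"p = {e.p:.2g}, partial eta^2 = {e.partial_eta_sq:.2f}")
print("\nA large group effect means patients' discourse drifts off-topic "
      "far more than controls'.")
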