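"""Ask how many repair processes the data support.

Generates the full eight-dataset synthetic knockout panel from the
three-process truth, then fits nested variants: M1 (fast only), M2
(fast + slow) and M3 (all three).  The knockout datasets are what
discriminate: under M1 the Ku-deficient datasets have no channel at all
and predict flat curves, and under M2 the single slow channel must absorb
two distinct timescales.  Scores are information criteria on a surrogate
likelihood; lower is better, and the three-process model should win.
"""

import dsbrepair as d
from dsbrepair.model_selection import M1, M2, M3, compare_models

datasets, _ = d.generate_suite(d.default_generator_config(seed=50))

sched = d.SMCSchedule(n_particles=64, n_generations=8)
table, _ = compare_models([M1, M2, M3], datasets, schedule=sched, seed=62)
print(table[["model", "k", "max_loglik", "aic", "dic", "final_eps"]]
      .round(2).to_string(index=False))
for crit in ["aic", "dic"]:
    print(f"best by {crit.upper()}-like score:",
          table.loc[table[crit].idxmin(), "model"])
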