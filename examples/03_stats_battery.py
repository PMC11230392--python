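"""Run the statistical battery on planted group effects.

Generates module-expression counts with a balanced set of planted 3-fold
frequency shifts in 5 of 40 modules (KO mice only), runs module-wise
rank-sum tests with Benjamini–Hochberg FDR, and then fits the
second-guessing mixed model on series with a planted Pot2-revisit peak in
aged wild-type females.
"""

import numpy as np

import foragekit.simulate as sim
import foragekit.stats as st

# --- module-wise differential expression ---------------------------------
cells = (("KO", "M", "young"), ("WT", "M", "young"))
meta = sim.make_group_metadata(15, cells)
base, fold = sim.fdr_battery_design()
rng = np.random.default_rng(0)
expr = sim.simulate_module_expression(meta, 40, rng,
                                      fold_changes={"KO|M|young": fold},
                                      base_weights=base)
res = st.test_module_expression(expr, "M", "young", "Foraging",
                                modules=list(range(1, 41)))
hits = sorted(int(r.term.split("=")[1]) for r in res if r.q < 0.2)
print(f"planted shifts in modules 1-5 (x3 up: 1-3, /3 down: 4-5)")
print(f"modules called at q < 0.2: {hits}")
print("calls inside 1..5 are true positives; anything above 5 is a false "
      "discovery that Benjamini–Hochberg holds below a 20% proportion.")

# --- second-guessing mixed model ------------------------------------------
meta8 = sim.make_group_metadata(12)
spec = sim.SecondGuessSpec(affected_groups=("WT|F|aged",),
                           peak_window_min=(5, 12),
                           peak_amplitude_s_per_min=20.0,
                           baseline_s_per_min=2.0)
series = sim.simulate_secondguess_series(spec, meta8, np.random.default_rng(1))
model = st.secondguess_model(series, meta8)
p_gab = st.secondguess_interaction_p(model, "geno_age_bin")
p_gsa = st.secondguess_interaction_p(model, "geno_sex_age")
print()
print(f"genotype x age x time-bin interaction p = {p_gab:.2e}")
print(f"genotype x sex x age interaction p = {p_gsa:.2e}")
print("both interactions are significant because only aged wild-type "
      "females carry the planted 5-12 minute Pot2 revisit peak.")
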