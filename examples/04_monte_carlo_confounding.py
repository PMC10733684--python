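"""Workflow B step 2: Monte Carlo cross-validation of the confounding effect.

Repeats the controlled-vs-uncontrolled SVM comparison over 100 seeded random
splits with Day-7 undersampling, removing single-split luck and class
imbalance from the comparison.  Reports mean dF1 (controlled - uncontrolled)
with a paired-t 95% CI per constituent.
"""

import nirconfound as nc
from nirconfound.monte_carlo import MCConfig, run_mc

inv = nc.generate_dataset(nc.GeneratorConfig(seed=0))
cleaned = nc.clean_inventory(nc.preprocess_inventory(inv))

for c in nc.CONSTITUENTS:
    res = run_mc(cleaned, MCConfig(constituent=c, n_iterations=100, root_seed=0),
                 precleaned=True)
    lo, hi = res.ci95
    print(f"{c:6s} mean dF1 {res.mean_delta_f1:+.3f}  CI95 [{lo:+.3f}, {hi:+.3f}]  "
          f"p = {res.t_test.p_value:.3g}")
# A CI excluding 0 = controlling for that constituent reliably improves
# maturity prediction; a degenerate [0, 0] interval means the constituent's
# signature is too weak to bias the models at all on this dataset.
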