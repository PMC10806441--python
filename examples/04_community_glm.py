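"""Community GLM: sequential resampling ANOVA and indicator taxa.

Presence/absence of every taxon is modelled with a binomial cloglog
GLM against the environmental design; community-level p-values come
from PIT residual resampling with shrunk among-taxon correlation, and
per-taxon indicator p-values are step-down adjusted (Westfall-Young).
"""

import numpy as np
import pandas as pd

import sedna

rng = np.random.default_rng(2)
n, m = 70, 30
X = pd.DataFrame({"bottom_temperature": rng.normal(size=n),
                  "sst_change": rng.normal(size=n)},
                 index=[f"S{i}" for i in range(n)])
B = np.zeros((m, 2))
B[:6, 0] = 1.4 * np.where(np.arange(6) % 2 == 0, 1, -1)   # 6 temperature responders
eta = -0.6 + X.to_numpy() @ B.T
Y = pd.DataFrame(rng.random((n, m)) < 1 - np.exp(-np.exp(eta)),
                 index=X.index, columns=[f"T{j:02d}" for j in range(m)])

res = sedna.community_anova(Y, X, n_resamples=499, seed=3)
print(res.anova.round(4))
print("\nRows are sequential terms; 'stat' pools per-taxon Wald statistics")
print("through the shrunk correlation; p-values are resampling-based.")

report = sedna.indicator_report(res, p_screen=0.10)
hits = report[report["term"] == "bottom_temperature"].sort_values("adj_p")
print(f"\nindicator taxa for bottom temperature (adj p < 0.10 screen):")
print(hits[["taxon_key", "coef_sign", "adj_p", "significant"]].to_string(index=False))
print(f"\nplanted responders: T00-T05; shrink intensities: "
      f"{ {k: round(v, 3) for k, v in res.shrink_intensities.items()} }")
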