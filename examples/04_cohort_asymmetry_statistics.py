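"""Cohort-level brain-behavior statistics with shuffle nulls.

Generates a 29-observer cohort with planted asymmetries and surface-area /
sensitivity coupling, computes per-observer HVA and VMA indices, the pooled
Spearman correlation between sensitivity and local surface area, and the
two shuffle null distributions that isolate the contribution of polar angle
vs individual observers.
"""

import cortmag as cm
from cortmag.stats import (CohortTable, meridian_aggregate, observer_indices,
                           paired_t, pooled_correlation, shuffle_null)

cohort = cm.make_cohort(n_observers=29, coupling=0.8, seed=12)
table = CohortTable.from_cohort(cohort)

idx = observer_indices(table)
print("group-mean asymmetry indices (%):")
for k in idx.columns:
    print(f"  {k}: {idx[k].mean():6.1f}")

agg = meridian_aggregate(table)
test = paired_t(agg["CS_HM"], agg["CS_VM"])
print(f"sensitivity HM vs VM: t({test.df}) = {test.t:.2f}, "
      f"p = {test.p:.2g}, d = {test.cohen_d:.2f}")

rho, p = pooled_correlation(table)
print(f"pooled rho (sensitivity vs wedge area, 29 x 4 pairs): "
      f"{rho:.2f} (one-tailed p = {p:.2g})")
for mode in ("across_observers", "across_locations"):
    null = shuffle_null(table, mode, n_iter=10_000, seed=1)
    print(f"  {mode:17s} null x0.95 = {null.x95:.2f} "
          f"-> {'significant' if null.significant else 'not significant'}")
print("The correlation beats both nulls only when polar angle AND "
      "individual observers each contribute shared variance.")
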