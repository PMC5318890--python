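"""Three-tier treatment of below-detection-limit chemistry.

Variables with > 50% non-detects are dropped, 10-50% get a random
Normal(LOD/2, LOD/4) imputation clamped to [0, LOD], and <= 10% get
half-LOD substitution. The report shows which rule fired and how the mean
shifted.
"""

from lakehealth.censoring import resolve_table
from lakehealth.synthetic import (apply_censoring, generate_abiotic,
                                  taihu_design, taihu_lods,
                                  taihu_variable_specs)

abiotic = generate_abiotic(taihu_design(), taihu_variable_specs(), seed=1)
censored = apply_censoring(abiotic, taihu_lods(), seed=1)
resolved, report = resolve_table(censored.table, taihu_lods(), seed=1)

print(f"{'variable':8s} {'non-detect':>10s} {'strategy':>14s} "
      f"{'mean(detects)':>14s} {'mean(after)':>12s}")
for v in report.variables:
    after = ("dropped" if v['strategy'] == 'drop'
             else f"{v['mean_after_resolution']:.4f}")
    print(f"{v['variable']:8s} {v['fraction']:>9.1%} {v['strategy']:>14s} "
          f"{v['mean_detects_only']:>14.4f} {after:>12s}")
print()
print(f"Dropped: {report.dropped} - at >90% non-detect the detected values")
print("no longer characterize the distribution, so no imputation is honest.")
print("For the imputed variables the resolved mean sits below the")
print("detects-only mean: censored values are low values, and ignoring them")
print("would bias nutrient concentrations upward.")
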