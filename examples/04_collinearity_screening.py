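"""Thin collinear predictors using the packaged published correlation matrix.

From each strongly correlated pair (|R| > 0.7, p < 0.05) the less
management-relevant member is removed by a fixed preference order.
"""

from lakehealth.screening import (load_taihu_correlations, select_predictors,
                                  strong_pairs)

m = load_taihu_correlations()
pairs = strong_pairs(m)
print(f"{len(pairs)} strong pairs among {len(m.r)} variables (n = {m.n}):")
for a, b, r, _p in pairs:
    print(f"  {a:6s} ~ {b:6s}  R = {r:+.2f}")

selected = select_predictors(m)
removed = sorted(set(m.r.columns) - set(selected) - {"Chla"})
print(f"\nRetained {len(selected)} predictors: {sorted(selected)}")
print(f"Removed as redundant: {removed}")
print()
print("Totals (TN, TP, DTP) fall to their dissolved species, and dissolved")
print("oxygen falls to water temperature: each removed variable has a")
print("retained partner that carries nearly the same information but is the")
print("more direct management lever.")
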