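"""Exact nonparametric statistics for a randomized crossover design.

Each animal is measured under both saline and drug; the within-animal
delta is tested against zero with the exact Wilcoxon signed-rank test, and
deltas of two cohorts are compared with the exact Mann-Whitney test.
"""

from somnoresp import boxplot_summary, mann_whitney_exact, wilcoxon_signed_rank_exact
from somnoresp.stats import PairedDesign

# minute ventilation (mL/min) in REM sleep, 8 animals x 2 conditions
design = PairedDesign(
    subjects=[f"m{i}" for i in range(1, 9)],
    condition_a="saline",
    condition_b="drug",
    values_a=[18.1, 20.4, 17.6, 21.0, 19.2, 18.8, 20.1, 17.9],
    values_b=[22.5, 24.1, 19.9, 25.3, 21.8, 23.0, 22.4, 20.6],
)
res = wilcoxon_signed_rank_exact(design.deltas)
print(f"within-group deltas: {[round(float(d), 1) for d in design.deltas]}")
print(f"Wilcoxon signed-rank: W = {res.statistic:.0f}, exact two-sided p = {res.p_value:.5f}")

# compare treatment effects between an intact and a lesioned cohort
lesioned_deltas = [0.8, -0.5, 1.1, 0.2, -0.9, 0.6, 0.4]
mw = mann_whitney_exact(design.deltas, lesioned_deltas)
print(f"Mann-Whitney between cohorts: U = {mw.statistic:.0f}, exact p = {mw.p_value:.5f}")

box = boxplot_summary(design.deltas)
print(
    f"delta boxplot: median {box.median:.2f} "
    f"[Q1 {box.q1:.2f}, Q3 {box.q3:.2f}], outliers {box.outliers}"
)
# p-values come from full enumeration of sign assignments / group labelings,
# appropriate at the group sizes of animal crossover studies.
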