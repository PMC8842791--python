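"""Group comparisons recomputed from printed summary statistics.

When only "mean ± SD (n)" triples are available, the summary-statistic
t-test forms reproduce the original comparisons exactly.
"""

from telofish import (GroupSummary, organoid_norm, pooled_group_summary,
                      positive_ratio, t_from_summary, t_paired)

# DNA-damage scoring: ratio of marker-positive to marker-negative cells
print(f"positive ratio for 36 positive / 100 negative cells: "
      f"{positive_ratio(36, 100):.2f}")

damage = t_from_summary(GroupSummary(0.36, 0.13, 8),
                        GroupSummary(0.22, 0.09, 8), "student")
print(f"damage-ratio t-test: t = {damage.statistic:.2f}, df = {damage.df:.0f}, "
      f"p = {damage.p:.3f}")

# telomere ratio, healthy cardia vs metaplasia (unequal n and SD -> Welch)
ratio = t_from_summary(GroupSummary(0.87, 0.23, 8),
                       GroupSummary(0.45, 0.18, 5), "welch")
print(f"cardia vs metaplasia: t = {ratio.statistic:.2f}, "
      f"df = {ratio.df:.1f}, p = {ratio.p:.4f}")

# paired comparison of matched per-specimen values
paired = t_paired([(0.50, 0.31), (0.62, 0.40), (0.38, 0.35), (0.47, 0.30)])
print(f"paired t-test: t = {paired.statistic:.2f}, p = {paired.p:.3f}")

# pooling printed per-time-point summaries into one group
pooled = pooled_group_summary([GroupSummary(2.67, 1.00, 9),
                               GroupSummary(2.25, 1.04, 8)])
print(f"pooled score: {pooled.mean:.2f} ± {pooled.sd:.2f} SD (n = {pooled.n})")

# organoid counts normalized to a starting count of 100
print(f"organoid count 75 from a start of 50 normalizes to "
      f"{organoid_norm(50, 75):.0f}")
# Each printed statistic matches the corresponding published comparison; the
# p-values are two-sided.
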