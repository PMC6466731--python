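"""Run the full cohort pipeline on a simulated two-group study.

Simulates the default study layout (control-like group, 15 eyes, vs
treated-like group, 12 eyes, 13 flash intensities, 5 sweeps each), runs
filtering, feature extraction, per-eye Hill fits and the gated group
statistics, and prints the comparison table.  Takes a few seconds.
"""

import warnings

import retinoscope as rs

warnings.filterwarnings("ignore")

cohort = rs.synth_cohort(rs.default_cohort_spec(seed=1))
results = rs.run_pipeline(cohort)

print(f"eyes analyzed: {len(cohort.eyes)}  "
      f"(features table: {len(results.features)} rows)")
print("\na-wave Hill parameter comparisons (Bonferroni m = 3):")
for (wave, param), stat in results.param_stats.items():
    if wave != "a":
        continue
    s1, s2 = stat.summaries
    print(f"  {param:8s} {stat.test_name:12s} p = {stat.p_two_tailed:6.4f} "
          f"significant = {str(stat.significant):5s}  "
          f"(group means {s1.mean:7.1f} vs {s2.mean:7.1f})")

print("\nOP areas at the designated intensities (Bonferroni m = 2):")
for idx, stat in results.op_stats.items():
    s1, s2 = stat.summaries
    print(f"  step {idx:2d}: {s1.mean:7.0f} vs {s2.mean:7.0f} uV*ms, p = {stat.p_two_tailed:.3f}")

print("\nwithin-trace amplitude ratios (medians, Mann-Whitney, m = 3):")
for name, stat in results.ratio_stats.items():
    s1, s2 = stat.summaries
    print(f"  {name:9s}: medians {s1.median:6.2f} vs {s2.median:6.2f}, p = {stat.p_two_tailed:.4f}")

print("\nExpected pattern: the a-wave V_max separates the groups while k, n,")
print("b-wave parameters and OP areas do not; OP/a and OP/b ratios shift")
print("because OP areas stay normal over a smaller photoreceptor drive.")
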