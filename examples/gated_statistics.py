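"""Normality-gated two-sample comparison and summary-statistic t tests.

First compares two simulated samples through the full gate (Shapiro-Wilk,
F test, t test or Mann-Whitney with Bonferroni adjustment), then re-tests a
published mean +/- SD pair - the open-field central locomotion of the two
mouse groups (426 +/- 156 cm, n = 13 vs 262 +/- 106 cm, n = 9) - from its
summaries alone.
"""

import numpy as np

import retinoscope as rs

rng = np.random.default_rng(7)
ctr = rng.normal(377.3, 87.5, size=15)
vpa = rng.normal(259.7, 121.1, size=12)

res = rs.two_sample_compare(ctr, vpa, m_comparisons=3)
print(f"test used        : {res.test_name} (normal flags {res.normal_flags}, "
      f"equal variances {res.variance_equal})")
print(f"statistic, p     : {res.statistic:.3f}, {res.p_two_tailed:.4f}")
print(f"alpha after m=3  : {res.alpha_effective:.4f} -> significant = {res.significant}")
print()

t, df, p = rs.t_from_summary(
    rs.SampleSummary(n=13, mean=426.0, sd=156.0),
    rs.SampleSummary(n=9, mean=262.0, sd=106.0),
    equal_var=True,
)
print(f"summary-statistic pooled t on central locomotion: t({df:.0f}) = {t:.3f}, p = {p:.4f}")
print("With rounded SDs this lands at p ~ 0.013, matching the published 0.012.")
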