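"""Pool two cohorts' estimates with the heterogeneity-gated rule.

Standard errors are recovered from printed 95% confidence intervals; the
pooling model is fixed-effect inverse variance unless Cochran's Q rejects
(p < 0.05) *and* I-squared exceeds 50%.
"""

from sibmr import se_from_ci, select_and_pool

# one-sample MR, anxiety: (estimate, LCI, UCI) per cohort, SD units
rows = [(-0.20, -0.26, -0.13), (-0.22, -0.34, -0.10)]
b = [r[0] for r in rows]
s = [se_from_ci(r[1], r[2]) for r in rows]
res = select_and_pool(b, s)
print(f"pooled: {res.pooled:+.3f} ({res.ci_low:+.3f}, {res.ci_high:+.3f})")
print(f"model: {res.model}  Q={res.Q:.2f} (p={res.Q_p:.2f})  I2={res.I2:.0f}%")
# Q is far from rejecting, so the fixed-effect model is kept and the pooled
# estimate rounds to the published -0.20

# odds ratios pool on the log scale
import numpy as np
or_rows = [(0.56, 0.44, 0.71), (0.85, 0.82, 0.89)]
b_log = [np.log(r[0]) for r in or_rows]
s_log = [se_from_ci(r[1], r[2], scale="log") for r in or_rows]
pooled = select_and_pool(b_log, s_log)
print(f"pooled OR: {np.exp(pooled.pooled):.2f} "
      f"({np.exp(pooled.ci_low):.2f}, {np.exp(pooled.ci_high):.2f}) "
      f"[{pooled.model}]")
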