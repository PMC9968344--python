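"""Score the Motion Sickness Assessment Questionnaire and compare conditions.

Sixteen items (1-9) in four dimensions; scores are percentages of summed
points.  Delta (post - pre) scores are compared between conditions with a
one-tailed Wilcoxon signed-rank test (alternative: stimulation < sham).
"""

import numpy as np

from vims_hrv import msaq_condition_comparison, score_msaq
from vims_hrv.synthetic import MSAQResponse, _msaq_items

rng = np.random.default_rng(0)
scales = ("total", "gastrointestinal", "central", "peripheral", "sopite")
d_sham = {s: [] for s in scales}
d_tes = {s: [] for s in scales}
for p in range(14):
    base = 1.5 + 0.5 * rng.standard_normal() + rng.normal(0, 0.4, 16)
    for cond, shift, out in (("sham", 1.5, d_sham), ("tes", 0.5, d_tes)):
        pre, post = _msaq_items(rng, base, shift)
        s_pre = score_msaq(MSAQResponse(pre, "pre", f"P{p}", cond))
        s_post = score_msaq(MSAQResponse(post, "post", f"P{p}", cond))
        for s in scales:
            out[s].append(s_post[s] - s_pre[s])

results = msaq_condition_comparison(
    {s: np.array(v) for s, v in d_sham.items()},
    {s: np.array(v) for s, v in d_tes.items()},
)
for scale in scales:
    r = results[scale]
    print(f"{scale:17s} delta sham {np.mean(d_sham[scale]):5.1f}%  "
          f"tes {np.mean(d_tes[scale]):5.1f}%  W = {r.statistic:5.1f}  "
          f"one-tailed p = {r.p_value:.4f}")
# Smaller symptom increases under stimulation show up as small p-values.
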