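"""Decision-curve analysis, Youden cutoff and prespecified score strata.

Net benefit compares the policy "attempt/counsel when predicted success
probability >= t" against treating everyone or no one.
"""

import numpy as np

from preecv import (
    fit_logistic,
    net_benefit,
    predict_prob,
    strata_rates,
    published_cohort_fixture,
    youden_cutoff,
)

cohort = published_cohort_fixture()
scores, outcomes = cohort.scores(), cohort.outcomes()
preds = predict_prob(fit_logistic(scores, outcomes), scores)

curve = net_benefit(preds, outcomes)
print("threshold  model   treat-all  treat-none")
for t in (0.3, 0.4, 0.5, 0.6, 0.7):
    i = int(np.argmin(np.abs(curve.thresholds - t)))
    print(f"   {t:.2f}    {curve.nb_model[i]:+.3f}    {curve.nb_treat_all[i]:+.3f}     "
          f"{curve.nb_treat_none[i]:+.3f}")
print("net benefit = TP/n - FP/n * t/(1-t); the model is useful where its "
      "curve lies above both comparators\n")

rep = youden_cutoff(scores, outcomes)
print(f"Youden-optimal cutoff: score >= {rep.cutoff} "
      f"(J = {rep.youden_j:.2f}; sens {rep.sensitivity.value:.2f}, "
      f"spec {rep.specificity.value:.2f})")

print("\nobserved success by prespecified strata:")
for st in strata_rates(scores, outcomes).strata:
    lo, hi = st.ci95
    print(f"  {st.label:>4}: {st.successes}/{st.n} = {100 * st.rate:.1f}% "
          f"(95% Wilson CI {100 * lo:.1f}-{100 * hi:.1f}%)")
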