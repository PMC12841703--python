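"""Score one patient and map the total to a success probability.

The probability mapping needs a fitted cohort model; here we fit the
univariable logistic model on the packaged 100-patient fixture cohort.
"""

from preecv import (
    Parity,
    PredictorProfile,
    Presentation,
    compute_score,
    fit_logistic,
    predict_prob,
    published_cohort_fixture,
)

patient = PredictorProfile(
    parity=Parity.MULTIPAROUS,
    presentation=Presentation.COMPLETE_BREECH,
    engaged=False,               # presenting part not engaged: +2
    palpable_head=True,          # fetal head palpable: +2
    efw_ge_10th_percentile=True, # +1
    mvp_ge_4cm=True,             # adequate fluid: +1
    placenta_posterior=False,    # anterior: +0
    tocolysis=True,              # +2
)

result = compute_score(patient)
print(f"total score: {result.total} / 13")
for factor, points in result.breakdown.items():
    print(f"  {factor:<20} {points}")

cohort = published_cohort_fixture()
fit = fit_logistic(cohort.scores(), cohort.outcomes())
prob = predict_prob(fit, result.total)
print(f"\npredicted probability of successful version: {prob:.2f}")
print("(from the univariable logistic model score -> outcome, fitted on the "
      "fixture cohort; higher totals mean better odds of turning the fetus)")
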