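"""Train the hybrid gate + SVM and classify held-out cases.

The gate learns four thresholds (per class extrema of range and ADC) from
the training cases; cases beyond the opposite class's extrema are labeled
directly ("typical"), everything else goes to the histogram SVM.
"""

from histogate import (
    HybridModel,
    classify,
    generate_cohort,
    learn_thresholds,
    records_from_cohort,
    train_svm,
)

cohort = generate_cohort(n_lym=12, n_gbm=12, seed=3)
records = records_from_cohort(cohort)
train, test = records[2:12] + records[14:], records[:2] + records[12:14]

thresholds = learn_thresholds(train, use_adc=True)
print(
    f"thresholds ({thresholds.geometry_case}): "
    f"range lym_max={thresholds.th_range_lym_max} gli_min={thresholds.th_range_gli_min}, "
    f"ADC lym_max={thresholds.th_adc_lym_max:.2f} gli_min={thresholds.th_adc_gli_min:.2f}"
)

model = HybridModel(thresholds=thresholds, svm=train_svm(train, kernel="linear"))
for case in test:
    pred = classify(case, model)
    ok = "ok " if pred.label == case.label else "MISS"
    print(f"{case.case_id}: true={case.label:13} pred={pred.label:13} route={pred.route} {ok}")
# route shows how each decision was made: by the range gate, the ADC gate,
# or the fallback SVM for nontypical cases.
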