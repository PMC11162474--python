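"""Uncertainty-based quality control on a synthetic cohort.

Generates a 30-patient cohort whose degradation spans easy to hard cases,
computes the coefficient-of-variation (CV) uncertainty and true DSC per
patient, calibrates the uncertainty threshold at the 0.61-DSC interobserver
anchor on half the cohort, and evaluates contingency, correlation and
batch referral on the other half.
"""

import numpy as np
from scipy import stats

from uqseg import (
    CohortRecord,
    PhantomSpec,
    batch_referral,
    calibrate_threshold,
    classify,
    coefficient_of_variation,
    conditional_probs,
    dsc,
    generate_cohort,
    posterior_mean,
    referral_auc,
    threshold_mask,
)

base = PhantomSpec(shape=(48, 48, 48), n_blobs=1,
                   blob_radius_range=(5.0, 9.0), n_members=5)
cohort = generate_cohort(30, [0, 2, 4, 6, 8, 10], base_spec=base, seed=7)

records = []
for i, patient in enumerate(cohort):
    cv = coefficient_of_variation(patient.stack)
    d = dsc(patient.truth, threshold_mask(posterior_mean(patient.stack)))
    records.append(CohortRecord(
        patient_id=f"P{i:03d}", uncertainty={"cv": cv}, dsc=d,
        split="calibration" if i < 15 else "evaluation",
    ))

cal = [r for r in records if r.split == "calibration"]
ev = [r for r in records if r.split == "evaluation"]

th = calibrate_threshold(cal, "cv", dsc_target=0.61)
print(f"calibrated CV threshold tau at 0.61 DSC: {th.tau:.3f}")

cont = classify(ev, th)
p_ac, p_iu, au = conditional_probs(cont)
print(f"contingency (n_ac, n_au, n_ic, n_iu) = "
      f"({cont.n_ac}, {cont.n_au}, {cont.n_ic}, {cont.n_iu})")
print(f"p(accurate | certain)     = {p_ac:.3f}")
print(f"p(inaccurate | uncertain) = {p_iu:.3f}")
print(f"accuracy-vs-uncertainty   = {au:.3f}")

rho, p = stats.pearsonr([-r.uncertainty["cv"] for r in ev], [r.dsc for r in ev])
print(f"Pearson(certainty, DSC)   = {rho:.3f} (p = {p:.2e})")

curve = batch_referral(ev, "cv", metric="dsc", stop_fraction=0.10)
print(f"\nbatch referral: mean retained DSC climbs from "
      f"{curve.points[0][1]:.3f} (nobody referred) to "
      f"{max(v for _, v in curve.points):.3f}; "
      f"R-DSC AUC = {referral_auc(curve):.3f}")
print("Referring the most CV-uncertain patients first concentrates the "
      "low-quality segmentations in the referred group.")
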