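"""Simulate a longitudinal cohort and identify every subject from a repeat scan.

Builds a 60-subject, 3-timepoint synthetic cohort (stable anatomical
signatures, -0.5%/yr drift, 2% scan-rescan noise; ICC ~ 0.94), then runs
both engines on each of the five feature sets.  Each row of the printed
summary gives macro accuracy, sensitivity, specificity and F1: sensitivity
is the fraction of subjects whose held-out scan was attributed to them;
with a strong anatomical signature it should be at or near 1.0.
"""

import morphid as m

schema = m.default_schema()
cohort = m.generate_cohort(m.default_config(n_subjects=60, seed=1))
print(f"cohort: {len(cohort.subjects)} subjects x "
      f"{len(cohort.timepoint_set)} timepoints x {cohort.n_features} features\n")

print(f"{'engine':6s} {'set':10s} {'ACC':>6s} {'SENS':>6s} {'SPEC':>6s} {'F1':>6s}")
for engine in ("lda", "wknn"):
    for set_name in ("ALL", "AREA", "THICKNESS", "VOLUME", "11LBR"):
        r = m.run_identification(cohort, schema, set_name, engine=engine, seed=7)
        print(f"{engine:6s} {set_name:10s} {r.accuracy:6.2f} {r.sensitivity:6.2f} "
              f"{r.specificity:6.2f} {r.f1:6.2f}")

print("\nEach subject's held-out scan was matched against all 60 classes;")
print("SENS = fraction of subjects correctly re-identified.")
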