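"""Generate the synthetic multi-center scenario and inspect its structure.

Builds four cohorts: A (tumor-heavy with a strong warm stain cast), B
(control-only with the opposing cool cast), C (balanced, mild cast, with
per-patient country labels) and T (small balanced held-out set).  In A+B
the class label is almost perfectly predictable from the dataset of origin
— the class-dataset confounding the downstream experiments probe.
"""

import pandas as pd

import histomil

scenario = histomil.make_multicenter_scenario("confounded_trio", scale=1, seed=7)

for name, (slides, manifest, spec) in scenario.items():
    counts = manifest.groupby("class_label")["patient_id"].nunique().to_dict()
    print(f"cohort {name}: {len(slides)} slides, patients per class {counts}")

ab = pd.concat([scenario["A"][1], scenario["B"][1]])
aligned = ((ab["dataset_id"] == "A") == (ab["class_label"] == "tumor")).mean()
print(f"\nA+B slides where dataset predicts class: {aligned:.1%}")
print("(a classifier can reach that accuracy on A+B without looking at tissue)")

slide = scenario["C"][0][0]
print(f"\nexample slide {slide.slide_id}: image {slide.image.shape}, "
      f"class {slide.class_label}, country {slide.group_label}")
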