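"""Classify organoid morphology: junk / budding / spheroid.

Builds labeled 120x120 crops from rendered single organoids, shows the
deterministic shape-rule classifier on a few of them, then trains the
logistic-regression backend and reports its held-out accuracy.
"""
from organoidq import classify, generate_labeled_crops, train_classifier

crops, labels, feats = generate_labeled_crops(60, seed=5)

print("rule-based classification of three example crops:")
for want in ("spheroid", "budding", "junk"):
    i = labels.index(want)
    pred, probs = classify(crops[i], feats[i])
    f = feats[i]
    print(f"  true {want:8s} -> predicted {pred:8s} "
          f"(p = junk {probs[0]:.2f} / budding {probs[1]:.2f} / spheroid {probs[2]:.2f}; "
          f"area {f.area_px:.0f} px, circularity {f.circularity:.2f}, "
          f"{f.lobe_count} lobes)")

model = train_classifier(crops, labels, backend="features", seed=0, features=feats)
print(f"\ntrained feature backend: held-out accuracy "
      f"{100 * model.holdout_accuracy:.1f}% on a 20% split of "
      f"{len(labels)} crops — the fraction of unseen organoids whose "
      "morphology class is predicted correctly")
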