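"""Screen synthetic photographs for usability (sharpness + exposure).

Builds 40 sharp/blurred scene pairs, fits the six-feature logistic
sharpness model on half of them, then gates a sharp scene, a blurred
variant and a darkened variant.
"""

from acnekit.quality import fit_sharpness_model, quality_gate, sharpness_features
from acnekit.synthetic import SceneSpec, degrade, render_scene

pairs = []
for i in range(40):
    rec, _ = render_scene(SceneSpec(seed=100 + i,
                                    counts={"comedone": 2, "papule": 1,
                                            "scar": 1}))
    pairs.append((rec, degrade(rec, "blur", sigma=2.0)))

feats, labels = [], []
for sharp, blurred in pairs[:20]:
    feats += [sharpness_features(sharp), sharpness_features(blurred)]
    labels += [1, 0]
model = fit_sharpness_model(feats, labels)

probe, _ = render_scene(SceneSpec(seed=999, counts={"papule": 2, "cyst": 1}))
for name, img in [("sharp", probe),
                  ("blurred", degrade(probe, "blur", sigma=2.5)),
                  ("darkened", degrade(probe, "darken", factor=0.15))]:
    rep = quality_gate(img, model)
    prob = "  n/a" if rep.sharpness_prob is None else f"{rep.sharpness_prob:.3f}"
    print(f"{name:9s} sharpness_prob={prob} exposure={rep.exposure:11s} "
          f"usable={rep.usable}")

# A usable image clears both checks: sharpness probability ≥ 0.5 and
# exposure 'ok'.  Blur drives the probability toward 0; darkening keeps the
# image sharp but fails the mean-V exposure rule.
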