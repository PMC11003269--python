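"""Compare two severity-grade labelings the way rater studies report them.

Simulates a reference labeling and a noisy 'rater' that downgrades some
images, then prints the confusion matrix, accuracy, Cohen's kappa and the
downgrade/cross-grade error fractions.
"""

import numpy as np

from acnekit.evaluation import grade_agreement_report
from acnekit.grading import Grade

rng = np.random.default_rng(11)
ref = [Grade(int(g)) for g in rng.choice([1, 2, 3, 4], size=200,
                                         p=[0.35, 0.3, 0.2, 0.15])]
pred = [Grade(max(int(g) - 1, 1)) if rng.uniform() < 0.2 else g for g in ref]

rep = grade_agreement_report(pred, ref)
print("confusion matrix (rows=reference NONE..IV, cols=predicted):")
print(rep["confusion_matrix"])
print(f"accuracy={rep['accuracy']:.3f}  kappa={rep['kappa']:.3f}")
print(f"downgrade fraction={rep['downgrade_fraction']:.2f}  "
      f"cross-grade fraction={rep['cross_grade_fraction']:.3f}")
for g in ("I", "II", "III", "IV"):
    row = rep["per_grade"][g]
    print(f"grade {g}: sensitivity={row['sensitivity']:.2f} "
          f"specificity={row['specificity']:.2f}")

# Kappa corrects raw agreement for chance; the downgrade fraction isolates
# errors that understate severity, the pattern that matters clinically.
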