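"""Train the detector on a small synthetic set, then detect and grade.

A deliberately small run (150 train images, 20 epochs, ~3 minutes on one
CPU): enough for the network to localize most lesions.  The reference
benchmark in docs/methods.md uses 300 images and 30 epochs.
"""

from acnekit.benchmark import evaluate_model, make_benchmark
from acnekit.detector import ModelConfig, TrainConfig, build_model, infer, train
from acnekit.grading import grade, grade_image

train_pairs, test_pairs = make_benchmark(n_train=150, n_test=10, seed=7)
model = build_model(ModelConfig(input_size=(64, 64), seed=0))
log = train(model, train_pairs, TrainConfig(epochs=20, seed=7))
print(f"loss: epoch0 L_total={log[0].total:.3f} -> "
      f"epoch{len(log)-1} L_total={log[-1].total:.3f}")

rec, ann = test_pairs[0]
dets, seg_instances, _ = infer(model, rec, score_min=0.3)
counts, pred_grade = grade_image(dets, seg_instances, score_min=0.3)
print(f"image {rec.id}: predicted counts={counts}")
print(f"predicted grade={pred_grade.name}  "
      f"reference grade={grade(ann.counts()).name}")

metrics = evaluate_model(model, test_pairs)
print(f"test split: mean AP@0.5={metrics['mean_ap']:.3f}  "
      f"mask IoU cyst={metrics['mask_iou']['cyst']:.3f} "
      f"scar={metrics['mask_iou']['scar']:.3f}  "
      f"grade accuracy={metrics['grade_accuracy']:.2f}")

# The multi-task loss drops as the heatmap, offset/size regression and
# segmentation branch co-train; the grade is derived from thresholded
# detection counts plus segmented cyst instances.
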