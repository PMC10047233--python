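"""Full pipeline: phantom video + clinical record -> class probabilities.

Simulates an investigation, trains the classifier on a synthetic cohort,
and runs the prediction workflow (segmentation -> TIC -> parameters ->
classifier).  The printed report mirrors the per-patient output format:
one probability per lesion class, summing to 1.
"""

from ceustic.classifier import TrainConfig, dataset_from_frame, train_classifier
from ceustic.pipeline import PipelineConfig, run_predict
from ceustic.synthetic import PhantomConfig, generate_patient_table, render_phantom, write_phantom

video = write_phantom(render_phantom(PhantomConfig(duration=60.0, frame_rate=1.0, seed=5)),
                      "scratch/investigation")

table = generate_patient_table(1000, separation=6.0, seed=0)
model = train_classifier(*dataset_from_frame(table), config=TrainConfig(seed=0))

clinical = {"Gender": 2, "Age": 71, "Cirrhosis History": 1, "Hepatitis History": 0}
cfg = PipelineConfig(output_dir="scratch/prediction")
report = run_predict(video, clinical, cfg, model=model)

print("TIC parameters:", {k: round(v, 1) for k, v in report["tic_params"].items()})
print("class probabilities:")
for name, p in report["probabilities"].items():
    print(f"  {name:<24} {p:.3f}")
print("(probabilities sum to 1; the largest is the predicted lesion type)")
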