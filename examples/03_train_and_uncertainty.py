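"""Train a small Bayesian U-Net and compute per-image uncertainty scores.

Trains a reduced-width model on 32×32 synthetic lesions with the
soft-Jaccard loss, runs Monte Carlo Dropout (T=10 stochastic passes), and
prints the cohort uncertainty table: per-image means of confidence (C),
predictive entropy (H), mutual information (MI) and expected pairwise KL
(EPKL), min–max normalised over the test cohort, and the aggregate score
U_tot = 0.4·C − 0.2·H + 0.2·MI − 0.2·EPKL.
"""

from lesionseg import (GeneratorConfig, MetaUNet, TrainConfig, default_schema,
                       generate_dataset, model_cohort_report,
                       rank_by_uncertainty, split_dataset, tiny_config, train)

samples = generate_dataset(GeneratorConfig(image_size=32, n_samples=80, seed=3))
split = split_dataset([s.id for s in samples], seed=3)
by_id = {s.id: s for s in samples}
dataset = {k: [by_id[i] for i in ids] for k, ids in split.as_dict().items()}

model = MetaUNet(tiny_config(fusion_strategy="embedding_concat", bayesian=True,
                             dropout_rate=0.1), default_schema(), seed=3)
result = train(model, dataset, TrainConfig(learning_rate=3e-3, max_epochs=20,
                                           early_stop_patience=20, loss="iou",
                                           augmentation=False, seed=3))
print(f"best epoch {result.best_epoch}, "
      f"val IoU {result.history.val_iou.iloc[result.best_epoch]:.3f}")

report = model_cohort_report(model, dataset["test"], cohort_id="demo:test",
                             T=10, seed=3)
print(report[["mean_C", "mean_H", "mean_MI", "mean_EPKL", "u_tot"]].round(4))
top = rank_by_uncertainty(report, k=3)
print("top-3 by aggregate score:", top)
# High H/MI/EPKL and low C flag images where the stochastic passes disagree,
# typically ambiguous boundaries.  Note the aggregate score's printed sign
# pattern rewards confidence (+0.4·C), so the ranking direction relative to
# "uncertainty" is a documented configuration choice; rank with
# descending=False to surface the lowest-scoring (high-entropy) images.
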