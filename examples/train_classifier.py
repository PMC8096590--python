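"""Train KecNet on a small synthetic 5-class dataset and evaluate it.

Generates a balanced dataset (100 records per AAMI class), trains for a
few epochs at desk scale, and prints the confusion matrix with the three
summary metrics.  Takes a few minutes on one CPU.
"""

from kecnet.experiments import desk_train_config, train_model
from kecnet.model import KecNetConfig, count_parameters, evaluate, predict
from kecnet.synth import synth_dataset

ds = synth_dataset(n_per_class=100, seed=0)
print(f"dataset: {len(ds)} segments, splits "
      f"{[len(ds.subset(s)) for s in ('train', 'val', 'test')]} "
      "(train/val/test)")

trained = train_model("sinc", ds, KecNetConfig(), desk_train_config(epochs=14, seed=0))
print("\ntraining history (last 3 epochs):")
print(trained.history.tail(3).to_string(index=False,
                                        float_format="%.4f".__mod__))

table, total = count_parameters(trained.model)
print(f"\ntrainable parameters: {total} total; first (sinc) layer "
      f"{table.iloc[0].n_params:.0f} "
      f"(gain {table.iloc[0].gain_vs_standard_pct:.2f}% vs free taps)")

te = ds.subset("test")
_, labels = predict(trained.model, te.segments, te.cv)
metrics = evaluate(te.labels, labels)
print("\nconfusion matrix (rows = truth N,S,V,F,Q):")
print(metrics.confusion)
print(f"ACC {100 * metrics.acc:.2f}%  SEN {100 * metrics.sen:.2f}%  "
      f"PRE {100 * metrics.pre:.2f}%")
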