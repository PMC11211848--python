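"""Train a small (1,2)-sensitive bucketing function on simulated pairs.

A Siamese pass sends both sequences of each labeled pair through one
shared-parameter inception network; the z4 hinge loss pulls the closest
aligned pair of real-valued codes together for similar pairs (edit
distance <= 1) and pushes all aligned pairs apart for dissimilar ones
(>= 2).  Prints the loss trajectory and the categorized accuracy of the
rounded hash-codes.
"""

from lsbucket import seqsim
from lsbucket.evalkit import accuracy_report
from lsbucket.losses import LossConfig
from lsbucket.lsbnet import InceptionModel, ModelConfig
from lsbucket.train import TrainConfig, train

n = 12
train_ds = seqsim.build_dataset(n, list(range(1, 6)), 200, seed=1)
val_ds = seqsim.build_dataset(n, list(range(1, 6)), 50, seed=2)
test_ds = seqsim.build_dataset(n, list(range(1, 6)), 100, seed=3)
d1, d2 = 1, 2

model = InceptionModel(
    ModelConfig(n=n, l=5, p=2, layers=1, k=8, m=12, channels=24), seed=7
)
config = TrainConfig(
    epochs=30, batch_size=128, learning_rate=2e-3, seed=5,
    d1=d1, d2=d2, loss=LossConfig(variant="z4"),
)
record = train(
    model,
    seqsim.label_pairs(train_ds, d1, d2),
    seqsim.label_pairs(val_ds, d1, d2),
    config,
)

print("epoch  train_loss  val_loss")
for e in range(0, config.epochs, 5):
    print(f"{e:5d}  {record.train_loss[e]:10.4f}  {record.val_loss[e]:8.4f}")
print(f"best validation loss {record.best_val_loss:.4f} "
      f"at epoch {record.best_epoch}")

report = accuracy_report(test_ds, model.hash_codes, d1, d2)
print("\ncategorized accuracy (fraction of pairs bucketed correctly):")
for d, acc in sorted(report.per_category.items()):
    kind = "collide" if d <= d1 else "separate"
    print(f"  d={d}: {acc:.2f}  (should {kind})")
print(f"overall accuracy: {report.overall:.2f}")
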