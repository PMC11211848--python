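"""Rescue erroneous cell barcodes with bucketed candidate retrieval.

Builds a synthetic whitelist W and erroneous set B (each erroneous barcode
is a whitelist member a small edit distance away), then compares three
candidate-pair strategies against the exact close-pair set P*:
  P1 - pairs sharing an aligned hash-code of a trained bucketing function,
  P2 - pairs sharing a kmer,
  P3 - pairs passing both filters.
All candidate sets come from inverted-index joins (linear in |B| + |W|),
never from all-versus-all comparison.
"""

from lsbucket import seqsim
from lsbucket.buckets import (
    combined_pairs,
    ground_truth_pairs,
    kmer_pairs,
    lsb_pairs,
    retrieval_metrics,
    synthetic_barcodes,
)
from lsbucket.losses import LossConfig
from lsbucket.lsbnet import InceptionModel, ModelConfig
from lsbucket.train import TrainConfig, train

n, t = 16, 1
data = synthetic_barcodes(
    n=n, whitelist_size=120, erroneous_size=400,
    error_profile={1: 0.7, 2: 0.3}, seed=8,
)
W, B = data.whitelist, data.erroneous
print(f"whitelist {len(W)} barcodes, erroneous {len(B)} barcodes "
      f"({data.erroneous_reads} reads)")

p_star = ground_truth_pairs(B, W, t)
print(f"ground truth P*: {len(p_star)} pairs within edit distance {t}")

# train a small (1,2)-LSB function on simulated pairs of the same length
train_ds = seqsim.build_dataset(n, list(range(1, 6)), 200, seed=21)
val_ds = seqsim.build_dataset(n, list(range(1, 6)), 50, seed=22)
model = InceptionModel(
    ModelConfig(n=n, l=5, p=2, layers=1, k=8, m=12, channels=24), seed=3
)
train(
    model,
    seqsim.label_pairs(train_ds, 1, 2),
    seqsim.label_pairs(val_ds, 1, 2),
    TrainConfig(epochs=30, batch_size=128, learning_rate=2e-3, seed=9,
                d1=1, d2=2, loss=LossConfig(variant="z4")),
)

p1 = lsb_pairs(B, W, model.hash_codes)
p2 = kmer_pairs(B, W, k=8)
p3 = combined_pairs(p1, p2)
for ps in (p1, p2, p3):
    recall, precision = retrieval_metrics(ps, p_star)
    print(f"{ps.tag}: {len(ps):6d} candidates, recall "
          f"{recall:.3f}, precision {precision:.3f}")
print("(recall: fraction of true close pairs retrieved; precision: "
      "fraction of candidates that are truly close)")
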