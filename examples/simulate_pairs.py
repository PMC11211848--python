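"""Simulate edit-distance-stratified sequence pairs.

Builds a small test set of length-20 DNA pairs, one category per true edit
distance, and prints the category histogram plus a few sample pairs.  Each
pair is created by mutating a random sequence and re-measuring the exact
Levenshtein distance, so the stored category is always the true distance.
"""

from lsbucket import seqsim

dataset = seqsim.build_dataset(
    n=20, d_range=list(range(1, 8)), count_per_category=100, delta=2, seed=42
)

print("category -> pairs (all verified by exact edit distance):")
for d in dataset.d_values:
    print(f"  d={d:2d}: {len(dataset.categories[d])} pairs")

print("\nexample pairs:")
for d in (1, 4, 7):
    p = dataset.categories[d][0]
    print(f"  d={d}: {p.s}  {p.t}")

labeled = seqsim.label_pairs(dataset, d1=2, d2=5)
neg = sum(p.y == -1 for p in labeled)
pos = sum(p.y == +1 for p in labeled)
print(
    f"\nlabeled for a (2,5) target: {neg} similar (y=-1), {pos} dissimilar "
    f"(y=+1); categories 2<d<5 discarded"
)
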