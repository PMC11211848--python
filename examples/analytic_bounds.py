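"""The analytic identities around bucketing for edit distance.

Two closed-form quantities frame why learned bucketing is interesting:
the bucket-universe size an optimal aligned (1,2)-bucketing needs, and
the accuracy ceiling any (1,2)-sensitive LSH family faces at distance 2
once it performs well at distance 1.
"""

from lsbucket.evalkit import bucket_universe_size, lsh_accuracy_bound

n, sigma = 20, 4
size = bucket_universe_size(n, sigma)
print(f"optimal (1,2)-bucketing for n={n}, |Sigma|={sigma} needs a bucket "
      f"universe of n*|Sigma|^(n-1) = {size:,} buckets (= 5*2^40)")
print(f"a learned function with m=40-bit codes uses 2^40 = {2**40:,}, "
      f"five times smaller")

for p1 in (0.75, 0.9, 1.0):
    bound, vacuous = lsh_accuracy_bound(p1)
    print(f"LSH with collision rate >= {p1:.2f} at distance 1 -> at most "
          f"{100 * bound:.0f}% accuracy at distance 2")
print("(the chain x -> y -> z with two distance-1 steps forces any "
      "uniformly sampled hash family into this trade-off; aligned "
      "multi-code bucketing is not bound by it)")
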