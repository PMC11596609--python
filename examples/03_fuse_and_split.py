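"""Low-level fusion of HILIC and RP blocks and the honey-level split.

Processes a small rice scenario end to end into per-mode and fused
matrices, then splits by honey: every sample of a test honey (pure and
all mixtures) leaves the training set together, so evaluation measures
generalization to honeys the models have never seen.
"""

from honeyscreen import ci_small_design, split_by_honey
from honeyscreen.pipeline import process_scenario

design = ci_small_design(seed=0)
data = process_scenario(design, "rice")

hilic, rp, fused = (data.matrix(k) for k in ("HILIC_neg", "RP_pos", "fused"))
print(f"HILIC block: {hilic.X.shape}   RP block: {rp.X.shape}   fused: {fused.X.shape}")
print(f"row sums (fused, blocks normalized before concatenation): "
      f"{fused.X.sum(axis=1).round(9).unique()}")

train, test = split_by_honey(fused.labels, n_test_honeys=2, seed=0)
test_honeys = sorted(fused.labels.loc[test, 'honey_id'].unique())
print(f"train samples: {len(train)}  test samples: {len(test)}  test honeys: {test_honeys}")
print("\nEach fused row sums to 2 (one per normalized block); no honey id "
      "appears on both sides of the split.")
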