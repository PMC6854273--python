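"""Train edge-detection networks on a small fixed-edge corpus.

Generates a 2.5%-scale fixed-edge corpus (3,600 patterns), trains a
two-network sample on raw signals from the two central visual units, and
prints training/holdout scores.  Expect a couple of minutes of compute.
"""

from dynedge.edgenet import TrainConfig
from dynedge.pipeline import corpus_features, generate_fixed_corpus, train_sample

corpus = generate_fixed_corpus(scale=0.025, seed=1)
print(f"corpus: {len(corpus)} ten-ms patterns "
      f"({int(corpus.y.sum())} edge / {int((1 - corpus.y).sum())} full-field)")

data = corpus_features(corpus, n_columns=2, mode="raw")
print(f"features: {data.X.shape[1]} raw signals from the 2 central columns")

cfg = TrainConfig(epochs=200, n_starts=5, start_epochs=25, seed=1)
result = train_sample(data, cfg, n_networks=2)
s = result.summary()
print(f"training score {100 * s['train_mean']:.1f}% +- {100 * s['train_sd']:.1f}")
print(f"holdout score  {100 * s['test_mean']:.1f}% +- {100 * s['test_sd']:.1f}")
print("chance is 50%; scores well above chance mean the network reads the "
      "difference in image dynamics across the central edge.")
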