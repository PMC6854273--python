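"""Prune a trained network and rank input significance.

Trains two small 4-column raw-signal networks on a 2.5%-scale corpus,
prunes each down to a single input, and prints the final-ten significance
ranking with each component's left-right mirror partner.
"""

from dynedge.edgenet import TrainConfig, score
from dynedge.pipeline import corpus_features, generate_fixed_corpus, train_sample
from dynedge.pruning import mirror_component, prune_full, significance_scores

corpus = generate_fixed_corpus(scale=0.025, seed=2)
data = corpus_features(corpus, n_columns=4, mode="raw")
cfg = TrainConfig(epochs=150, n_starts=3, start_epochs=20, seed=2)
result = train_sample(data, cfg, n_networks=2)

traces = []
for k, net in enumerate(result.nets):
    Xtr, ytr = data.X[result.train_idx], data.y[result.train_idx]
    print(f"net {k}: training score before pruning {100 * score(net, Xtr, ytr):.1f}%")
    trace = prune_full(net, Xtr, ytr, mode="input", retrain_epochs=40,
                       cfg=TrainConfig(seed=k))
    traces.append(trace)
    ten = dict(zip(trace.n_remaining, trace.scores))
    print(f"  score with 10 inputs left: {100 * ten[10]:.1f}%, "
          f"with 2 left: {100 * ten[2]:.1f}%")

ranking = significance_scores(traces)
top = ranking.head(8)
print("\nmost significant inputs (mean final-ten score over the sample):")
for _, row in top.iterrows():
    print(f"  {row.component:<22s} score {row.score:4.1f}  "
          f"occurrences {row.occurrences}  mirror {mirror_component(row.component, 4)}")
print("a mirror-symmetric corpus should select left/right partners together.")
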