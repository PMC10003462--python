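"""Compare the six baseline classifiers and the small neural net.

Trains each model on the 10 most significant LD-pruned SNPs of a simulated
panel and prints test accuracy / weighted F1 / AUC side by side.
"""

from gannet.classifiers import (
    ANNSpec,
    BASELINE_ALGORITHMS,
    make_split,
    train_ann,
    train_baseline,
)
from gannet.evaluation import compute_metrics
from gannet.pipeline import prepare
from gannet.simulate import paper_like_spec, simulate_genotypes

dataset, _ = simulate_genotypes(paper_like_spec(seed=1))
prep = prepare(dataset)
split = make_split(prep.dataset, seed=1)

subset = prep.subset("p005")
ids = subset.snp_ids[:10] if len(subset) >= 10 else prep.subset("all").snp_ids[:10]
x = prep.matrix.select(ids)
y = prep.matrix.phenotypes
pos = {s: i for i, s in enumerate(prep.matrix.sample_ids)}
tr = [pos[s] for s in split.train_ids]
va = [pos[s] for s in split.val_ids]
te = [pos[s] for s in split.test_ids]

print(f"{'model':<28} {'acc':>6} {'wF1':>6} {'AUC':>6}")
for algo in BASELINE_ALGORITHMS:
    scorer = train_baseline(algo, x[tr + va], y[tr + va], seed=1)
    rep = compute_metrics(scorer.predict_proba(x[te]), y[te])
    print(f"{algo:<28} {rep.accuracy:6.3f} {rep.weighted_f1:6.3f} {rep.auc:6.3f}")

net = train_ann(ANNSpec(n_inputs=len(ids)), x[tr], y[tr], x[va], y[va], seed=1)
rep = compute_metrics(net.predict_proba(x[te]), y[te])
print(f"{'ann (2x16 ReLU, sigmoid)':<28} {rep.accuracy:6.3f} "
      f"{rep.weighted_f1:6.3f} {rep.auc:6.3f}")
print(f"\nann restored checkpoint: epoch {net.best_epoch}, "
      f"val loss {net.val_loss:.3f}, train accuracy {net.train_accuracy:.3f}")
print("Small panels overfit quickly: training metrics run far ahead of test.")
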