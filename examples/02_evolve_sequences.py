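"""Evolve protein sequences with substitutions and indels down a simulated
tree, recording the true all-node alignment and every event."""

from collections import Counter

from asrbench import (
    IndelParams, RateModel, TreeSimParams, evolve, simulate_tree, tip_fasta,
)

tree = simulate_tree(TreeSimParams(n_taxa=8, height=1.0, sampling_fraction=0.25, seed=4))
model = RateModel(gamma_shape=1.8, n_categories=4)            # WAG + Gamma
history = evolve(tree, model, IndelParams(0.05, 0.05), root_length=408, seed=5)

events = Counter(kind for _, kind, _, _ in history.event_log)
print(f"root length: {len(history.sequences['N1'])} residues")
print(f"true alignment: {history.n_columns} columns x {len(history.true_alignment)} rows"
      " (tips AND ancestors)")
print(f"events: {events['substitution']} substitutions, "
      f"{events['insertion']} insertions, {events['deletion']} deletions")
tips = sorted(len(history.sequences[t]) for t in tree.tip_labels)
print(f"tip sequence lengths: {tips}")
print("\nfirst tip FASTA record:")
print("\n".join(tip_fasta(history).splitlines()[:2])[:120])
# The alignment gains columns only through insertions; removing the gaps from
# any row gives back that node's actual sequence.
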