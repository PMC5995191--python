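"""Score an estimated multiple alignment against the simulator's true
alignment with the four reference-based quality measures."""

from asrbench import (
    IndelParams, RateModel, TreeSimParams, builtin_progressive_align, evolve,
    score_msa, simulate_tree,
)
from asrbench.benchmark_pipeline import _drop_allgap_columns

tree = simulate_tree(TreeSimParams(n_taxa=8, height=1.2, sampling_fraction=0.25, seed=8))
model = RateModel()
history = evolve(tree, model, IndelParams(0.05, 0.05), root_length=200, seed=9)

reference = _drop_allgap_columns({t: history.true_alignment[t] for t in tree.tip_labels})
estimate = builtin_progressive_align({t: history.sequences[t] for t in tree.tip_labels})

scores = score_msa(estimate, reference)
print(f"estimated MSA: {len(next(iter(estimate.values())))} columns; "
      f"reference: {len(next(iter(reference.values())))} columns")
print(f"SP (Developer) score: {scores.sp_score:.3f}   "
      f"(reference residue pairs recovered)")
print(f"Modeler score:        {scores.modeler_score:.3f}   "
      f"(estimated pairs that are correct)")
print(f"Total Column score:   {scores.tc_score:.3f}   "
      f"(reference columns reproduced exactly)")
print(f"Cline shift score:    {scores.cline_shift:.3f}   "
      f"(near-miss placements earn partial credit)")
# A perfect alignment scores 1 on all four; the TC score is the strictest.
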