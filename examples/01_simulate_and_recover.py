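"""Plant five sponge triplets, run the full inference, compare to truth.

Builds a synthetic dataset (40 circRNAs, 30 miRNAs, 60 mRNAs, 5 planted
triplets at the default strong-coupling scenario), runs DE -> seed matching
-> triplet scoring -> network assembly for the aging-vs-young control
contrast, and scores the recovered edge set against the ground-truth ledger.
"""

from cerna_weaver import (
    StudyDesign,
    find_all_sites,
    generate_sequences,
    infer_network,
    simulate_counts,
)

design = StudyDesign()
seqs, truth = generate_sequences(40, 30, 60, n_planted=5, rng_seed=1)
counts = simulate_counts(design, truth, rng_seed=10_001)

sites_circ = find_all_sites(seqs["circ"], seqs["mir"], circular=True)
sites_mrna = find_all_sites(seqs["mrna"], seqs["mir"], circular=False)

net, de_records, triplets = infer_network(
    counts,
    sites_circ,
    sites_mrna,
    design.samples_for(age="young", condition="control"),
    design.samples_for(age="aging", condition="control"),
)

got = {tuple(sorted(e)) for e in net.graph.edges}
true = truth.true_edges()
tp, fp, fn = len(got & true), len(got - true), len(true - got)
f1 = 2 * tp / (2 * tp + fp + fn) if (tp + fp + fn) else 0.0

print(f"planted triplets : {len(truth.triplets)} (10 true edges)")
print(f"DE passing       : "
      + ", ".join(f"{c}={sum(r.passes_filter for r in de_records[c])}" for c in de_records))
print(f"scored triplets  : {len(triplets)}, valid: {sum(t.valid for t in triplets)}")
print(f"recovered edges  : TP={tp} FP={fp} FN={fn}  F1={f1:.2f}")
print()
print("F1 near 1 means the network contains the planted circRNA-miRNA and")
print("miRNA-mRNA arms and nothing else; background features never enter")
print("because their sequences carry no seed sites.")
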