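"""Full stepwise-PCO delimitation with mtDNA congruence on study-like data.

Simulates the study-like scenario (94 individuals, 42 loci, 10 planted taxa,
828-site mtDNA alignment), runs the recursive FD-validated clustering, and
assesses each terminal cluster against the congruence rule (fixed
differences + reciprocal monophyly + between > within divergence).
"""

from crenadelim import (
    assess_candidates,
    distance_matrix,
    make_paper_like_scenario,
    read_newick,
    simulate_allozymes,
    simulate_sequences,
    stepwise_pco,
)

spec = make_paper_like_scenario(seed=1)
gt, truth = simulate_allozymes(spec)
aln, _ = simulate_sequences(spec)

root = stepwise_pco(gt, min_fd=3)
unc = distance_matrix(aln, "p_uncorrected")
cor = distance_matrix(aln, "jc69")
report = assess_candidates(root, gt, unc, cor, read_newick(spec.tree_newick))

print(f"terminal clusters: {len(report.candidates)}")
print(f"candidate species: {report.n_candidates}\n")
print(f"{'cluster':8s} {'n':>3s} {'minFD':>5s} {'priv':>4s} {'mono':>5s} "
      f"{'mt min-between':>14s} {'mt max-within':>13s} verdict")
for c in report.candidates:
    mono = {True: "yes", False: "no", None: "n/a"}[c.monophyletic]
    mb = "-" if c.mt_min_between_uncorrected is None else f"{c.mt_min_between_uncorrected:.3f}"
    mw = "-" if c.mt_max_within_uncorrected is None else f"{c.mt_max_within_uncorrected:.3f}"
    print(f"{c.label:8s} {c.n_individuals:3d} {c.min_fd_count:5d} {c.private_fd_loci:4d} "
          f"{mono:>5s} {mb:>14s} {mw:>13s} {c.verdict}")
print(
    "\nEvery cluster is diagnosable from all others by >= 3 fixed differences,\n"
    "is monophyletic on the mtDNA tree (or a singleton), and its smallest\n"
    "between-cluster divergence exceeds any within-cluster divergence — the\n"
    "pattern that elevates clusters to candidate species."
)
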