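"""PCO of an individual-level Rogers' distance matrix.

Simulates two populations fixed for different alleles at 6 of 15 loci,
computes Rogers' distances between individuals, and embeds them with
principal co-ordinates — the clustering engine of the stepwise procedure.
"""

from crenadelim import (
    ScenarioSpec,
    distance_matrix,
    individual_profiles,
    pco,
    simulate_allozymes,
)

spec = ScenarioSpec(
    group_names=["X", "Y"],
    group_sizes={"X": 12, "Y": 12},
    n_loci=15,
    seed=4,
    fd_partitions=[[["X"], ["Y"]]] * 6,
    n_polymorphic_fillers=4,
)
gt, truth = simulate_allozymes(spec)

m = distance_matrix(individual_profiles(gt), "rogers")
res = pco(m, k=2)

print(f"eigenvalues (positive): {len(res.eigenvalues)}, negative discarded: {res.n_negative_discarded}")
print(f"axis 1 explains {res.percent_variation[0]:.1f}% of the multivariate variation")
print(f"axis 2 explains {res.percent_variation[1]:.1f}%\n")
print("first-axis scores (planted group in brackets):")
for label, x in sorted(zip(res.labels, res.axis(0)), key=lambda t: t[1]):
    print(f"  {label:6s} [{truth.group_of[label]}]  {x:+.3f}")
print(
    "\nThe two planted populations separate cleanly along axis 1; within-group\n"
    "scatter comes only from the shared polymorphic filler loci."
)
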