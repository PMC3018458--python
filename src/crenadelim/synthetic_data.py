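"""Synthetic allozyme tables, alignments and trees with planted truth.

The generator emulates the sampling design of the Crenadactylus survey this
package analyses: ~94 diploid individuals scored at 42 allozyme loci across
10 groups (6 primary regional groups, one of which — the Kimberley — splits
into 5 subgroups), plus an ~828-site mitochondrial alignment whose
between-group uncorrected divergences span roughly 0.14-0.29.

Fixed differences are planted as per-locus *block partitions* of the groups:
every block at a locus is fixed for its own allele, so any two groups in
different blocks are a strict fixed difference there and any two groups in
the same block share an allele.  The planted strict FD count between two
groups is therefore exactly the number of loci at which they fall in
different blocks — realizable by construction, no rejection sampling.
A greedy realizer (:func:`plant_fd_partitions`) converts a target FD-count
matrix into such partitions when possible and raises a validation error for
infeasible plans.

Genotypes are drawn under Hardy-Weinberg equilibrium with a configurable
missing-data rate.  Sequences evolve site-independently along a Newick tree
under GTR with optional discrete-gamma rate heterogeneity and invariant
sites; the root is drawn from the stationary frequencies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import distances as _dist
from .io_model import (
    AlleleFreqProfile,
    DistanceMatrix,
    GenotypeTable,
    SequenceAlignment,
    ValidationError,
    allele_frequencies,
    read_newick,
)

__all__ = [
    "ScenarioSpec",
    "SimTruth",
    "simulate_allozymes",
    "simulate_sequences",
    "make_paper_like_scenario",
    "plant_fd_partitions",
]

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


@dataclass
class ScenarioSpec:
    """Full description of a synthetic study, sufficient to regenerate it.

    ``fd_partitions`` lists, per planted-FD locus, the blocks of group names
    (groups omitted from every block form one implicit shared block).
    ``tolerance_loci`` plants near-fixed loci: the two named groups are fixed
    for different private alleles but share a third allele at the given low
    frequency — a fixed difference under the 10% tolerance rule but not under
    the strict rule.  Loci beyond the planted ones are fillers: the first
    ``n_polymorphic_fillers`` segregate two alleles shared by all groups, the
    rest are monomorphic.
    """

    group_names: list[str]
    group_sizes: dict[str, int]
    n_loci: int
    seed: int
    fd_partitions: list[list[list[str]]] = field(default_factory=list)
    tolerance_loci: list[tuple[str, str, float]] = field(default_factory=list)
    n_polymorphic_fillers: int = 0
    polymorphic_major_range: tuple[float, float] = (0.6, 0.9)
    missing_rate: float = 0.0
    # sequence side
    tree_newick: str | None = None
    seq_length: int = 828
    gtr_rates: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    gamma_categories: int = 4
    p_invariant: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory for reproducibility")
        names = set(self.group_names)
        if len(names) != len(self.group_names):
            raise ValidationError("duplicate group names")
        for g, n in self.group_sizes.items():
            if g not in names:
                raise ValidationError(f"size given for unknown group {g!r}")
            if n < 1:
                raise ValidationError(f"group {g!r} must have >= 1 individual")
        if set(self.group_sizes) != names:
            raise ValidationError("every group needs a size")
        n_planted = len(self.fd_partitions) + len(self.tolerance_loci)
        if n_planted + self.n_polymorphic_fillers > self.n_loci:
            raise ValidationError(
                f"FD plan needs {n_planted} loci plus {self.n_polymorphic_fillers} "
                f"polymorphic fillers but only {self.n_loci} loci are available"
            )
        for partition in self.fd_partitions:
            flat = [g for block in partition for g in block]
            if len(flat) != len(set(flat)):
                raise ValidationError(f"group repeated within partition {partition}")
            unknown = set(flat) - names
            if unknown:
                raise ValidationError(f"unknown groups in partition: {sorted(unknown)}")
        for a, b, freq in self.tolerance_loci:
            if a not in names or b not in names:
                raise ValidationError(f"unknown groups in tolerance locus ({a}, {b})")
            if not (0.0 < freq < 0.5):
                raise ValidationError(f"shared low frequency must be in (0, 0.5), got {freq}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValidationError("missing rate must be in [0, 1)")
        if not (0.0 <= self.p_invariant < 1.0):
            raise ValidationError("invariant-site proportion must be in [0, 1)")
        if not math.isclose(sum(self.base_freqs), 1.0, abs_tol=1e-6) or any(
            f <= 0 for f in self.base_freqs
        ):
            raise ValidationError("base frequencies must be positive and sum to 1")
        if any(r <= 0 for r in self.gtr_rates):
            raise ValidationError("GTR exchangeability rates must be positive")

    # -- derived structure ---------------------------------------------------

    def individual_ids(self) -> dict[str, list[str]]:
        return {
            g: [f"{g}_{i + 1:02d}" for i in range(self.group_sizes[g])]
            for g in self.group_names
        }

    def locus_names(self) -> list[str]:
        return [f"L{i + 1:02d}" for i in range(self.n_loci)]

    def _complete_partition(self, partition: list[list[str]]) -> list[list[str]]:
        listed = {g for block in partition for g in block}
        rest = [g for g in self.group_names if g not in listed]
        blocks = [list(b) for b in partition]
        if rest:
            blocks.append(rest)
        return blocks

    def planted_fd_matrix(self, tolerant: bool = False) -> DistanceMatrix:
        """Strict (or tolerance-rule) FD counts implied by the plan."""
        n = len(self.group_names)
        idx = {g: i for i, g in enumerate(self.group_names)}
        counts = np.zeros((n, n))
        for partition in self.fd_partitions:
            block_of = {}
            for bi, block in enumerate(self._complete_partition(partition)):
                for g in block:
                    block_of[g] = bi
            for g, h in itertools.combinations(self.group_names, 2):
                if block_of[g] != block_of[h]:
                    counts[idx[g], idx[h]] += 1
                    counts[idx[h], idx[g]] += 1
        if tolerant:
            for a, b, _freq in self.tolerance_loci:
                counts[idx[a], idx[b]] += 1
                counts[idx[b], idx[a]] += 1
        return DistanceMatrix(list(self.group_names), counts, statistic="fd_count")

    def planted_frequencies(self) -> dict[str, AlleleFreqProfile]:
        """The generating allele-frequency profiles (infinite-sample truth)."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 7]))
        loci = self.locus_names()
        freqs: dict[str, dict[str, dict[str, float]]] = {g: {} for g in self.group_names}
        cursor = 0
        for partition in self.fd_partitions:
            locus = loci[cursor]
            cursor += 1
            for bi, block in enumerate(self._complete_partition(partition)):
                allele = _ALPHABET[bi]
                for g in block:
                    freqs[g][locus] = {allele: 1.0}
        for a, b, low in self.tolerance_loci:
            locus = loci[cursor]
            cursor += 1
            for g in self.group_names:
                if g == a:
                    freqs[g][locus] = {"a": 1.0 - low, "c": low}
                elif g == b:
                    freqs[g][locus] = {"b": 1.0 - low, "c": low}
                else:
                    freqs[g][locus] = {"a": 0.5, "b": 0.5}
        lo, hi = self.polymorphic_major_range
        for _ in range(self.n_polymorphic_fillers):
            locus = loci[cursor]
            cursor += 1
            for g in self.group_names:
                p = float(rng.uniform(lo, hi))
                freqs[g][locus] = {"a": p, "b": 1.0 - p}
        for locus in loci[cursor:]:
            for g in self.group_names:
                freqs[g][locus] = {"a": 1.0}
        sizes = self.group_sizes
        return {
            g: AlleleFreqProfile(g, freqs[g], {l: 2 * sizes[g] for l in loci})
            for g in self.group_names
        }


@dataclass
class SimTruth:
    """Planted and realized ground truth accompanying a simulated dataset."""

    group_of: dict[str, str]
    planted_fd_strict: DistanceMatrix | None = None
    planted_fd_tolerant: DistanceMatrix | None = None
    realized_fd_strict: DistanceMatrix | None = None
    realized_fd_tolerant: DistanceMatrix | None = None
    realized_p_distances: DistanceMatrix | None = None
    tree_newick: str | None = None


def plant_fd_partitions(
    group_names: Sequence[str], target: np.ndarray, n_loci: int
) -> list[list[list[str]]]:
    """Greedy decomposition of a target FD-count matrix into locus partitions.

    Each round, groups whose remaining demand is zero are merged (union-find);
    the resulting components become the blocks of one locus, decrementing the
    demand of every pair split apart.  Raises a validation error when the
    demands cannot be met — either the plan needs more than *n_loci* loci or
    it is not decomposable into per-locus cuts (e.g. demands 1/1/3 among
    three groups).
    """
    groups = list(group_names)
    n = len(groups)
    remaining = np.array(target, dtype=int)
    if remaining.shape != (n, n) or not np.array_equal(remaining, remaining.T):
        raise ValidationError("target FD matrix must be square and symmetric")
    if np.any(np.diag(remaining) != 0) or np.any(remaining < 0):
        raise ValidationError("target FD matrix needs zero diagonal, no negatives")
    partitions: list[list[list[str]]] = []
    while remaining.any():
        if len(partitions) >= n_loci:
            raise ValidationError(
                f"infeasible FD plan: pairwise demands exceed {n_loci} loci"
            )
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(n), 2):
            if remaining[i, j] == 0:
                parent[find(i)] = find(j)
        comps: dict[int, list[str]] = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(groups[i])
        if len(comps) < 2:
            raise ValidationError(
                "infeasible FD plan: remaining demands are not decomposable into "
                "per-locus cuts (all groups forced into one block)"
            )
        blocks = list(comps.values())
        partitions.append(blocks)
        block_of = {g: bi for bi, block in enumerate(blocks) for g in block}
        for i, j in itertools.combinations(range(n), 2):
            if block_of[groups[i]] != block_of[groups[j]]:
                remaining[i, j] -= 1
                remaining[j, i] -= 1
    return partitions


# ---------------------------------------------------------------------------
# allozyme simulation


def simulate_allozymes(spec: ScenarioSpec) -> tuple[GenotypeTable, SimTruth]:
    """Draw HWE genotypes from the planted frequencies; recompute realized FDs.

    The truth records *realized* FD counts (recomputed from the emitted table
    with the same statistics the pipeline uses), not just the planted plan:
    finite samples can fail to draw a low-frequency shared allele or lose a
    locus to missing data.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    profiles = spec.planted_frequencies()
    ids_by_group = spec.individual_ids()
    loci = spec.locus_names()

    individuals: list[str] = []
    calls: dict[str, dict[str, tuple[str, str] | None]] = {}
    sites: dict[str, str] = {}
    groups: dict[str, str | None] = {}
    for g in spec.group_names:
        prof = profiles[g]
        for ind in ids_by_group[g]:
            individuals.append(ind)
            sites[ind] = g
            groups[ind] = g
            row: dict[str, tuple[str, str] | None] = {}
            for locus in loci:
                if spec.missing_rate and rng.random() < spec.missing_rate:
                    row[locus] = None
                    continue
                alleles = sorted(prof.freqs[locus])
                p = np.array([prof.freqs[locus][a] for a in alleles])
                draw = rng.choice(len(alleles), size=2, p=p)
                row[locus] = tuple(sorted(alleles[k] for k in draw))  # type: ignore[assignment]
            if all(v is None for v in row.values()):  # keep the diploid invariant
                alleles = sorted(prof.freqs[loci[0]])
                p = np.array([prof.freqs[loci[0]][a] for a in alleles])
                draw = rng.choice(len(alleles), size=2, p=p)
                row[loci[0]] = tuple(sorted(alleles[k] for k in draw))  # type: ignore[assignment]
            calls[ind] = row
    gt = GenotypeTable(individuals, loci, calls, sites, groups)

    group_of = {ind: g for g, inds in ids_by_group.items() for ind in inds}
    multi = len(spec.group_names) >= 2
    emp = allele_frequencies(gt, group_of) if multi else None
    truth = SimTruth(
        group_of=group_of,
        planted_fd_strict=spec.planted_fd_matrix(tolerant=False) if multi else None,
        planted_fd_tolerant=spec.planted_fd_matrix(tolerant=True) if multi else None,
        realized_fd_strict=_dist.distance_matrix(
            {g: emp[g] for g in spec.group_names}, "fd", tolerance=0.0
        )
        if multi
        else None,
        realized_fd_tolerant=_dist.distance_matrix(
            {g: emp[g] for g in spec.group_names}, "fd", tolerance=0.10
        )
        if multi
        else None,
        tree_newick=spec.tree_newick,
    )
    return gt, truth


# ---------------------------------------------------------------------------
# sequence simulation


def simulate_sequences(spec: ScenarioSpec) -> tuple[SequenceAlignment, SimTruth]:
    """Evolve sequences along ``spec.tree_newick`` under GTR(+G)(+I).

    Site rates: invariant with probability ``p_invariant`` (rate 0), else a
    discrete-gamma category rate rescaled so the overall mean rate is 1 —
    branch lengths therefore remain expected substitutions per site.
    """
    if spec.tree_newick is None:
        raise ValidationError("scenario has no tree")
    tree = read_newick(spec.tree_newick)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    pi = np.asarray(spec.base_freqs, dtype=float)
    Q = _dist.gtr_rate_matrix(spec.gtr_rates, pi)
    L = spec.seq_length

    if spec.gamma_shape is None:
        cat_rates = np.array([1.0])
    else:
        cat_rates = _dist.gamma_category_rates(spec.gamma_shape, spec.gamma_categories)
    # assign each site a rate; rescale variable categories so E[rate] = 1
    site_cat = np.full(L, -1)  # -1 = invariant
    variable = rng.random(L) >= spec.p_invariant
    site_cat[variable] = rng.integers(0, len(cat_rates), size=variable.sum())
    scale = 1.0 / (1.0 - spec.p_invariant) if spec.p_invariant else 1.0
    rates = np.where(site_cat >= 0, cat_rates[np.clip(site_cat, 0, None)] * scale, 0.0)

    root_state = rng.choice(4, size=L, p=pi)
    states: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = root_state
            continue
        t = node.edge.length or 0.0
        parent_state = states[id(node.parent_node)]
        child = parent_state.copy()
        if t > 0:
            for ci, r in enumerate(cat_rates):
                mask = site_cat == ci
                if not mask.any() or r * t == 0:
                    continue
                P = _dist.transition_probabilities(Q, r * t * scale)
                cum = np.cumsum(P, axis=1)
                u = rng.random(mask.sum())
                child[mask] = (u[:, None] > cum[parent_state[mask]]).sum(axis=1)
        states[id(node)] = child

    ids, seqs = [], []
    for leaf in tree.leaf_node_iter():
        ids.append(leaf.taxon.label.replace(" ", "_"))
        seqs.append("".join("ACGT"[s] for s in states[id(leaf)]))
    order = np.argsort(ids)
    aln = SequenceAlignment([ids[i] for i in order], [seqs[i] for i in order])

    realized = _dist.distance_matrix(aln, "p_uncorrected") if len(ids) > 1 else None
    group_of = {i: i.rsplit("_", 1)[0] for i in aln.ids}
    truth = SimTruth(
        group_of=group_of,
        realized_p_distances=realized,
        tree_newick=spec.tree_newick,
    )
    return aln, truth


# ---------------------------------------------------------------------------
# the study-like default scenario


_PRIMARY = ["SouthWest", "CarnarvonBasin", "CapeRange", "Pilbara", "CentralRanges"]
_KIMBERLEY = ["KimberleyA", "KimberleyB", "KimberleyC", "KimberleyD", "KimberleyE"]


def _paper_like_partitions() -> list[list[list[str]]]:
    SW, CB, CR, PB, CE = _PRIMARY
    KA, KB, KC, KD, KE = _KIMBERLEY
    K = _KIMBERLEY
    parts: list[list[list[str]]] = []
    # 6 loci: every primary group fixed for its own allele (Kimberley shares one)
    parts += [[[SW], [CB], [CR], [PB], [CE], K]] * 6
    # 3 loci: south-western vs north-central clades
    parts += [[[SW, CB, CR], [PB, CE, *K]]] * 3
    # private boosts for single primary groups
    parts += [[[SW]]] * 2 + [[[CB]]] * 2 + [[[CR]]] + [[[PB]]] * 2 + [[[CE]]] + [[K]] * 2
    # Kimberley-internal structure (each singleton block is a private allele)
    parts += [[[KA], [KB], [KC], [KD], [KE]]] * 2
    parts += [
        [[KA], [KB, KC], [KD, KE]],
        [[KB], [KA, KC, KD, KE]],
        [[KC], [KA, KB], [KD, KE]],
        [[KD], [KE], [KA, KB, KC]],
        [[KC], [KA, KD], [KB, KE]],
    ]
    return parts


def _paper_like_tree(sequenced: dict[str, int], rng: np.random.Generator) -> str:
    """Ultrametric Newick over sequenced individuals, mirroring the mtDNA
    topology: (SW,(CR,CB)) vs ((PB,CE),(KA,(KB,(KC,(KD,KE))))).

    Heights are in expected substitutions per site; the values are tuned so
    realized between-group uncorrected divergences land in ~0.14-0.29 under
    the scenario's GTR+I+G model.
    """
    SW, CB, CR, PB, CE = _PRIMARY
    KA, KB, KC, KD, KE = _KIMBERLEY
    heights = {
        "root": 0.315,
        "south": 0.27,
        "crcb": 0.23,
        "north": 0.29,
        "pbce": 0.22,
        "kim": 0.21,
        "k2": 0.19,
        "k3": 0.17,
        "k4": 0.155,
    }

    def fan(group: str, parent_h: float) -> str:
        k = sequenced[group]
        tips = [f"{group}_{i + 1:02d}" for i in range(k)]
        if k == 1:
            return f"{tips[0]}:{parent_h:.6f}"
        hw = float(rng.uniform(0.005, 0.02))
        inner = ",".join(f"{t}:{hw:.6f}" for t in tips)
        return f"({inner}):{parent_h - hw:.6f}"

    def node(children: list[str], h: float, parent_h: float) -> str:
        return "(" + ",".join(children) + f"):{parent_h - h:.6f}"

    h = heights
    south = node(
        [fan(SW, h["south"]), node([fan(CR, h["crcb"]), fan(CB, h["crcb"])], h["crcb"], h["south"])],
        h["south"],
        h["root"],
    )
    k4 = node([fan(KD, h["k4"]), fan(KE, h["k4"])], h["k4"], h["k3"])
    k3 = node([fan(KC, h["k3"]), k4], h["k3"], h["k2"])
    k2 = node([fan(KB, h["k2"]), k3], h["k2"], h["kim"])
    kim = node([fan(KA, h["kim"]), k2], h["kim"], h["north"])
    pbce = node([fan(PB, h["pbce"]), fan(CE, h["pbce"])], h["pbce"], h["north"])
    north = node([pbce, kim], h["north"], h["root"])
    return f"({south},{north});"


def make_paper_like_scenario(seed: int = 0) -> ScenarioSpec:
    """Deterministic scenario encoding the study's geometry.

    94 individuals in 10 groups (13 in the five Kimberley subgroups, with
    Kimberley A/C/D singletons), 42 loci; cross-primary planted FD counts
    >= 6 and Kimberley-internal counts in 4-14, every Kimberley subgroup
    carrying private-allele FD loci; 828-site mtDNA-like alignment for a
    Table-2-like subset of individuals under a transition-biased GTR+I+G.
    """
    sizes = {
        "SouthWest": 25,
        "CarnarvonBasin": 15,
        "CapeRange": 10,
        "Pilbara": 20,
        "CentralRanges": 11,
        "KimberleyA": 1,
        "KimberleyB": 4,
        "KimberleyC": 1,
        "KimberleyD": 1,
        "KimberleyE": 6,
    }
    sequenced = {
        "SouthWest": 7,
        "CapeRange": 4,
        "CarnarvonBasin": 10,
        "Pilbara": 10,
        "CentralRanges": 11,
        "KimberleyA": 1,
        "KimberleyB": 1,
        "KimberleyC": 1,
        "KimberleyD": 1,
        "KimberleyE": 6,
    }
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    tree = _paper_like_tree(sequenced, rng)
    return ScenarioSpec(
        group_names=[*_PRIMARY, *_KIMBERLEY],
        group_sizes=sizes,
        n_loci=42,
        seed=seed,
        fd_partitions=_paper_like_partitions(),
        tolerance_loci=[("SouthWest", "CarnarvonBasin", 0.06), ("Pilbara", "CentralRanges", 0.05)],
        n_polymorphic_fillers=6,
        missing_rate=0.01,
        tree_newick=tree,
        seq_length=828,
        gtr_rates=(1.0, 4.5, 1.0, 1.0, 4.5, 1.0),
        base_freqs=(0.35, 0.30, 0.10, 0.25),
        gamma_shape=0.75,
        p_invariant=0.35,
    )
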