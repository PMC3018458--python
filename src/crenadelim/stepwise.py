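"""Recursive stepwise-PCO species delimitation and congruence assessment.

The procedure mirrors the allozyme workflow for the Crenadactylus complex:

1. PCO of Rogers' distances among individuals;
2. candidate clusters detected on the first two PCO axes (here automated as
   average-linkage agglomerative partitions, k = 2..K_max, replacing the
   original by-eye reading of scatterplots);
3. a partition is accepted only if EVERY pair of its groups is diagnosable
   by at least ``min_fd`` fixed allozyme differences;
4. recursion within each validated cluster until no further validated split
   (or ``max_rounds`` reached) — terminal clusters are the proposed taxa;
5. congruence assessment: a terminal cluster is a candidate species when its
   fixed-difference support holds AND it is reciprocally monophyletic on the
   mtDNA tree (or monophyly is not assessable for singletons) AND its
   minimum between-cluster mtDNA divergence exceeds the maximum divergence
   within any cluster (where computable).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .distances import FDResult, distance_matrix, fixed_differences
from .io_model import (
    AlleleFreqProfile,
    DistanceMatrix,
    GenotypeTable,
    ValidationError,
    allele_frequencies,
    individual_profiles,
)
from .pco import PCOResult, pco

__all__ = [
    "ClusterNode",
    "CandidateSpecies",
    "CandidateSpeciesReport",
    "detect_clusters",
    "stepwise_pco",
    "private_allele_diagnosis",
    "is_reciprocally_monophyletic",
    "assess_candidates",
]


@dataclass
class ClusterNode:
    """One round of the recursive partition."""

    members: list[str]
    depth: int
    pco_result: PCOResult | None
    children: list["ClusterNode"] = field(default_factory=list)
    split_support: dict[tuple[int, int], FDResult] = field(default_factory=dict)

    @property
    def terminal(self) -> bool:
        return not self.children

    def terminal_clusters(self) -> list["ClusterNode"]:
        if self.terminal:
            return [self]
        out: list[ClusterNode] = []
        for child in self.children:
            out.extend(child.terminal_clusters())
        return out

    def to_nested_newick(self) -> str:
        """Cluster tree as Newick-like nesting for inspection."""
        if self.terminal:
            return "(" + ",".join(self.members) + ")"
        return "(" + ",".join(c.to_nested_newick() for c in self.children) + ")"


def _rogers_pco(gt: GenotypeTable, k: int | None = 2) -> PCOResult:
    profiles = individual_profiles(gt)
    m = distance_matrix(profiles, "rogers")
    return pco(m, k=k)


def detect_clusters(
    p: PCOResult,
    gt: GenotypeTable,
    min_fd: int = 3,
    tolerance: float = 0.0,
    k_max: int = 8,
) -> list[list[str]]:
    """FD-validated partition of the individuals behind a PCO.

    Average-linkage agglomerative partitions of the first two PCO axes are
    scanned for k = 2..min(k_max, n-1); a partition is accepted only when
    every pair of its groups shows >= *min_fd* fixed differences at the given
    tolerance.  The accepted partition with the largest k wins (ties toward
    larger k, then lexicographically smallest member sets); with none, the
    trivial single-group partition is returned.
    """
    if min_fd < 1:
        raise ValidationError(f"min_fd must be >= 1, got {min_fd}")
    n = len(p.labels)
    if n < 2:
        return [sorted(p.labels)]
    coords = p.coordinates[:, : min(2, p.n_axes)]
    Z = linkage(coords, method="average")
    sub = gt.subset(p.labels)
    best: list[list[str]] | None = None
    # k is capped at n-1 to keep the all-singletons partition out of the scan,
    # except at n=2 where the two-singleton split is the only possible one
    for k in range(2, max(min(k_max, n - 1), 2) + 1):
        assignment = fcluster(Z, t=k, criterion="maxclust")
        if len(set(assignment)) != k:
            continue
        groups: dict[int, list[str]] = {}
        for label, a in zip(p.labels, assignment):
            groups.setdefault(int(a), []).append(label)
        partition = sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])
        if _validates(sub, partition, min_fd, tolerance):
            best = partition
    return best if best is not None else [sorted(p.labels)]


def _validates(
    gt: GenotypeTable, partition: Sequence[Sequence[str]], min_fd: int, tolerance: float
) -> bool:
    grouping = {ind: str(i) for i, grp in enumerate(partition) for ind in grp}
    try:
        profiles = allele_frequencies(gt, grouping)
    except ValidationError:
        return False
    for a, b in itertools.combinations(sorted(profiles), 2):
        try:
            res = fixed_differences(profiles[a], profiles[b], tolerance)
        except ValidationError:
            return False
        if res.count < min_fd:
            return False
    return True


def stepwise_pco(
    gt: GenotypeTable,
    min_fd: int = 3,
    tolerance: float = 0.0,
    max_rounds: int = 3,
    k_max: int = 8,
) -> ClusterNode:
    """Recursive PCO + FD-validated clustering; terminals are proposed taxa."""
    if len(gt.individuals) < 2:
        raise ValidationError("stepwise PCO needs at least 2 individuals")
    return _stepwise(gt, sorted(gt.individuals), 1, min_fd, tolerance, max_rounds, k_max)


def _stepwise(
    gt: GenotypeTable,
    members: list[str],
    depth: int,
    min_fd: int,
    tolerance: float,
    max_rounds: int,
    k_max: int,
) -> ClusterNode:
    if len(members) < 2 or depth > max_rounds:
        return ClusterNode(members=sorted(members), depth=depth, pco_result=None)
    sub = gt.subset(sorted(members))
    try:
        p = _rogers_pco(sub)
    except ValidationError:  # e.g. all individuals identical -> no positive axis
        return ClusterNode(members=sorted(members), depth=depth, pco_result=None)
    partition = detect_clusters(p, sub, min_fd=min_fd, tolerance=tolerance, k_max=k_max)
    node = ClusterNode(members=sorted(members), depth=depth, pco_result=p)
    if len(partition) == 1:
        return node
    grouping = {ind: str(i) for i, grp in enumerate(partition) for ind in grp}
    profiles = allele_frequencies(sub, grouping)
    for (ia, a), (ib, b) in itertools.combinations(enumerate(sorted(profiles)), 2):
        node.split_support[(ia, ib)] = fixed_differences(
            profiles[a], profiles[b], tolerance
        )
    for grp in partition:
        node.children.append(
            _stepwise(gt, list(grp), depth + 1, min_fd, tolerance, max_rounds, k_max)
        )
    return node


# ---------------------------------------------------------------------------
# private alleles


def private_allele_diagnosis(
    profiles: Mapping[str, AlleleFreqProfile],
    fd_results: Mapping[tuple[str, str], FDResult] | None = None,
) -> dict[str, int]:
    """Per group: number of loci fixed against ALL other groups via an allele
    found in no other group.

    When *fd_results* is given, only loci appearing among the FD loci of
    every pair involving the group are counted; otherwise diagnosability is
    recomputed from the profiles (strict rule).
    """
    names = sorted(profiles)
    if len(names) < 2:
        raise ValidationError("need at least 2 profiles")
    counts: dict[str, int] = {}
    for g in names:
        prof = profiles[g]
        n_private_fd = 0
        for locus in prof.typed_loci:
            own = prof.alleles(locus)
            others = [
                profiles[h]
                for h in names
                if h != g and profiles[h].gene_copies.get(locus, 0) > 0
            ]
            if not others:
                continue
            elsewhere: set[str] = set()
            for other in others:
                elsewhere |= other.alleles(locus)
            private = own - elsewhere
            if not private:
                continue
            if fd_results is not None:
                fd_everywhere = all(
                    locus in _pair_fd(fd_results, g, h).fd_loci
                    for h in names
                    if h != g
                )
            else:
                fd_everywhere = all(own.isdisjoint(other.alleles(locus)) for other in others)
            if fd_everywhere:
                n_private_fd += 1
        counts[g] = n_private_fd
    return counts


def _pair_fd(
    fd_results: Mapping[tuple[str, str], FDResult], a: str, b: str
) -> FDResult:
    if (a, b) in fd_results:
        return fd_results[(a, b)]
    if (b, a) in fd_results:
        return fd_results[(b, a)]
    raise ValidationError(f"no FD result for pair ({a}, {b})")


# ---------------------------------------------------------------------------
# monophyly


def is_reciprocally_monophyletic(
    tree: dendropy.Tree, grouping: Mapping[str, str]
) -> dict[str, bool | None]:
    """Per-group monophyly flags on an (un)rooted tree.

    A group with >= 2 tips is monophyletic iff its tips are separated from
    all others by a single edge (clade under some rooting); singletons get
    ``None`` (not assessable).  Tip names in *grouping* must all be on the
    tree.
    """
    taxa = {t.label.replace(" ", "_"): t for t in tree.taxon_namespace}
    missing = sorted(set(grouping) - set(taxa))
    if missing:
        raise ValidationError(f"tips absent from tree: {missing}")
    tree = tree.clone(depth=1)
    tree.is_rooted = False
    tree.encode_bipartitions()
    all_mask = tree.taxon_namespace.all_taxa_bitmask()
    edge_masks = set()
    for bip in tree.bipartition_encoding:
        edge_masks.add(bip.split_bitmask & all_mask)
        edge_masks.add(~bip.split_bitmask & all_mask)

    members: dict[str, list[str]] = {}
    for tip, g in grouping.items():
        members.setdefault(g, []).append(tip)
    out: dict[str, bool | None] = {}
    for g, tips in members.items():
        if len(tips) < 2:
            out[g] = None
            continue
        mask = 0
        for tip in tips:
            mask |= tree.taxon_namespace.taxon_bitmask(taxa[tip])
        out[g] = mask in edge_masks
    return out


# ---------------------------------------------------------------------------
# congruence assessment


@dataclass
class CandidateSpecies:
    """Congruence evidence for one terminal cluster."""

    label: str
    members: list[str]
    n_individuals: int
    min_fd_count: int
    min_fd_percent: float
    private_fd_loci: int
    mt_min_between_uncorrected: float | None
    mt_min_between_corrected: float | None
    mt_max_within_uncorrected: float | None
    mt_max_within_corrected: float | None
    monophyletic: bool | None  # None = not assessable (singleton / no sequence)
    mtdna_assessed: bool
    verdict: bool

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class CandidateSpeciesReport:
    candidates: list[CandidateSpecies]
    min_fd: int
    tolerance: float

    @property
    def n_candidates(self) -> int:
        return sum(1 for c in self.candidates if c.verdict)

    def to_dict(self) -> dict:
        return {
            "min_fd": self.min_fd,
            "tolerance": self.tolerance,
            "n_terminal_clusters": len(self.candidates),
            "n_candidate_species": self.n_candidates,
            "clusters": [c.to_dict() for c in self.candidates],
        }


def assess_candidates(
    root: ClusterNode,
    gt: GenotypeTable,
    mt_uncorrected: DistanceMatrix | None = None,
    mt_corrected: DistanceMatrix | None = None,
    mt_tree: dendropy.Tree | None = None,
    min_fd: int = 3,
    tolerance: float = 0.10,
) -> CandidateSpeciesReport:
    """Populate the congruence report for the terminal clusters of a run.

    mtDNA matrices/tree may cover only a subset of individuals; clusters with
    no sequenced member fall back to allozyme-only evidence with monophyly
    and divergence fields not available.
    """
    terminals = root.terminal_clusters()
    labels = [f"C{i + 1}" for i in range(len(terminals))]
    cluster_of = {
        ind: lab for lab, node in zip(labels, terminals) for ind in node.members
    }
    profiles = allele_frequencies(gt, cluster_of)
    fd: dict[tuple[str, str], FDResult] = {}
    for a, b in itertools.combinations(labels, 2):
        fd[(a, b)] = fixed_differences(profiles[a], profiles[b], tolerance)
    private = (
        private_allele_diagnosis(profiles, fd) if len(labels) > 1 else {labels[0]: 0}
    )

    mono: dict[str, bool | None] = {}
    if mt_tree is not None:
        tip_names = {t.label.replace(" ", "_") for t in mt_tree.taxon_namespace}
        seq_grouping = {ind: c for ind, c in cluster_of.items() if ind in tip_names}
        if seq_grouping:
            mono = is_reciprocally_monophyletic(mt_tree, seq_grouping)

    def _mt_summary(m: DistanceMatrix | None, lab: str):
        if m is None:
            return None, None
        mine = [i for i, l in enumerate(m.labels) if cluster_of.get(l) == lab]
        other = [i for i, l in enumerate(m.labels) if cluster_of.get(l) not in (None, lab)]
        min_between = (
            float(min(m.values[i, j] for i in mine for j in other))
            if mine and other
            else None
        )
        max_within = (
            float(max(m.values[i, j] for i, j in itertools.combinations(mine, 2)))
            if len(mine) >= 2
            else None
        )
        return min_between, max_within

    candidates: list[CandidateSpecies] = []
    for lab, node in zip(labels, terminals):
        if len(labels) > 1:
            pair_fds = [_pair_fd(fd, lab, other) for other in labels if other != lab]
            min_count = min(r.count for r in pair_fds)
            min_percent = min(r.percent for r in pair_fds)
        else:
            min_count, min_percent = 0, 0.0
        mb_u, mw_u = _mt_summary(mt_uncorrected, lab)
        mb_c, mw_c = _mt_summary(mt_corrected, lab)
        flag = mono.get(lab)
        assessed = mb_u is not None or mb_c is not None or lab in mono
        fd_ok = min_count >= min_fd and len(labels) > 1
        mono_ok = flag is not False  # True or not-assessable
        # compare like with like: between vs within on whichever scale exists
        div_ok = True
        for mb, mw in ((mb_u, mw_u), (mb_c, mw_c)):
            if mb is not None and mw is not None and mb <= mw:
                div_ok = False
        candidates.append(
            CandidateSpecies(
                label=lab,
                members=list(node.members),
                n_individuals=len(node.members),
                min_fd_count=min_count,
                min_fd_percent=min_percent,
                private_fd_loci=private.get(lab, 0),
                mt_min_between_uncorrected=mb_u,
                mt_min_between_corrected=mb_c,
                mt_max_within_uncorrected=mw_u,
                mt_max_within_corrected=mw_c,
                monophyletic=flag,
                mtdna_assessed=assessed,
                verdict=bool(fd_ok and mono_ok and div_ok),
            )
        )
    return CandidateSpeciesReport(candidates=candidates, min_fd=min_fd, tolerance=tolerance)
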