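"""Between-taxon genetic distance and diagnosability statistics.

Allozyme side
-------------
* ``rogers_distance`` — per-locus Euclidean distance between allele-frequency
  vectors scaled to [0, 1], averaged over jointly typed loci.
* ``nei_unbiased_distance`` — Nei's (1978) unbiased standard genetic distance,
  with the small-sample (2n) correction of the within-group identities.
* ``fixed_differences`` — count of loci at which two samples share no alleles,
  optionally allowing a cumulative shared-allele tolerance: a locus still
  counts as a fixed difference when the total frequency mass of the alleles
  shared by the two groups, averaged over the two groups,
  ``m = sum_shared (p_A + p_B) / 2``, does not exceed the tolerance (default
  0.10).  ``tolerance=0`` is the strict no-shared-alleles definition.

DNA side
--------
* ``p_distance`` — proportion of differing sites under pairwise deletion
  (gaps, N and IUPAC ambiguity codes are treated as missing, never partially
  matched).
* ``corrected_distance`` — JC69/K2P/TN93 closed forms, or pairwise ML branch
  length under GTR with discrete-gamma rate heterogeneity (``gtr_g``).

All between-group statistics use pairwise deletion: only loci (or sites)
scored in both members of a comparison enter that comparison.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .io_model import (
    AlleleFreqProfile,
    DistanceMatrix,
    SequenceAlignment,
    ValidationError,
)

__all__ = [
    "FDResult",
    "rogers_distance",
    "nei_unbiased_distance",
    "fixed_differences",
    "p_distance",
    "corrected_distance",
    "distance_matrix",
    "group_divergence_summary",
    "GroupDivergenceSummary",
    "divergence_to_rate",
    "round_half_away",
]

NUCLEOTIDES = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}


def _joint_loci(a: AlleleFreqProfile, b: AlleleFreqProfile) -> list[str]:
    typed_b = set(b.typed_loci)
    loci = [l for l in a.typed_loci if l in typed_b]
    if not loci:
        raise ValidationError(
            f"no comparable loci between groups {a.group!r} and {b.group!r}"
        )
    return loci


def rogers_distance(a: AlleleFreqProfile, b: AlleleFreqProfile) -> float:
    """Rogers' (1972) genetic distance, mean over jointly typed loci.

    Per locus: ``sqrt(0.5 * sum_alleles (p_A - p_B)^2)``, alleles unioned
    across the two groups; lies in [0, 1], reaching 1 only when the groups
    are fixed for different alleles.
    """
    loci = _joint_loci(a, b)
    total = 0.0
    for locus in loci:
        pa = a.freqs[locus]
        pb = b.freqs[locus]
        ss = 0.0
        for allele in set(pa) | set(pb):
            diff = pa.get(allele, 0.0) - pb.get(allele, 0.0)
            ss += diff * diff
        total += math.sqrt(0.5 * ss)
    return total / len(loci)


def nei_unbiased_distance(a: AlleleFreqProfile, b: AlleleFreqProfile) -> float:
    """Nei's (1978) unbiased standard genetic distance.

    ``D = -ln( Jbar_AB / sqrt(Jbar_A * Jbar_B) )`` with the within-group
    identities bias-corrected for sample size:
    ``Jhat_X(l) = (2n_X * sum p^2 - 1) / (2n_X - 1)``.
    Means are taken over jointly typed loci.  Loci where either group has
    fewer than 2 typed gene copies are excluded (the correction is undefined
    there).  Small negative D caused by the correction overshooting is
    clamped to 0; groups sharing no allele at any locus give ``+inf``.
    """
    loci = _joint_loci(a, b)
    jab: list[float] = []
    ja: list[float] = []
    jb: list[float] = []
    for locus in loci:
        na, nb = a.gene_copies[locus], b.gene_copies[locus]
        if na < 2 or nb < 2:
            warnings.warn(
                f"locus {locus!r} excluded from Nei's D: fewer than 2 gene copies",
                stacklevel=2,
            )
            continue
        pa = a.freqs[locus]
        pb = b.freqs[locus]
        jab.append(sum(p * pb.get(al, 0.0) for al, p in pa.items()))
        ja.append((na * sum(p * p for p in pa.values()) - 1.0) / (na - 1.0))
        jb.append((nb * sum(p * p for p in pb.values()) - 1.0) / (nb - 1.0))
    if not jab:
        raise ValidationError(
            f"no locus with >=2 gene copies in both groups {a.group!r}, {b.group!r}"
        )
    mean_jab = float(np.mean(jab))
    mean_ja = float(np.mean(ja))
    mean_jb = float(np.mean(jb))
    if mean_jab <= 0.0:
        warnings.warn(
            f"groups {a.group!r} and {b.group!r} share no alleles: Nei's D is infinite",
            stacklevel=2,
        )
        return math.inf
    d = -math.log(mean_jab / math.sqrt(mean_ja * mean_jb))
    if d < 0.0:
        warnings.warn(
            f"Nei's D between {a.group!r} and {b.group!r} slightly negative "
            f"({d:.3e}) from the unbiased correction; clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return d


def round_half_away(x: float) -> int:
    """Round half away from zero (display convention for %FD)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass
class FDResult:
    """Fixed-difference diagnosis between two groups."""

    group_a: str
    group_b: str
    count: int
    denominator: int
    fd_loci: list[str]
    shared_mass: dict[str, float]
    tolerance: float
    private_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def percent(self) -> float:
        """Unrounded %FD = 100 * count / jointly-scorable loci."""
        return 100.0 * self.count / self.denominator

    @property
    def percent_display(self) -> int:
        """%FD rounded half away from zero, as printed in summary tables."""
        return round_half_away(self.percent)


def fixed_differences(
    a: AlleleFreqProfile,
    b: AlleleFreqProfile,
    tolerance: float = 0.10,
) -> FDResult:
    """Count loci at which two groups are (near-)fixed for different alleles.

    A locus is a fixed difference iff the cumulative shared-allele mass
    ``m = sum over alleles present in both groups of (p_A + p_B)/2`` does not
    exceed *tolerance*.  The denominator is the number of loci scorable in
    BOTH groups (not the full panel).
    """
    if not (0.0 <= tolerance < 0.5):
        raise ValidationError(f"tolerance must lie in [0, 0.5), got {tolerance}")
    loci = _joint_loci(a, b)
    fd_loci: list[str] = []
    shared_mass: dict[str, float] = {}
    for locus in loci:
        shared = a.alleles(locus) & b.alleles(locus)
        m = sum((a.freqs[locus][al] + b.freqs[locus][al]) / 2.0 for al in shared)
        shared_mass[locus] = m
        if m <= tolerance + 1e-12:
            fd_loci.append(locus)
    return FDResult(
        group_a=a.group,
        group_b=b.group,
        count=len(fd_loci),
        denominator=len(loci),
        fd_loci=fd_loci,
        shared_mass=shared_mass,
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# DNA distances


def _comparable_site_pairs(x: str, y: str) -> list[tuple[str, str]]:
    if len(x) != len(y):
        raise ValidationError(f"sequences differ in length: {len(x)} vs {len(y)}")
    pairs = []
    for cx, cy in zip(x.upper(), y.upper()):
        if cx in _NT_INDEX and cy in _NT_INDEX:
            pairs.append((cx, cy))
    return pairs


def p_distance(x: str, y: str) -> float:
    """Uncorrected proportion of differing sites, pairwise deletion."""
    pairs = _comparable_site_pairs(x, y)
    if not pairs:
        raise ValidationError("no comparable sites (all gapped/ambiguous)")
    mismatches = sum(1 for cx, cy in pairs if cx != cy)
    return mismatches / len(pairs)


def _count_matrix(x: str, y: str) -> np.ndarray:
    """4x4 site-pattern counts over comparable sites (rows = x, cols = y)."""
    counts = np.zeros((4, 4))
    for cx, cy in _comparable_site_pairs(x, y):
        counts[_NT_INDEX[cx], _NT_INDEX[cy]] += 1
    return counts


def _jc69(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        warnings.warn(f"JC69 correction undefined at p={p:.4f} (>= 0.75)", stacklevel=3)
        return math.inf
    return -0.75 * math.log(arg)


def _k2p(counts: np.ndarray) -> float:
    n = counts.sum()
    transitions = counts[0, 2] + counts[2, 0] + counts[1, 3] + counts[3, 1]  # A<->G, C<->T
    total_diff = n - np.trace(counts)
    P = transitions / n
    Q = (total_diff - transitions) / n
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0.0 or a2 <= 0.0:
        warnings.warn("K2P correction undefined (log of non-positive argument)", stacklevel=3)
        return math.inf
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


def _tn93(counts: np.ndarray) -> float:
    n = counts.sum()
    freq = (counts.sum(axis=0) + counts.sum(axis=1)) / (2.0 * n)
    gA, gC, gG, gT = freq
    gR, gY = gA + gG, gC + gT
    P1 = (counts[0, 2] + counts[2, 0]) / n  # A<->G
    P2 = (counts[1, 3] + counts[3, 1]) / n  # C<->T
    total_diff = n - np.trace(counts)
    Q = (total_diff / n) - P1 - P2
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = 1.0 - P1 * gR / (2.0 * gA * gG) - Q / (2.0 * gR) if gA * gG > 0 else 1.0
        a2 = 1.0 - P2 * gY / (2.0 * gC * gT) - Q / (2.0 * gY) if gC * gT > 0 else 1.0
        a3 = 1.0 - Q / (2.0 * gR * gY)
    if min(a1, a2, a3) <= 0.0:
        warnings.warn("TN93 correction undefined (log of non-positive argument)", stacklevel=3)
        return math.inf
    k1 = 2.0 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2.0 * gC * gT / gY if gY > 0 else 0.0
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    return -k1 * math.log(a1) - k2 * math.log(a2) - k3 * math.log(a3)


def gamma_category_rates(shape: float, ncat: int = 4) -> np.ndarray:
    """Discrete-gamma category rates (mean of each quantile band, mean 1)."""
    edges = np.linspace(0.0, 1.0, ncat + 1)
    cuts = gamma_dist.ppf(edges[1:-1], a=shape, scale=1.0 / shape)
    cuts = np.concatenate([[0.0], cuts, [np.inf]])
    # mean of a gamma(shape, 1/shape) within [lo, hi), renormalized to band mass
    rates = np.empty(ncat)
    for i in range(ncat):
        lo, hi = cuts[i], cuts[i + 1]
        mass = gamma_dist.cdf(hi, a=shape, scale=1.0 / shape) - gamma_dist.cdf(
            lo, a=shape, scale=1.0 / shape
        )
        upper = gamma_dist.cdf(hi, a=shape + 1, scale=1.0 / shape) - gamma_dist.cdf(
            lo, a=shape + 1, scale=1.0 / shape
        )
        rates[i] = upper / mass  # E[X | band] for mean-1 gamma
    return rates / rates.mean()


def gtr_rate_matrix(
    exchangeabilities: Sequence[float], base_freqs: Sequence[float]
) -> np.ndarray:
    """Normalized GTR rate matrix Q (1 expected substitution per unit time).

    *exchangeabilities* order: AC, AG, AT, CG, CT, GT.
    """
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(base_freqs, dtype=float)
    if s.shape != (6,) or np.any(s <= 0):
        raise ValidationError("GTR needs 6 positive exchangeability rates")
    if pi.shape != (4,) or np.any(pi <= 0) or not math.isclose(pi.sum(), 1.0, abs_tol=1e-6):
        raise ValidationError("base frequencies must be 4 positive values summing to 1")
    pi = pi / pi.sum()
    R = np.zeros((4, 4))
    R[0, 1] = R[1, 0] = s[0]
    R[0, 2] = R[2, 0] = s[1]
    R[0, 3] = R[3, 0] = s[2]
    R[1, 2] = R[2, 1] = s[3]
    R[1, 3] = R[3, 1] = s[4]
    R[2, 3] = R[3, 2] = s[5]
    Q = R * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    return Q / mu


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via symmetric eigendecomposition (Q GTR-reversible)."""
    pi = _stationary(Q)
    sq = np.sqrt(pi)
    S = (Q * sq[:, None]) / sq[None, :]
    S = (S + S.T) / 2.0
    w, U = np.linalg.eigh(S)
    P = (U * np.exp(w * t)) @ U.T
    P = P / sq[:, None] * sq[None, :]
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


def _stationary(Q: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(Q.T)
    i = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _gtr_gamma_ml(
    counts: np.ndarray,
    exchangeabilities: Sequence[float],
    base_freqs: Sequence[float] | None,
    gamma_shape: float,
    ncat: int,
) -> float:
    n = counts.sum()
    if base_freqs is None:
        freq = (counts.sum(axis=0) + counts.sum(axis=1)) / (2.0 * n)
        freq = np.clip(freq, 1e-6, None)
        base_freqs = freq / freq.sum()
    pi = np.asarray(base_freqs, dtype=float)
    Q = gtr_rate_matrix(exchangeabilities, pi)
    rates = gamma_category_rates(gamma_shape, ncat)

    def neg_loglik(t: float) -> float:
        mix = np.zeros((4, 4))
        for r in rates:
            mix += transition_probabilities(Q, r * t)
        mix /= len(rates)
        with np.errstate(divide="ignore"):
            logjoint = np.log(np.clip(pi[:, None] * mix, 1e-300, None))
        return -float((counts * logjoint).sum())

    if np.trace(counts) == n:
        return 0.0
    res = minimize_scalar(neg_loglik, bounds=(1e-8, 20.0), method="bounded")
    return float(res.x)


def corrected_distance(
    x: str,
    y: str,
    model: str = "gtr_g",
    *,
    exchangeabilities: Sequence[float] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
    base_freqs: Sequence[float] | None = None,
    gamma_shape: float = 0.5,
    gamma_categories: int = 4,
) -> float:
    """Model-corrected substitutions/site between two aligned sequences.

    ``jc69``, ``k2p`` and ``tn93`` use their closed forms; ``gtr_g``
    maximizes the pairwise likelihood of the branch length under GTR with
    discrete-gamma rates (frequencies empirical from the pair unless given).
    Saturated pairs where a closed-form log argument is non-positive return
    ``+inf`` with a warning.
    """
    model = model.lower()
    if model in ("p", "p_uncorrected"):
        return p_distance(x, y)
    counts = _count_matrix(x, y)
    if counts.sum() == 0:
        raise ValidationError("no comparable sites (all gapped/ambiguous)")
    if model == "jc69":
        return _jc69(1.0 - np.trace(counts) / counts.sum())
    if model == "k2p":
        return _k2p(counts)
    if model == "tn93":
        return _tn93(counts)
    if model in ("gtr_g", "gtr+g"):
        return _gtr_gamma_ml(counts, exchangeabilities, base_freqs, gamma_shape, gamma_categories)
    raise ValidationError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# matrix-level helpers


def distance_matrix(
    source: Mapping[str, AlleleFreqProfile] | SequenceAlignment,
    statistic: str,
    **params,
) -> DistanceMatrix:
    """All-pairs distance matrix.

    *source* is either a mapping group -> :class:`AlleleFreqProfile` (for
    ``rogers`` / ``nei_unbiased`` / ``fd`` / ``fd_percent``) or a
    :class:`SequenceAlignment` (for ``p_uncorrected`` / ``jc69`` / ``k2p`` /
    ``tn93`` / ``gtr_g``).  For sequence statistics the support payload holds
    the number of compared sites; for allozyme statistics the number of
    jointly typed loci.
    """
    if isinstance(source, SequenceAlignment):
        labels = list(source.ids)
        n = len(labels)
        if n < 2:
            raise ValidationError("need at least 2 sequences")
        values = np.zeros((n, n))
        support = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            x, y = source.seqs[i], source.seqs[j]
            if statistic in ("p_uncorrected", "p"):
                d = p_distance(x, y)
                tag = "p_uncorrected"
            else:
                d = corrected_distance(x, y, model=statistic, **params)
                tag = "corrected"
            values[i, j] = values[j, i] = d
            support[i, j] = support[j, i] = len(_comparable_site_pairs(x, y))
        return DistanceMatrix(labels, values, statistic=tag, support=support)

    profiles = dict(source)
    labels = list(profiles)
    n = len(labels)
    if n < 2:
        raise ValidationError("need at least 2 profiles")
    values = np.zeros((n, n))
    support = np.zeros((n, n))
    tolerance = params.get("tolerance", 0.10)
    for i, j in itertools.combinations(range(n), 2):
        a, b = profiles[labels[i]], profiles[labels[j]]
        if statistic == "rogers":
            d = rogers_distance(a, b)
            support[i, j] = support[j, i] = len(_joint_loci(a, b))
        elif statistic in ("nei", "nei_unbiased"):
            d = nei_unbiased_distance(a, b)
            support[i, j] = support[j, i] = len(_joint_loci(a, b))
        elif statistic in ("fd", "fd_count"):
            res = fixed_differences(a, b, tolerance)
            d = res.count
            support[i, j] = support[j, i] = res.denominator
        elif statistic == "fd_percent":
            res = fixed_differences(a, b, tolerance)
            d = res.percent
            support[i, j] = support[j, i] = res.denominator
        else:
            raise ValidationError(f"unknown allozyme statistic {statistic!r}")
        values[i, j] = values[j, i] = d
    tag = {"nei": "nei_unbiased", "fd": "fd_count"}.get(statistic, statistic)
    return DistanceMatrix(labels, values, statistic=tag, support=support)


@dataclass
class GroupDivergenceSummary:
    """Between/within-group divergence summary of a labelled matrix.

    ``between[(g, h)]`` holds (min, mean, max) over cross-group cells;
    ``within[g]`` holds (max, mean) over within-group cells, or ``None`` for
    singleton groups (within-group divergence is undefined, not zero).
    """

    statistic: str
    between: dict[tuple[str, str], tuple[float, float, float]]
    within: dict[str, tuple[float, float] | None]

    @property
    def min_between(self) -> float | None:
        return min((v[0] for v in self.between.values()), default=None)

    @property
    def max_between(self) -> float | None:
        return max((v[2] for v in self.between.values()), default=None)

    @property
    def max_within(self) -> float | None:
        vals = [v[0] for v in self.within.values() if v is not None]
        return max(vals) if vals else None


def group_divergence_summary(
    m: DistanceMatrix, grouping: Mapping[str, str]
) -> GroupDivergenceSummary:
    """Min/mean/max between-group and max/mean within-group divergences.

    These are the quantities the delimitation argument compares: minimum
    between-candidate divergence against maximum within-candidate divergence.
    """
    unmapped = [l for l in m.labels if l not in grouping]
    if unmapped:
        raise ValidationError(f"labels missing from grouping: {unmapped}")
    members: dict[str, list[int]] = {}
    for i, lab in enumerate(m.labels):
        members.setdefault(grouping[lab], []).append(i)
    groups = sorted(members)
    between: dict[tuple[str, str], tuple[float, float, float]] = {}
    for g, h in itertools.combinations(groups, 2):
        cells = [m.values[i, j] for i in members[g] for j in members[h]]
        between[(g, h)] = (float(np.min(cells)), float(np.mean(cells)), float(np.max(cells)))
    within: dict[str, tuple[float, float] | None] = {}
    for g in groups:
        idx = members[g]
        if len(idx) < 2:
            within[g] = None
            continue
        cells = [m.values[i, j] for i, j in itertools.combinations(idx, 2)]
        within[g] = (float(np.max(cells)), float(np.mean(cells)))
    return GroupDivergenceSummary(m.statistic, between, within)


def divergence_to_rate(d: float, crown_age: float) -> float:
    """Convert a divergence fraction to percent change per lineage per Myr.

    Two lineages diverging for *crown_age* Myr each accumulate half the
    pairwise divergence: ``rate = 100 * d / (2 * crown_age)``.
    """
    if crown_age <= 0:
        raise ValidationError(f"crown age must be positive, got {crown_age}")
    return 100.0 * d / (2.0 * crown_age)
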