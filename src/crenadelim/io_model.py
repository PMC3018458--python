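"""Shared data model and file I/O for the delimitation pipeline.

The pipeline touches four kinds of data:

* codominant diploid genotype tables (allozymes: individual x locus, two
  allele labels per cell, plus site/group metadata) in delimited text;
* per-group allele-frequency profiles derived from them;
* labelled symmetric distance matrices (Rogers, Nei, p-distance, ...);
* nucleotide alignments (FASTA) and trees (Newick).

Genotype files are comma- or tab-delimited (auto-detected) with columns
``id, site, group, <locus...>``; calls look like ``a/b`` or ``a/a``; missing
data is ``""`` or ``?``.  Allele labels are case-sensitive strings; their
alphabetical order is cosmetic (electrophoretic-mobility order plays no role
in any statistic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenotypeTable",
    "AlleleFreqProfile",
    "DistanceMatrix",
    "SequenceAlignment",
    "ParseError",
    "ValidationError",
    "read_genotypes",
    "write_genotypes",
    "allele_frequencies",
    "individual_profiles",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "read_matrix",
    "write_matrix",
]

MISSING_TOKENS = {"", "?", "NA", "na", "-"}


class ParseError(ValueError):
    """A file could not be parsed (malformed cell, bad Newick, ...)."""


class ValidationError(ValueError):
    """Parsed data violate a model invariant (duplicate IDs, ragged rows, ...)."""


Call = tuple[str, str]  # unordered diploid call, stored sorted


@dataclass
class GenotypeTable:
    """Diploid allele calls per individual x locus with site/group labels.

    ``calls[ind][locus]`` is either ``None`` (missing) or a sorted pair of
    allele labels; homozygotes are pairs of identical labels.
    """

    individuals: list[str]
    loci: list[str]
    calls: dict[str, dict[str, Call | None]]
    sites: dict[str, str] = field(default_factory=dict)
    groups: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            dupes = sorted({i for i in self.individuals if self.individuals.count(i) > 1})
            raise ValidationError(f"duplicate individual IDs: {dupes}")
        for ind in self.individuals:
            row = self.calls.get(ind, {})
            typed = 0
            for locus in self.loci:
                call = row.get(locus)
                if call is None:
                    continue
                if len(call) != 2:
                    raise ValidationError(
                        f"call for individual {ind!r} at locus {locus!r} is not diploid: {call!r}"
                    )
                typed += 1
            if typed == 0:
                raise ValidationError(f"individual {ind!r} has no typed locus")

    def call(self, ind: str, locus: str) -> Call | None:
        return self.calls[ind].get(locus)

    def allele_set(self, locus: str, individuals: Iterable[str] | None = None) -> set[str]:
        """All allele labels observed at *locus* (optionally restricted)."""
        inds = self.individuals if individuals is None else individuals
        out: set[str] = set()
        for ind in inds:
            call = self.calls[ind].get(locus)
            if call is not None:
                out.update(call)
        return out

    def subset(self, individuals: Sequence[str]) -> "GenotypeTable":
        keep = list(individuals)
        missing = [i for i in keep if i not in self.calls]
        if missing:
            raise ValidationError(f"unknown individuals: {missing}")
        return GenotypeTable(
            individuals=keep,
            loci=list(self.loci),
            calls={i: dict(self.calls[i]) for i in keep},
            sites={i: self.sites[i] for i in keep if i in self.sites},
            groups={i: self.groups.get(i) for i in keep},
        )


@dataclass
class AlleleFreqProfile:
    """Per-group allele frequencies and gene-copy counts, one group.

    ``freqs[locus]`` maps allele label -> frequency among the ``2n_l`` gene
    copies actually typed at that locus; loci with ``gene_copies == 0`` are
    untyped for this group and excluded from every between-group statistic.
    """

    group: str
    freqs: dict[str, dict[str, float]]
    gene_copies: dict[str, int]

    def __post_init__(self) -> None:
        for locus, copies in self.gene_copies.items():
            if copies < 0 or copies % 2 != 0:
                raise ValidationError(
                    f"gene-copy count at locus {locus!r} must be an even non-negative integer, got {copies}"
                )
            if copies > 0:
                total = sum(self.freqs.get(locus, {}).values())
                if not math.isclose(total, 1.0, abs_tol=1e-9):
                    raise ValidationError(
                        f"allele frequencies at locus {locus!r} sum to {total}, expected 1"
                    )
                for allele, p in self.freqs[locus].items():
                    if not (0.0 <= p <= 1.0 + 1e-12):
                        raise ValidationError(
                            f"frequency of allele {allele!r} at locus {locus!r} out of [0,1]: {p}"
                        )

    @property
    def typed_loci(self) -> list[str]:
        return [l for l, c in self.gene_copies.items() if c > 0]

    def alleles(self, locus: str) -> set[str]:
        if self.gene_copies.get(locus, 0) == 0:
            return set()
        return {a for a, p in self.freqs[locus].items() if p > 0.0}


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix of non-negative values with a statistic tag.

    ``support`` optionally carries a per-cell payload (e.g. sites compared
    for sequence distances, or jointly typed loci for allozyme distances).
    """

    labels: list[str]
    values: np.ndarray
    statistic: str = "other"
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite & finite.T], self.values.T[finite & finite.T], atol=1e-12
        ):
            raise ValidationError("matrix is not symmetric within 1e-12")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("matrix diagonal is not zero")
        with np.errstate(invalid="ignore"):
            if np.any(self.values[finite] < -1e-12):
                raise ValidationError("matrix has negative entries")
        if self.statistic == "rogers" and np.any(self.values[finite] > 1.0 + 1e-9):
            raise ValidationError("Rogers' distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        sup = self.support[np.ix_(idx, idx)] if self.support is not None else None
        return DistanceMatrix(
            labels=list(labels),
            values=self.values[np.ix_(idx, idx)],
            statistic=self.statistic,
            support=sup,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class SequenceAlignment:
    """Equal-length nucleotide sequences with optional group labels."""

    ids: list[str]
    seqs: list[str]
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValidationError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate sequence IDs")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValidationError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def sequence(self, seq_id: str) -> str:
        return self.seqs[self.ids.index(seq_id)]


# ---------------------------------------------------------------------------
# genotype table I/O


def _parse_call(cell: str, ind: str, locus: str) -> Call | None:
    cell = cell.strip()
    if cell in MISSING_TOKENS:
        return None
    parts = cell.split("/")
    if len(parts) != 2 or any(not p.strip() for p in parts):
        raise ParseError(
            f"malformed genotype cell {cell!r} for individual {ind!r} at locus {locus!r}: "
            "expected two '/'-separated allele labels"
        )
    a, b = (p.strip() for p in parts)
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read a delimited genotype table (columns ``id, site, group, <loci...>``).

    The delimiter (comma or tab) is auto-detected from the header line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 4 or cols[0].lower() != "id":
        raise ParseError(
            f"{path}: expected header 'id, site, group, <locus...>', got {cols[:3]}"
        )
    loci = cols[3:]
    individuals = df.iloc[:, 0].tolist()
    calls: dict[str, dict[str, Call | None]] = {}
    sites: dict[str, str] = {}
    groups: dict[str, str | None] = {}
    for _, row in df.iterrows():
        ind = row.iloc[0]
        sites[ind] = row.iloc[1]
        grp = row.iloc[2].strip()
        groups[ind] = grp if grp not in MISSING_TOKENS else None
        calls[ind] = {locus: _parse_call(row[locus], ind, locus) for locus in loci}
    return GenotypeTable(individuals, loci, calls, sites, groups)


def write_genotypes(gt: GenotypeTable, path: str | Path, sep: str = ",") -> None:
    rows = []
    for ind in gt.individuals:
        row: dict[str, str] = {
            "id": ind,
            "site": gt.sites.get(ind, ""),
            "group": gt.groups.get(ind) or "",
        }
        for locus in gt.loci:
            call = gt.calls[ind].get(locus)
            row[locus] = "" if call is None else "/".join(call)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# allele frequencies


def allele_frequencies(
    gt: GenotypeTable, grouping: Mapping[str, str] | None = None
) -> dict[str, AlleleFreqProfile]:
    """Per-group allele frequencies with pairwise-deletion gene-copy counts.

    *grouping* maps every individual to exactly one group; if omitted, the
    table's own group metadata is used (all individuals must carry a label).
    """
    if grouping is None:
        grouping = {}
        for ind in gt.individuals:
            g = gt.groups.get(ind)
            if g is None:
                raise ValidationError(
                    f"individual {ind!r} has no group label and no grouping was supplied"
                )
            grouping[ind] = g
    unmapped = [i for i in gt.individuals if i not in grouping]
    if unmapped:
        raise ValidationError(f"individuals missing from grouping: {unmapped}")

    members: dict[str, list[str]] = {}
    for ind in gt.individuals:
        members.setdefault(grouping[ind], []).append(ind)
    for group, inds in members.items():
        if not inds:
            raise ValidationError(f"group {group!r} has no individuals")

    profiles: dict[str, AlleleFreqProfile] = {}
    for group, inds in members.items():
        freqs: dict[str, dict[str, float]] = {}
        copies: dict[str, int] = {}
        for locus in gt.loci:
            counts: dict[str, int] = {}
            n_copies = 0
            for ind in inds:
                call = gt.calls[ind].get(locus)
                if call is None:
                    continue
                for allele in call:
                    counts[allele] = counts.get(allele, 0) + 1
                n_copies += 2
            copies[locus] = n_copies
            if n_copies:
                freqs[locus] = {a: c / n_copies for a, c in sorted(counts.items())}
        profiles[group] = AlleleFreqProfile(group, freqs, copies)
    return profiles


def individual_profiles(gt: GenotypeTable) -> dict[str, AlleleFreqProfile]:
    """One profile per individual (frequencies 0/0.5/1), for individual-level
    distance matrices such as the PCO input."""
    return allele_frequencies(gt, {ind: ind for ind in gt.individuals})


# ---------------------------------------------------------------------------
# FASTA / Newick / matrix I/O


def read_fasta(path: str | Path) -> SequenceAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return SequenceAlignment([r.id for r in records], [str(r.seq) for r in records])


def write_fasta(aln: SequenceAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Parse a Newick tree from a file path or a literal Newick string."""
    s = str(path_or_string)
    try:
        if s.lstrip().startswith("("):
            return dendropy.Tree.get(data=s, schema="newick")
        return dendropy.Tree.get(path=s, schema="newick")
    except Exception as exc:  # dendropy raises assorted error types
        raise ParseError(f"unparseable Newick input: {exc}") from exc


def write_matrix(m: DistanceMatrix, path: str | Path) -> None:
    """Write a labelled square matrix as TSV with a ``# statistic:`` header."""
    with open(path, "w") as fh:
        fh.write(f"# statistic: {m.statistic}\n")
        fh.write("label\t" + "\t".join(m.labels) + "\n")
        for i, lab in enumerate(m.labels):
            cells = "\t".join(repr(float(v)) for v in m.values[i])
            fh.write(f"{lab}\t{cells}\n")


def read_matrix(path: str | Path) -> DistanceMatrix:
    statistic = "other"
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("statistic:"):
                    statistic = body.split(":", 1)[1].strip()
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise ParseError(f"{path}: empty matrix file")
    labels = rows[0][1:]
    n = len(labels)
    values = np.empty((n, n), dtype=float)
    if len(rows) - 1 != n:
        raise ParseError(f"{path}: {len(rows) - 1} rows for {n} column labels")
    for i, row in enumerate(rows[1:]):
        if len(row) != n + 1:
            raise ParseError(f"{path}: row {row[0]!r} has {len(row) - 1} cells, expected {n}")
        values[i] = [float(c) for c in row[1:]]
    return DistanceMatrix(labels, values, statistic=statistic)
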