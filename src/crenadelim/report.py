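"""Summary tables, the end-to-end pipeline, and access to the published
matrices for the Crenadactylus complex.

Two summary operations reproduce the headline statistics of the published
combined tables:

* ``summarize_fd_matrix`` — fixed-difference counts + %FD (lower-triangle
  style) alongside Nei's unbiased D, with mean/min/max %FD over all pairs;
* ``summarize_divergence_matrix`` — uncorrected vs corrected mtDNA
  divergences, with minimum between-group and maximum within-group values,
  the quantities the delimitation argument compares.

``run_pipeline`` wires the whole analysis together from a JSON config:
genotypes -> stepwise PCO -> candidate assessment -> matrices + report, with
one structured provenance log line per stage (inputs hashed, parameters
echoed).
"""

from __future__ import annotations

import hashlib
import itertools
import json
import time
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import distances as dist
from .io_model import (
    DistanceMatrix,
    ValidationError,
    allele_frequencies,
    read_fasta,
    read_genotypes,
    read_matrix,
    read_newick,
    write_matrix,
)
from .stepwise import assess_candidates, stepwise_pco

__all__ = [
    "SummaryTable",
    "summarize_fd_matrix",
    "summarize_divergence_matrix",
    "load_published_matrix",
    "run_pipeline",
]

_PUBLISHED = {
    "fd_counts": "table1_fd_counts.tsv",
    "fd_percent": "table1_fd_percent.tsv",
    "nei": "table1_nei.tsv",
    "mt_uncorrected": "table2_uncorrected.tsv",
    "mt_corrected": "table2_corrected.tsv",
}


def load_published_matrix(name: str) -> DistanceMatrix:
    """Load one of the transcribed published matrices shipped with the package.

    Names: ``fd_counts``, ``fd_percent``, ``nei`` (allozyme summary) and
    ``mt_uncorrected``, ``mt_corrected`` (mitochondrial divergences).  These
    are test/demonstration fixtures, never pipeline defaults.
    """
    if name not in _PUBLISHED:
        raise ValidationError(f"unknown published matrix {name!r}; choose from {sorted(_PUBLISHED)}")
    ref = resources.files("crenadelim.data") / _PUBLISHED[name]
    with resources.as_file(ref) as path:
        return read_matrix(path)


def _offdiag(m: DistanceMatrix) -> np.ndarray:
    iu = np.triu_indices(m.n, 1)
    return m.values[iu]


@dataclass
class SummaryTable:
    """Combined matrix view plus recomputable headline statistics."""

    combined: pd.DataFrame
    headline: dict[str, float | None]

    def to_text(self) -> str:
        lines = [self.combined.to_string(), ""]
        for key, value in self.headline.items():
            lines.append(f"{key}: {'NA' if value is None else round(value, 4)}")
        return "\n".join(lines)


def summarize_fd_matrix(
    fd_counts: DistanceMatrix,
    fd_percent: DistanceMatrix,
    nei: DistanceMatrix,
) -> SummaryTable:
    """Combined allozyme summary: FD count (%FD) below, Nei's D above the
    diagonal; headline mean/min/max %FD over all pairs."""
    labels = fd_counts.labels
    if fd_percent.labels != labels or nei.labels != labels:
        raise ValidationError("FD count, %FD and Nei matrices must share labels")
    combined = pd.DataFrame("-", index=labels, columns=labels, dtype=object)
    for i, j in itertools.combinations(range(len(labels)), 2):
        combined.iloc[j, i] = (
            f"{fd_counts.values[j, i]:.0f} ({dist.round_half_away(fd_percent.values[j, i])}%)"
        )
        combined.iloc[i, j] = f"{nei.values[i, j]:.3f}"
    pct = _offdiag(fd_percent)
    headline = {
        "mean_percent_fd": float(np.mean(pct)),
        "min_percent_fd": float(np.min(pct)),
        "max_percent_fd": float(np.max(pct)),
        "min_fd_count": float(np.min(_offdiag(fd_counts))),
        "max_fd_count": float(np.max(_offdiag(fd_counts))),
        "min_nei": float(np.min(_offdiag(nei))),
        "max_nei": float(np.max(_offdiag(nei))),
    }
    return SummaryTable(combined=combined, headline=headline)


def summarize_divergence_matrix(
    upper: DistanceMatrix,
    lower: DistanceMatrix,
    grouping: Mapping[str, str] | None = None,
) -> SummaryTable:
    """Mitochondrial summary: uncorrected above, corrected below the diagonal.

    *grouping* maps matrix labels to groups (default: each label its own
    group, as in a one-row-per-taxon published matrix).  Headlines report the
    minimum between-group value of both triangles and the maximum
    within-group value where groups have >= 2 members (``None`` otherwise —
    undefined, not zero).
    """
    labels = upper.labels
    if lower.labels != labels:
        raise ValidationError("upper and lower matrices must share labels")
    if grouping is None:
        grouping = {l: l for l in labels}
    combined = pd.DataFrame("-", index=labels, columns=labels, dtype=object)
    for i, j in itertools.combinations(range(len(labels)), 2):
        combined.iloc[i, j] = f"{upper.values[i, j]:.3f}"
        combined.iloc[j, i] = f"{lower.values[j, i]:.3f}"
    su = dist.group_divergence_summary(upper, grouping)
    sl = dist.group_divergence_summary(lower, grouping)
    headline = {
        "min_between_uncorrected": su.min_between,
        "max_between_uncorrected": su.max_between,
        "max_within_uncorrected": su.max_within,
        "min_between_corrected": sl.min_between,
        "max_between_corrected": sl.max_between,
        "max_within_corrected": sl.max_within,
    }
    return SummaryTable(combined=combined, headline=headline)


# ---------------------------------------------------------------------------
# pipeline


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path | None = None) -> dict:
    """End-to-end delimitation from a JSON config (path or mapping).

    Config keys: ``genotypes`` (required path), optional ``fasta`` and
    ``tree`` paths, parameters ``min_fd`` (default 3), ``validation_tolerance``
    (default 0.0), ``tolerance`` (reported %FD tolerance, default 0.10),
    ``max_rounds`` (default 3), ``seq_model`` (default ``gtr_g``), and
    ``out_dir``.  Returns the report dict; writes matrices, the cluster
    nesting, the JSON report and a provenance log when an output directory
    is configured.
    """
    if not isinstance(config, Mapping):
        config_path = Path(config)
        if not config_path.exists():
            raise ValidationError(f"config file not found: {config_path}")
        config = json.loads(config_path.read_text())
    if "genotypes" not in config:
        raise ValidationError("config is missing required field 'genotypes'")
    geno_path = Path(config["genotypes"])
    if not geno_path.exists():
        raise ValidationError(f"genotype file not found: {geno_path}")

    out = Path(out_dir or config.get("out_dir", "")) if (out_dir or config.get("out_dir")) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, **info) -> None:
        payload = " ".join(f"{k}={v}" for k, v in info.items())
        log_lines.append(f"[{time.strftime('%Y-%m-%dT%H:%M:%S')}] stage={stage} {payload}")

    min_fd = int(config.get("min_fd", 3))
    validation_tol = float(config.get("validation_tolerance", 0.0))
    report_tol = float(config.get("tolerance", 0.10))
    max_rounds = int(config.get("max_rounds", 3))

    t0 = time.time()
    gt = read_genotypes(geno_path)
    log("read_genotypes", path=geno_path, sha256=_sha256(geno_path),
        n_individuals=len(gt.individuals), n_loci=len(gt.loci))

    root = stepwise_pco(gt, min_fd=min_fd, tolerance=validation_tol, max_rounds=max_rounds)
    terminals = root.terminal_clusters()
    log("stepwise_pco", min_fd=min_fd, validation_tolerance=validation_tol,
        max_rounds=max_rounds, n_terminal=len(terminals))

    mt_unc = mt_cor = None
    mt_tree = None
    if config.get("fasta"):
        fasta_path = Path(config["fasta"])
        if not fasta_path.exists():
            raise ValidationError(f"FASTA file not found: {fasta_path}")
        aln = read_fasta(fasta_path)
        mt_unc = dist.distance_matrix(aln, "p_uncorrected")
        mt_cor = dist.distance_matrix(aln, config.get("seq_model", "gtr_g"))
        log("seqdiv", path=fasta_path, sha256=_sha256(fasta_path),
            n_sequences=len(aln.ids), length=aln.length,
            model=config.get("seq_model", "gtr_g"))
    if config.get("tree"):
        tree_path = Path(config["tree"])
        if not tree_path.exists():
            raise ValidationError(f"tree file not found: {tree_path}")
        mt_tree = read_newick(tree_path)
        log("read_tree", path=tree_path, sha256=_sha256(tree_path))

    report = assess_candidates(
        root, gt, mt_unc, mt_cor, mt_tree, min_fd=min_fd, tolerance=report_tol
    )
    log("assess_candidates", n_candidates=report.n_candidates)

    cluster_of = {ind: c.label for c in report.candidates for ind in c.members}
    profiles = allele_frequencies(gt, cluster_of)
    result = {
        "config": {
            "min_fd": min_fd,
            "validation_tolerance": validation_tol,
            "tolerance": report_tol,
            "max_rounds": max_rounds,
        },
        "cluster_nesting": root.to_nested_newick(),
        "report": report.to_dict(),
    }
    if len(profiles) >= 2:
        fd_counts = dist.distance_matrix(profiles, "fd", tolerance=validation_tol)
        fd_percent = dist.distance_matrix(profiles, "fd_percent", tolerance=report_tol)
        nei = dist.distance_matrix(profiles, "nei_unbiased")
        summary = summarize_fd_matrix(fd_counts, fd_percent, nei)
        result["allozyme_headline"] = summary.headline
        if out is not None:
            write_matrix(fd_counts, out / "fd_counts.tsv")
            write_matrix(fd_percent, out / "fd_percent.tsv")
            write_matrix(nei, out / "nei.tsv")
            (out / "allozyme_summary.txt").write_text(summary.to_text() + "\n")
    if mt_unc is not None and mt_cor is not None:
        seq_grouping = {l: cluster_of.get(l, f"_unassigned_{l}") for l in mt_unc.labels}
        mt_summary = summarize_divergence_matrix(mt_unc, mt_cor, seq_grouping)
        result["mtdna_headline"] = mt_summary.headline
        if out is not None:
            write_matrix(mt_unc, out / "mt_uncorrected.tsv")
            write_matrix(mt_cor, out / "mt_corrected.tsv")
    log("done", seconds=round(time.time() - t0, 2))
    if out is not None:
        (out / "report.json").write_text(json.dumps(result, indent=2, sort_keys=True) + "\n")
        (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    result["log"] = log_lines
    return result
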