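"""Workflow orchestration: per-locus and concatenated analyses across schemes.

Each locus is annotated for gaps, coded under the requested indel
treatments, measured (character counts, p-distances, hierarchical
summaries, haplotypes), subjected to NJ + bootstrap, and scored for species
discrimination.  A concatenated run joins loci character-wise — each locus
contributes its nucleotide columns and, under coded schemes, its per-locus
coded characters (indels never span locus boundaries).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .discrimination import (
    DiscriminationReport,
    assess_species,
    indel_only_discrimination,
)
from .distances import (
    DistanceMatrix,
    DistanceSummary,
    count_haplotypes,
    p_distance,
    summarize_distances,
)
from .errors import ConfigError, PipelineError
from .gap_annotation import IndelSet, TerminalGapPolicy, gap_regions_for
from .indel_coding import (
    SCHEMES,
    CharacterCounts,
    ExtendedMatrix,
    MISSING,
    Scheme,
    build_extended_matrix,
    count_characters,
)
from .io_formats import (
    AlignedLocus,
    SampleMetadata,
    write_nexus,
    write_tree,
)
from .tree_inference import SupportTree, bootstrap_support

logger = logging.getLogger(__name__)


def default_pair_rule(scheme: Scheme) -> str:
    """CD analyses run on the gap-free matrix with complete deletion;
    all other schemes use pairwise deletion."""
    return "complete" if scheme == "CD" else "pairwise"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    schemes: tuple[Scheme, ...] = ("CD", "PWD", "SIC", "MCIC")
    replicates: int = 1000
    seed: int = 0
    threshold: float = 50.0
    terminal_gap_policy: TerminalGapPolicy = "exclude"
    pair_rule: str | None = None  # None = per-scheme default
    outdir: Path | None = None

    def __post_init__(self) -> None:
        if not self.schemes:
            raise ConfigError("at least one scheme must be requested")
        bad = [s for s in self.schemes if s not in SCHEMES]
        if bad:
            raise ConfigError(f"unknown scheme(s) {bad}; expected subset of {SCHEMES}")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if not 0 < self.threshold < 100:
            raise ConfigError("threshold must lie in (0, 100)")


def _derived_seed(base: int, *key: object) -> int:
    """Deterministic per-stage seed below 2**31 (stable across processes)."""
    import zlib

    digest = zlib.crc32(repr(key).encode()) & 0x7FFFFFFF
    h = np.random.SeedSequence([base & 0x7FFFFFFF, digest])
    return int(h.generate_state(1)[0]) & 0x7FFFFFFF


@dataclass
class SchemeResult:
    """All artifacts of one locus under one indel treatment."""

    scheme: Scheme
    matrix: ExtendedMatrix
    counts: CharacterCounts
    dm: DistanceMatrix
    summary: DistanceSummary
    tree: SupportTree
    report: DiscriminationReport
    indel_report: DiscriminationReport | None = None
    n_indels: int = 0


def run_locus(
    config: RunConfig,
    locus: AlignedLocus,
    meta: SampleMetadata,
) -> dict[Scheme, SchemeResult]:
    """Run every requested scheme on one locus; write artifacts if outdir set."""
    indels = gap_regions_for(locus, policy=config.terminal_gap_policy)
    haplos = count_haplotypes(locus, meta)
    results: dict[Scheme, SchemeResult] = {}
    for scheme in config.schemes:
        matrix = build_extended_matrix(locus, scheme, indels)
        counts = count_characters(matrix)
        rule = config.pair_rule or default_pair_rule(scheme)
        dm = p_distance(matrix, rule)
        summary = summarize_distances(dm, meta, haplotypes=haplos)
        seed = _derived_seed(config.seed, locus.locus_name, scheme)
        tree = bootstrap_support(
            matrix, rule, replicates=config.replicates, seed=seed
        )
        report = assess_species(
            tree, meta, threshold=config.threshold,
            scheme=scheme, locus=locus.locus_name,
        )
        indel_report = None
        if matrix.coded is not None:
            indel_report = indel_only_discrimination(
                matrix.coded, meta, locus=locus.locus_name
            )
        logger.info(
            "locus=%s scheme=%s seed=%d chars=%d VC=%d PIC=%d resolution=%.1f "
            "discarded_reps=%d",
            locus.locus_name, scheme, seed, matrix.total_length,
            counts.vc, counts.pic, report.resolution, tree.discarded_replicates,
        )
        results[scheme] = SchemeResult(
            scheme=scheme, matrix=matrix, counts=counts, dm=dm, summary=summary,
            tree=tree, report=report, indel_report=indel_report,
            n_indels=len(indels),
        )
    if config.outdir is not None:
        _write_locus_artifacts(config, locus, results)
    return results


def summary_table(results: dict[Scheme, SchemeResult]) -> pd.DataFrame:
    """One row per scheme mirroring the character-accounting and
    discrimination summary layout (indel count, aligned length, VC/PIC with
    percentages, mean inter-/intraspecific distance, per-species supports,
    resolution)."""
    rows = []
    for scheme, res in results.items():
        row = {
            "scheme": scheme,
            "n_indels": res.n_indels,
            "aligned_length": res.matrix.total_length,
            "VC": res.counts.vc,
            "VC_pct": res.counts.vc_pct,
            "PIC": res.counts.pic,
            "PIC_pct": res.counts.pic_pct,
            "mean_interspecific": (
                res.summary.interspecific[0] if res.summary.interspecific else np.nan
            ),
            "mean_intraspecific": (
                res.summary.intraspecific[0] if res.summary.intraspecific else np.nan
            ),
        }
        for a in res.report.assessments:
            row[f"support_{a.species_id}"] = (
                a.support if a.support is not None else "n.d."
            )
        row["resolution_pct"] = res.report.resolution
        row["resolved"] = f"{res.report.n_distinguished}/{res.report.n_species}"
        rows.append(row)
    return pd.DataFrame(rows)


def _write_locus_artifacts(
    config: RunConfig, locus: AlignedLocus, results: dict[Scheme, SchemeResult]
) -> None:
    base = Path(config.outdir) / locus.locus_name
    for scheme, res in results.items():
        d = base / scheme
        d.mkdir(parents=True, exist_ok=True)
        if res.matrix.coded is not None:
            write_nexus(res.matrix, d / "matrix.nex")
            res.matrix.coded.export_tsv(d / "coded_characters.tsv")
        write_tree(res.tree, d / "tree.nwk")
        res.dm.to_tsv(d / "distances.tsv")
        res.summary.to_tsv(d / "distance_summary.tsv")
        res.report.to_json(d / "discrimination.json")
        res.report.to_tsv(d / "discrimination.tsv")
        if res.indel_report is not None:
            res.indel_report.to_json(d / "indel_only_discrimination.json")
        (d / "character_counts.json").write_text(
            json.dumps(
                {
                    "scheme": scheme,
                    "total_length": res.counts.total_length,
                    "VC": res.counts.vc,
                    "VC_pct": res.counts.vc_pct,
                    "PIC": res.counts.pic,
                    "PIC_pct": res.counts.pic_pct,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
    summary_table(results).to_csv(base / "summary_table.tsv", sep="\t", index=False)


class ConcatenatedMatrix:
    """Character-wise concatenation of per-locus extended matrices.

    Individuals missing from a locus receive all-missing states for that
    locus's characters.  Exposes the ``ids`` / ``state_matrix()`` protocol
    that distance and bootstrap functions consume.
    """

    def __init__(self, parts: Sequence[ExtendedMatrix], ids: Sequence[str]):
        if not parts:
            raise PipelineError("no matrices to concatenate")
        self.parts = tuple(parts)
        self.ids = tuple(ids)
        self.scheme = parts[0].scheme

    @property
    def total_length(self) -> int:
        return sum(p.total_length for p in self.parts)

    def state_matrix(self) -> np.ndarray:
        blocks = []
        for part in self.parts:
            S = part.state_matrix()
            out = np.full((len(self.ids), S.shape[1]), MISSING, dtype=np.int16)
            pos = {sid: i for i, sid in enumerate(part.ids)}
            for i, sid in enumerate(self.ids):
                if sid in pos:
                    out[i] = S[pos[sid]]
                else:
                    logger.info(
                        "individual %s missing from locus part; padded as missing",
                        sid,
                    )
            blocks.append(out)
        return np.hstack(blocks)


@dataclass
class ConcatenatedResult:
    scheme: Scheme
    matrix: ConcatenatedMatrix
    tree: SupportTree
    report: DiscriminationReport


def run_concatenated(
    config: RunConfig,
    loci: Sequence[AlignedLocus],
    meta: SampleMetadata,
) -> dict[Scheme, ConcatenatedResult]:
    """Concatenate loci character-wise and run NJ + bootstrap + discrimination.

    Indel coding is per locus (indels never span locus boundaries).  The id
    set is the union across loci; an empty intersection is an error.
    """
    if not loci:
        raise PipelineError("no loci supplied")
    common = set(loci[0].ids)
    union: list[str] = []
    for locus in loci:
        common &= set(locus.ids)
        for sid in locus.ids:
            if sid not in union:
                union.append(sid)
    if not common:
        raise PipelineError("loci share no individual ids")
    results: dict[Scheme, ConcatenatedResult] = {}
    for scheme in config.schemes:
        parts = []
        for locus in loci:
            indels = gap_regions_for(locus, policy=config.terminal_gap_policy)
            parts.append(build_extended_matrix(locus, scheme, indels))
        cm = ConcatenatedMatrix(parts, union)
        rule = config.pair_rule or default_pair_rule(scheme)
        seed = _derived_seed(config.seed, "concatenated", scheme)
        tree = bootstrap_support(cm, rule, replicates=config.replicates, seed=seed)
        report = assess_species(
            tree, meta, threshold=config.threshold,
            scheme=scheme, locus="concatenated",
        )
        results[scheme] = ConcatenatedResult(
            scheme=scheme, matrix=cm, tree=tree, report=report
        )
        if config.outdir is not None:
            d = Path(config.outdir) / "concatenated" / scheme
            d.mkdir(parents=True, exist_ok=True)
            write_tree(tree, d / "tree.nwk")
            report.to_json(d / "discrimination.json")
    return results
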