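"""P-distances under complete/pairwise deletion, hierarchical summaries, haplotypes.

The p-distance between two sequences is the proportion of usable shared
characters at which they differ.  Usable excludes gaps, N, IUPAC ambiguity
codes and inapplicable coded states — per pair under ``pairwise`` deletion,
or globally (any sequence missing removes the character for everyone) under
``complete`` deletion.  Coded indel characters count as single characters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .errors import DistanceUndefinedError
from .io_formats import AlignedLocus, SampleMetadata

PairRule = Literal["complete", "pairwise"]


def _sigfig(x: float, sig: int = 5) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + sig - 1)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of p-distances with per-pair usable-site counts."""

    ids: tuple[str, ...]
    values: np.ndarray
    usable: np.ndarray
    scheme: str
    pair_rule: PairRule

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.values.shape == (n, n) and self.usable.shape == (n, n)

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids)).to_csv(
            path, sep="\t"
        )

    def to_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for sid, row in zip(self.ids, self.values):
                cells = " ".join(f"{v:.6f}" for v in row)
                fh.write(f"{sid}  {cells}\n")


def p_distance(matrix, pair_rule: PairRule = "pairwise") -> DistanceMatrix:
    """Pairwise p-distances of an extended matrix (or any object exposing
    ``ids`` and ``state_matrix()``).

    Raises :class:`DistanceUndefinedError` naming the first pair with zero
    usable characters.
    """
    S = matrix.state_matrix()
    ids = tuple(matrix.ids)
    values, usable = _p_distance_states(S, pair_rule)
    bad = np.argwhere(usable == 0)
    bad = bad[bad[:, 0] < bad[:, 1]]
    if bad.size:
        i, j = bad[0]
        raise DistanceUndefinedError(ids[i], ids[j])
    return DistanceMatrix(
        ids=ids,
        values=values,
        usable=usable,
        scheme=getattr(matrix, "scheme", "?"),
        pair_rule=pair_rule,
    )


def _p_distance_states(S: np.ndarray, pair_rule: PairRule) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised core: distances and usable counts from a state matrix."""
    valid = S >= 0
    if pair_rule == "complete":
        cols = valid.all(axis=0)
        S = S[:, cols]
        valid = valid[:, cols]
    both = valid[:, None, :] & valid[None, :, :]
    diff = (S[:, None, :] != S[None, :, :]) & both
    usable = both.sum(axis=2)
    ndiff = diff.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(usable > 0, ndiff / np.maximum(usable, 1), np.nan)
    np.fill_diagonal(values, 0.0)
    return values, usable


@dataclass(frozen=True)
class SpeciesDistanceStats:
    """Hierarchical p-distance summary for one species."""

    species_id: str
    n: int
    n_haplotypes: int | None
    within_population: tuple[float, float, float] | None  # (mean, min, max)
    between_population: tuple[float, float, float] | None
    intraspecific: tuple[float, float, float] | None
    computable: bool  # False when the species has a single individual


@dataclass(frozen=True)
class DistanceSummary:
    """Per-species hierarchical summary plus global inter/intraspecific means."""

    per_species: tuple[SpeciesDistanceStats, ...]
    interspecific: tuple[float, float, float] | None  # (mean, min, max) over pairs
    intraspecific: tuple[float, float, float] | None  # mean of per-species means
    scheme: str
    interspecific_mode: str = "all-pairs"

    def species(self, species_id: str) -> SpeciesDistanceStats:
        for s in self.per_species:
            if s.species_id == species_id:
                return s
        raise KeyError(species_id)

    def to_dataframe(self) -> pd.DataFrame:
        def fmt(t):
            if t is None:
                return (np.nan, "n.c.")
            mean, lo, hi = t
            return (_sigfig(mean), f"{_sigfig(lo):g}-{_sigfig(hi):g}")

        rows = []
        for s in self.per_species:
            wm, wr = fmt(s.within_population)
            bm, br = fmt(s.between_population)
            im, ir = fmt(s.intraspecific)
            rows.append(
                {
                    "lineage": s.species_id,
                    "N": s.n,
                    "N_H": s.n_haplotypes if s.n_haplotypes is not None else np.nan,
                    "within_population_mean": wm,
                    "within_population_range": wr,
                    "between_population_mean": bm,
                    "between_population_range": br,
                    "intraspecific_mean": im,
                    "intraspecific_range": ir,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _stats(vals: list[float]) -> tuple[float, float, float] | None:
    if not vals:
        return None
    a = np.asarray(vals, dtype=float)
    return (float(a.mean()), float(a.min()), float(a.max()))


def summarize_distances(
    dm: DistanceMatrix,
    meta: SampleMetadata,
    haplotypes: Mapping[str, int] | None = None,
    interspecific_mode: str = "all-pairs",
) -> DistanceSummary:
    """Hierarchical distance summary: within-population / between-population /
    intraspecific per species, plus global inter- and intraspecific means.

    Populations with a single sampled individual are skipped in the
    within-population pool (mirroring the exclusion of singleton populations
    from intra-population analyses).  The global intraspecific mean is the
    unweighted mean of per-species means; the interspecific mean averages all
    heterospecific pairs by default, or per species-pair means when
    ``interspecific_mode="species-pairs"``.
    """
    idx = {sid: i for i, sid in enumerate(dm.ids)}
    for sid in dm.ids:
        meta.species_of(sid)  # raises KeyError for unresolvable ids
    per_species = []
    inter_vals: list[float] = []
    inter_by_pair: dict[tuple[str, str], list[float]] = {}
    for sp in meta.species:
        inds = [i for i in meta.individuals_of_species(sp) if i in idx]
        if not inds:
            continue
        within, between, intra = [], [], []
        for a in range(len(inds)):
            for b in range(a + 1, len(inds)):
                ia, ib = idx[inds[a]], idx[inds[b]]
                d = float(dm.values[ia, ib])
                intra.append(d)
                pa = meta.population_of(inds[a])
                pb = meta.population_of(inds[b])
                if pa == pb:
                    within.append(d)
                else:
                    between.append(d)
        per_species.append(
            SpeciesDistanceStats(
                species_id=sp,
                n=len(inds),
                n_haplotypes=haplotypes.get(sp) if haplotypes else None,
                within_population=_stats(within),
                between_population=_stats(between),
                intraspecific=_stats(intra),
                computable=len(inds) >= 2,
            )
        )
    all_ids = [i for i in dm.ids]
    for a in range(len(all_ids)):
        for b in range(a + 1, len(all_ids)):
            sa, sb = meta.species_of(all_ids[a]), meta.species_of(all_ids[b])
            if sa != sb:
                d = float(dm.values[a, b])
                inter_vals.append(d)
                inter_by_pair.setdefault(tuple(sorted((sa, sb))), []).append(d)
    if interspecific_mode == "species-pairs":
        pair_means = [float(np.mean(v)) for v in inter_by_pair.values()]
        inter = _stats(pair_means)
    else:
        inter = _stats(inter_vals)
    sp_means = [s.intraspecific[0] for s in per_species if s.computable]
    intra = _stats(sp_means)
    return DistanceSummary(
        per_species=tuple(per_species),
        interspecific=inter,
        intraspecific=intra,
        scheme=dm.scheme,
        interspecific_mode=interspecific_mode,
    )


def count_haplotypes(locus: AlignedLocus, meta: SampleMetadata) -> dict[str, int]:
    """Number of distinct aligned sequences (exact string identity, gaps
    included) among conspecific individuals, per species."""
    out: dict[str, int] = {}
    present = set(locus.ids)
    for sp in meta.species:
        rows = {
            locus.row(i) for i in meta.individuals_of_species(sp) if i in present
        }
        if rows:
            out[sp] = len(rows)
    return out
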