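"""Gap-run detection and the distinct-indel inventory.

An indel is identified by its exact 5' and 3' termini in alignment
coordinates: two gap runs represent the same indel if and only if they share
both start and end columns.  Runs touching the first or last column are
terminal and, under the default policy, are treated as missing data from
incomplete amplicon coverage rather than as length mutations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .io_formats import AlignedLocus

TerminalGapPolicy = Literal["exclude", "include"]

_GAP_RUN = re.compile(r"-+")


@dataclass(frozen=True)
class GapRegion:
    """A maximal run of ``-`` in one aligned sequence (1-based, inclusive)."""

    seq_id: str
    start: int
    end: int
    terminal: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def covers(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass(frozen=True)
class Indel:
    """A distinct indel: an exact (start, end) span plus its carriers."""

    start: int
    end: int
    seq_ids: tuple[str, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


Relation = Literal["disjoint", "identical", "nested", "straddling-overlap"]


@dataclass(frozen=True)
class IndelSet:
    """Distinct indels of one locus with their pairwise structural relations."""

    indels: tuple[Indel, ...]
    alignment_length: int
    policy: TerminalGapPolicy = "exclude"
    _by_span: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_by_span", {i.span: i for i in self.indels})

    def __len__(self) -> int:
        return len(self.indels)

    def __iter__(self):
        return iter(self.indels)

    @property
    def spans(self) -> tuple[tuple[int, int], ...]:
        return tuple(i.span for i in self.indels)

    @staticmethod
    def relation(a: Indel | tuple[int, int], b: Indel | tuple[int, int]) -> Relation:
        """Structural relation of span a with respect to span b."""
        a = a.span if isinstance(a, Indel) else a
        b = b.span if isinstance(b, Indel) else b
        if a == b:
            return "identical"
        if a[1] < b[0] or b[1] < a[0]:
            return "disjoint"
        if (b[0] <= a[0] and a[1] <= b[1]) or (a[0] <= b[0] and b[1] <= a[1]):
            return "nested"
        return "straddling-overlap"

    def overlap_components(self) -> list[tuple[Indel, ...]]:
        """Connected components under {identical ∪ nested ∪ straddling-overlap}.

        Interval union-by-sweep: after sorting by start, a component breaks
        whenever the next indel starts past the running maximum end.
        """
        if not self.indels:
            return []
        order = sorted(self.indels, key=lambda i: (i.start, i.end))
        comps: list[list[Indel]] = [[order[0]]]
        reach = order[0].end
        for ind in order[1:]:
            if ind.start > reach:
                comps.append([ind])
                reach = ind.end
            else:
                comps[-1].append(ind)
                reach = max(reach, ind.end)
        return [tuple(c) for c in comps]


def find_gap_regions(locus: AlignedLocus) -> list[GapRegion]:
    """Report every maximal gap run per sequence, flagging terminal runs.

    Runs interrupted by ``N`` split naturally (N is a missing base, not a gap).
    A gap-free locus yields an empty list.
    """
    L = locus.length
    regions: list[GapRegion] = []
    for sid, row in zip(locus.ids, locus.rows):
        for m in _GAP_RUN.finditer(row):
            start, end = m.start() + 1, m.end()
            regions.append(
                GapRegion(
                    seq_id=sid,
                    start=start,
                    end=end,
                    terminal=(start == 1 or end == L),
                )
            )
    return regions


def build_indel_set(
    regions: Iterable[GapRegion],
    policy: TerminalGapPolicy = "exclude",
    alignment_length: int | None = None,
) -> IndelSet:
    """Collapse gap regions into distinct indels by exact-termini identity.

    Terminal runs are dropped under ``policy="exclude"`` (the default);
    identical (start, end) spans across sequences share one indel.
    """
    regions = list(regions)
    if alignment_length is None:
        alignment_length = max((r.end for r in regions), default=0)
    groups: dict[tuple[int, int], list[str]] = {}
    for r in regions:
        if policy == "exclude" and r.terminal:
            continue
        groups.setdefault((r.start, r.end), []).append(r.seq_id)
    indels = tuple(
        Indel(start=s, end=e, seq_ids=tuple(ids))
        for (s, e), ids in sorted(groups.items())
    )
    return IndelSet(indels=indels, alignment_length=alignment_length, policy=policy)


def gap_regions_for(locus: AlignedLocus, policy: TerminalGapPolicy = "exclude") -> IndelSet:
    """Convenience: find gap regions and build the indel inventory in one call."""
    return build_indel_set(
        find_gap_regions(locus), policy=policy, alignment_length=locus.length
    )


def export_gap_regions_bed(regions: Iterable[GapRegion], path: str | Path) -> None:
    """BED-like TSV (0-based half-open start, inclusive end) for inspection."""
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tterminal\n")
        for r in regions:
            fh.write(f"{r.seq_id}\t{r.start - 1}\t{r.end}\t{int(r.terminal)}\n")
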