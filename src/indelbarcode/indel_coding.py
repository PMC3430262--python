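"""Simple and modified complex indel coding, matrix extension and character accounting.

Four indel treatments are supported when building an analysis matrix:

* **CD** (complete deletion): every column containing a gap is removed up front.
* **PWD** (pairwise deletion): matrix untouched; gaps are excluded per pair at
  distance time.
* **SIC** (simple indel coding): each distinct-termini indel becomes one
  binary presence/absence character appended to the matrix; a sequence whose
  longer gap strictly contains a smaller indel is inapplicable for it.
* **MCIC** (modified complex indel coding): overlap-connected indels merge
  into one multistate character per component, with a symmetric minimum-event
  step matrix emitted for parsimony interchange.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ConsistencyError
from .gap_annotation import (
    GapRegion,
    Indel,
    IndelSet,
    find_gap_regions,
    gap_regions_for,
)
from .io_formats import AlignedLocus

Scheme = Literal["CD", "PWD", "SIC", "MCIC"]
SCHEMES: tuple[Scheme, ...] = ("CD", "PWD", "SIC", "MCIC")

#: Sentinel state codes used in coded characters and state matrices.
INAPPLICABLE = -1  # logically inapplicable (longer containing gap)
MISSING = -2  # missing data (terminal gap coverage, N, ambiguity, plain gap)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class CodedCharacter:
    """One coded indel character.

    ``states`` holds one small int per sequence: ``>=0`` a real state index
    into ``alphabet``, :data:`INAPPLICABLE` or :data:`MISSING` otherwise.
    For SIC the alphabet is (absent, present); for MCIC it is the no-gap
    pattern followed by the observed gap patterns (tuples of spans).
    """

    span: tuple[int, int]
    states: np.ndarray
    alphabet: tuple[tuple[tuple[int, int], ...], ...]
    member_spans: tuple[tuple[int, int], ...]
    step_matrix: np.ndarray | None = None


@dataclass(frozen=True)
class CodedBlock:
    """The coded-character part of an extended matrix under one scheme."""

    scheme: Scheme
    ids: tuple[str, ...]
    characters: tuple[CodedCharacter, ...]

    def __len__(self) -> int:
        return len(self.characters)

    def state_matrix(self) -> np.ndarray:
        """(n_seqs, n_characters) int matrix of coded states."""
        if not self.characters:
            return np.empty((len(self.ids), 0), dtype=np.int16)
        return np.column_stack([c.states for c in self.characters]).astype(np.int16)

    def export_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("character\tspan_start\tspan_end\t" + "\t".join(self.ids) + "\n")
            for i, ch in enumerate(self.characters):
                cells = []
                for st in ch.states:
                    st = int(st)
                    cells.append(
                        "-" if st == INAPPLICABLE else "?" if st == MISSING else str(st)
                    )
                fh.write(
                    f"{self.scheme}_{i + 1}\t{ch.span[0]}\t{ch.span[1]}\t"
                    + "\t".join(cells)
                    + "\n"
                )


@dataclass(frozen=True)
class ExtendedMatrix:
    """Nucleotide columns plus appended coded indel characters under a scheme.

    ``nucleotides`` is the (possibly column-reduced, for CD) nucleotide part;
    ``source_columns`` maps its columns back to the original alignment for CD.
    """

    nucleotides: AlignedLocus
    scheme: Scheme
    coded: CodedBlock | None = None
    source_columns: tuple[int, ...] | None = None

    @property
    def ids(self) -> tuple[str, ...]:
        return self.nucleotides.ids

    @property
    def n_coded(self) -> int:
        return len(self.coded.characters) if self.coded else 0

    @property
    def total_length(self) -> int:
        return self.nucleotides.length + self.n_coded

    def state_matrix(self) -> np.ndarray:
        """(n_seqs, total_length) int16 matrix; missing/inapplicable < 0.

        Nucleotide columns map A,C,G,T to 0–3; gaps, N and IUPAC ambiguity
        codes to :data:`MISSING`.  Coded characters keep their state codes.
        Each coded character is one column, so bootstrap resampling treats
        coded indels and nucleotide sites as equal units.
        """
        n = self.nucleotides.n_seqs
        nuc = np.full((n, self.nucleotides.length), MISSING, dtype=np.int16)
        for i, row in enumerate(self.nucleotides.rows):
            codes = [_BASE_CODE.get(c, MISSING) for c in row]
            nuc[i] = codes
        if self.coded and self.coded.characters:
            return np.hstack([nuc, self.coded.state_matrix()])
        return nuc


@dataclass(frozen=True)
class CharacterCounts:
    """Variable (VC) and parsimony-informative (PIC) character totals."""

    scheme: Scheme
    total_length: int
    vc: int
    pic: int

    @property
    def vc_pct(self) -> float:
        return round(100.0 * self.vc / self.total_length, 2)

    @property
    def pic_pct(self) -> float:
        return round(100.0 * self.pic / self.total_length, 2)


def _runs_by_sequence(locus: AlignedLocus) -> dict[str, list[GapRegion]]:
    runs: dict[str, list[GapRegion]] = {sid: [] for sid in locus.ids}
    for r in find_gap_regions(locus):
        runs[r.seq_id].append(r)
    return runs


def _check_indels(locus: AlignedLocus, indels: IndelSet) -> None:
    for ind in indels:
        if not (1 <= ind.start <= ind.end <= locus.length):
            raise ConsistencyError(
                f"indel {ind.span} outside alignment of length {locus.length}"
            )


def _sic_state(
    span: tuple[int, int],
    runs: list[GapRegion],
    policy: str,
) -> int:
    """SIC state of one sequence for one indel span.

    Present (1) on an exact-termini match; inapplicable on a strictly
    containing gap; missing when a terminal run (treated as no-coverage under
    policy=exclude) covers the span; absent (0) otherwise — including partial
    overlaps, which by the termini rule are different indels.
    """
    s, e = span
    for r in runs:
        if policy == "exclude" and r.terminal:
            if r.covers(s, e):
                return MISSING
            continue
        if (r.start, r.end) == span:
            return 1
        if r.covers(s, e):
            return INAPPLICABLE
    return 0


def code_sic(locus: AlignedLocus, indels: IndelSet) -> CodedBlock:
    """Simple indel coding: one presence/absence character per distinct indel."""
    _check_indels(locus, indels)
    runs = _runs_by_sequence(locus)
    chars = []
    for ind in indels:
        states = np.array(
            [_sic_state(ind.span, runs[sid], indels.policy) for sid in locus.ids],
            dtype=np.int16,
        )
        chars.append(
            CodedCharacter(
                span=ind.span,
                states=states,
                alphabet=((), (ind.span,)),
                member_spans=(ind.span,),
                step_matrix=None,
            )
        )
    return CodedBlock(scheme="SIC", ids=locus.ids, characters=tuple(chars))


def _pattern_cost(
    a: tuple[tuple[int, int], ...], b: tuple[tuple[int, int], ...]
) -> int:
    """Minimum indel events transforming gap pattern a into pattern b.

    Solved as an assignment problem over gap runs: matching identical runs is
    free, matching overlapping runs costs one boundary-shift event, matching
    disjoint runs costs a loss plus a gain (2), and unmatched runs cost one
    event each.  Symmetric by construction.
    """
    only_a = [r for r in a if r not in b]
    only_b = [r for r in b if r not in a]
    if not only_a or not only_b:
        return len(only_a) + len(only_b)
    n = len(only_a) + len(only_b)
    cost = np.ones((n, n), dtype=float)  # dummy slots cost 1 (unmatched run)
    for i, ra in enumerate(only_a):
        for j, rb in enumerate(only_b):
            if ra[1] < rb[0] or rb[1] < ra[0]:
                cost[i, j] = 2.0
            else:
                cost[i, j] = 1.0
    # dummy-vs-dummy pairings are free
    cost[len(only_a):, len(only_b):] = 0.0
    ri, ci = linear_sum_assignment(cost)
    return int(round(cost[ri, ci].sum()))


def code_mcic(locus: AlignedLocus, indels: IndelSet) -> CodedBlock:
    """Modified complex indel coding: one multistate character per
    overlap-connected component of indels, with a symmetric zero-diagonal
    minimum-event step matrix.

    A sequence's state is the exact set of component-member spans it carries;
    the no-gap pattern is always state 0.  A sequence whose terminal missing
    region covers the whole component span is inapplicable.
    """
    _check_indels(locus, indels)
    runs = _runs_by_sequence(locus)
    chars = []
    for comp in indels.overlap_components():
        member_spans = frozenset(i.span for i in comp)
        span = (min(i.start for i in comp), max(i.end for i in comp))
        patterns: list[tuple[tuple[int, int], ...]] = []
        for sid in locus.ids:
            terminal_cover = any(
                r.terminal and r.covers(*span)
                for r in runs[sid]
                if indels.policy == "exclude"
            )
            if terminal_cover:
                patterns.append(None)  # type: ignore[arg-type]
                continue
            carried = tuple(
                sorted(
                    (r.start, r.end)
                    for r in runs[sid]
                    if (r.start, r.end) in member_spans
                    and not (indels.policy == "exclude" and r.terminal)
                )
            )
            patterns.append(carried)
        observed = sorted({p for p in patterns if p is not None and p != ()})
        alphabet: tuple = ((),) + tuple(observed)
        index = {p: i for i, p in enumerate(alphabet)}
        states = np.array(
            [MISSING if p is None else index[p] for p in patterns], dtype=np.int16
        )
        k = len(alphabet)
        step = np.zeros((k, k), dtype=int)
        for i in range(k):
            for j in range(i + 1, k):
                c = _pattern_cost(alphabet[i], alphabet[j])
                step[i, j] = step[j, i] = c
        chars.append(
            CodedCharacter(
                span=span,
                states=states,
                alphabet=alphabet,
                member_spans=tuple(sorted(member_spans)),
                step_matrix=step,
            )
        )
    return CodedBlock(scheme="MCIC", ids=locus.ids, characters=tuple(chars))


def build_extended_matrix(
    locus: AlignedLocus,
    scheme: Scheme,
    indels: IndelSet | None = None,
) -> ExtendedMatrix:
    """Assemble the analysis matrix for one locus under one indel treatment.

    ``indels`` may be omitted for SIC/MCIC, in which case the inventory is
    built from the locus with the default terminal-gap policy.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if scheme == "CD":
        keep = [
            c + 1
            for c in range(locus.length)
            if all(row[c] != "-" for row in locus.rows)
        ]
        reduced = locus.subset_columns(keep)
        return ExtendedMatrix(
            nucleotides=reduced, scheme="CD", coded=None, source_columns=tuple(keep)
        )
    if scheme == "PWD":
        return ExtendedMatrix(nucleotides=locus, scheme="PWD", coded=None)
    if indels is None:
        indels = gap_regions_for(locus)
    coder = code_sic if scheme == "SIC" else code_mcic
    return ExtendedMatrix(nucleotides=locus, scheme=scheme, coded=coder(locus, indels))


def count_characters(matrix: ExtendedMatrix) -> CharacterCounts:
    """Count variable and parsimony-informative characters of a matrix.

    Nucleotide columns containing any gap are excluded from the counts in
    every scheme (their length variation is carried by the coded characters,
    never double-counted as substitution variability); within countable
    columns N and IUPAC ambiguity codes are missing.  A coded character
    counts its non-missing, applicable states.  Variable needs >=2 distinct
    states; parsimony-informative needs >=2 states each carried by >=2
    sequences.
    """
    vc = pic = 0
    ncols = zip(*matrix.nucleotides.rows)
    for col in ncols:
        if "-" in col:
            continue
        counts: dict[str, int] = {}
        for c in col:
            if c in _BASE_CODE:
                counts[c] = counts.get(c, 0) + 1
        if len(counts) >= 2:
            vc += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                pic += 1
    if matrix.coded:
        for ch in matrix.coded.characters:
            usable = ch.states[ch.states >= 0]
            vals, cnts = np.unique(usable, return_counts=True)
            if len(vals) >= 2:
                vc += 1
                if int((cnts >= 2).sum()) >= 2:
                    pic += 1
    return CharacterCounts(
        scheme=matrix.scheme, total_length=matrix.total_length, vc=vc, pic=pic
    )
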