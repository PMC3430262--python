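"""Species-discrimination scoring: monophyly + bootstrap support, and
indel-characters-only diagnosis via private diagnostic indels.

A species counts as distinguished when the bipartition isolating exactly its
individuals is present in the (unrooted) tree with nodal support strictly
greater than the threshold (default 50%). "Clade" on an unrooted tree is
operationalised as a bipartition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .indel_coding import CodedBlock
from .io_formats import SampleMetadata
from .tree_inference import SupportTree


@dataclass(frozen=True)
class SpeciesAssessment:
    species_id: str
    n: int
    monophyletic: bool | None  # None when not applicable (indel-only mode)
    support: float | None  # None = n.d. (no such split / not assessed)
    singleton: bool
    distinguished: bool
    diagnostic_spans: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class DiscriminationReport:
    """Per-species discrimination outcomes and the overall resolution %."""

    assessments: tuple[SpeciesAssessment, ...]
    threshold: float
    scheme: str
    locus: str
    mode: str = "tree"  # "tree" or "indel-only"
    notes: tuple[str, ...] = ()

    @property
    def n_species(self) -> int:
        return len(self.assessments)

    @property
    def n_distinguished(self) -> int:
        return sum(1 for a in self.assessments if a.distinguished)

    @property
    def resolution(self) -> float:
        """Percentage of species distinguished, to 1 decimal."""
        return round(100.0 * self.n_distinguished / self.n_species, 1)

    def species(self, species_id: str) -> SpeciesAssessment:
        for a in self.assessments:
            if a.species_id == species_id:
                return a
        raise KeyError(species_id)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for a in self.assessments:
            rows.append(
                {
                    "species": a.species_id,
                    "N": a.n,
                    "monophyletic": a.monophyletic,
                    "support": a.support if a.support is not None else "n.d.",
                    "singleton": a.singleton,
                    "distinguished": a.distinguished,
                    "diagnostic_spans": ";".join(
                        f"{s}-{e}" for s, e in a.diagnostic_spans
                    ),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        with open(path, "w") as fh:
            df.to_csv(fh, sep="\t", index=False)
            fh.write(
                f"# scheme={self.scheme} locus={self.locus} mode={self.mode} "
                f"threshold={self.threshold} resolution={self.resolution} "
                f"({self.n_distinguished}/{self.n_species})\n"
            )
            for note in self.notes:
                fh.write(f"# {note}\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scheme": self.scheme,
            "locus": self.locus,
            "mode": self.mode,
            "threshold": self.threshold,
            "resolution": self.resolution,
            "n_distinguished": self.n_distinguished,
            "n_species": self.n_species,
            "notes": list(self.notes),
            "species": [asdict(a) for a in self.assessments],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def assess_species(
    tree: SupportTree,
    meta: SampleMetadata,
    threshold: float = 50.0,
    scheme: str = "?",
    locus: str = "?",
) -> DiscriminationReport:
    """Score each species' monophyly and support on a bootstrapped tree.

    A species is monophyletic iff the split separating exactly its
    individuals from all others exists; distinguished iff additionally the
    split's support exceeds the threshold.  Single-individual species are
    trivially monophyletic (every tree contains the trivial split, support
    100) and flagged as singletons.
    """
    leaves = frozenset(tree.leaf_names)
    supports = tree.split_supports()
    species = [
        sp
        for sp in meta.species
        if any(i in leaves for i in meta.individuals_of_species(sp))
    ]
    if len(species) < 2:
        raise ValueError("need >=2 species on the tree to assess discrimination")
    notes = [
        "distinguished requires monophyly AND support strictly > threshold",
    ]
    out = []
    for sp in species:
        inds = frozenset(i for i in meta.individuals_of_species(sp) if i in leaves)
        if len(inds) == 1:
            out.append(
                SpeciesAssessment(
                    species_id=sp,
                    n=1,
                    monophyletic=True,
                    support=100.0,
                    singleton=True,
                    distinguished=100.0 > threshold,
                )
            )
            continue
        key = frozenset({inds, leaves - inds})
        if key in supports:
            sup = supports[key]
            out.append(
                SpeciesAssessment(
                    species_id=sp,
                    n=len(inds),
                    monophyletic=True,
                    support=sup,
                    singleton=False,
                    distinguished=sup is not None and sup > threshold,
                )
            )
        else:
            out.append(
                SpeciesAssessment(
                    species_id=sp,
                    n=len(inds),
                    monophyletic=False,
                    support=None,
                    singleton=False,
                    distinguished=False,
                )
            )
    return DiscriminationReport(
        assessments=tuple(out),
        threshold=threshold,
        scheme=scheme,
        locus=locus,
        mode="tree",
        notes=tuple(notes),
    )


def resolution_from_supports(
    supports: Sequence[float | None], threshold: float = 50.0
) -> float:
    """Resolution % from a row of per-species support values (None = n.d.),
    applying the strictly-greater-than-threshold success rule."""
    distinguished = sum(1 for s in supports if s is not None and s > threshold)
    return round(100.0 * distinguished / len(supports), 1)


def indel_only_discrimination(
    block: CodedBlock,
    meta: SampleMetadata,
    scheme: str | None = None,
    locus: str = "?",
) -> DiscriminationReport:
    """Species discrimination from coded indel characters alone.

    A species is distinguished iff some coded character has every one of its
    individuals sharing a single definite state that no other individual
    carries — a private diagnostic indel.  Diagnostic character spans are
    listed per species.
    """
    ids = block.ids
    idx = {sid: i for i, sid in enumerate(ids)}
    species = [
        sp
        for sp in meta.species
        if any(i in idx for i in meta.individuals_of_species(sp))
    ]
    out = []
    for sp in species:
        inds = [i for i in meta.individuals_of_species(sp) if i in idx]
        others = [i for i in ids if meta.species_of(i) != sp]
        diagnostics: list[tuple[int, int]] = []
        for ch in block.characters:
            sp_states = {int(ch.states[idx[i]]) for i in inds}
            if len(sp_states) != 1:
                continue
            state = next(iter(sp_states))
            if state < 0:
                continue
            if any(int(ch.states[idx[o]]) == state for o in others):
                continue
            diagnostics.append(ch.span)
        out.append(
            SpeciesAssessment(
                species_id=sp,
                n=len(inds),
                monophyletic=None,
                support=None,
                singleton=len(inds) == 1,
                distinguished=bool(diagnostics),
                diagnostic_spans=tuple(sorted(diagnostics)),
            )
        )
    return DiscriminationReport(
        assessments=tuple(out),
        threshold=0.0,
        scheme=scheme or block.scheme,
        locus=locus,
        mode="indel-only",
        notes=("distinguished = carries a private diagnostic indel character",),
    )
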