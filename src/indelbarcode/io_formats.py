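"""Input/output for the standard formats the pipeline touches.

Reads pre-aligned FASTA and delimited sample metadata; writes aligned FASTA,
NEXUS matrices with coded-indel partitions, and newick trees with bootstrap
supports as internal node labels.  All alignment coordinates in this package
are 1-based, closed intervals.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, FormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type hints only
    from .indel_coding import ExtendedMatrix
    from .tree_inference import SupportTree

#: Permitted alignment symbols: the four bases, IUPAC ambiguity codes, N and gap.
IUPAC_SYMBOLS = frozenset("ACGTURYSWKMBDHVN-")


@dataclass(frozen=True)
class AlignedLocus:
    """A rectangular aligned character matrix for one locus.

    Rows are equal-length strings over IUPAC nucleotide symbols plus ``-``.
    Column coordinates are 1-based and inclusive.
    """

    locus_name: str
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in count")
        if not self.rows:
            raise AlignmentError(f"{self.locus_name}: alignment has no sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.locus_name}: ragged alignment, row lengths {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise AlignmentError(f"{self.locus_name}: zero-length alignment")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate sequence ids: {dupes}")
        for sid, row in zip(self.ids, self.rows):
            bad = set(row) - IUPAC_SYMBOLS
            if bad:
                col = min(row.index(b) for b in bad) + 1
                raise FormatError(
                    f"{self.locus_name}: non-IUPAC symbol {sorted(bad)} in "
                    f"sequence {sid!r} at column {col}"
                )
            if set(row) == {"-"}:
                raise AlignmentError(
                    f"{self.locus_name}: sequence {sid!r} is entirely gaps"
                )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0])

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(seq_id) from None

    def subset_columns(self, columns: Sequence[int]) -> "AlignedLocus":
        """New locus keeping only the given 1-based columns, in the given order."""
        idx = [c - 1 for c in columns]
        return AlignedLocus(
            locus_name=self.locus_name,
            ids=self.ids,
            rows=tuple("".join(r[i] for i in idx) for r in self.rows),
        )

    def subset_ids(self, keep: Iterable[str]) -> "AlignedLocus":
        keep = list(keep)
        rows = tuple(self.row(i) for i in keep)
        return AlignedLocus(self.locus_name, tuple(keep), rows)


@dataclass(frozen=True)
class MetadataRecord:
    individual_id: str
    population_id: str
    species_id: str


@dataclass(frozen=True)
class SampleMetadata:
    """Individual → population → species assignment table."""

    records: tuple[MetadataRecord, ...]
    _species_of: dict = field(init=False, repr=False, compare=False)
    _population_of: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        pop_species: dict[str, str] = {}
        for rec in self.records:
            if rec.individual_id in seen:
                raise ValidationError(f"duplicate individual_id {rec.individual_id!r}")
            seen.add(rec.individual_id)
            prev = pop_species.get(rec.population_id)
            if prev is not None and prev != rec.species_id:
                raise ValidationError(
                    f"population {rec.population_id!r} mapped to two species "
                    f"({prev!r}, {rec.species_id!r})"
                )
            pop_species[rec.population_id] = rec.species_id
        object.__setattr__(
            self, "_species_of", {r.individual_id: r.species_id for r in self.records}
        )
        object.__setattr__(
            self,
            "_population_of",
            {r.individual_id: r.population_id for r in self.records},
        )

    @property
    def individuals(self) -> tuple[str, ...]:
        return tuple(r.individual_id for r in self.records)

    @property
    def species(self) -> tuple[str, ...]:
        out: list[str] = []
        for r in self.records:
            if r.species_id not in out:
                out.append(r.species_id)
        return tuple(out)

    def species_of(self, individual_id: str) -> str:
        return self._species_of[individual_id]

    def population_of(self, individual_id: str) -> str:
        return self._population_of[individual_id]

    def individuals_of_species(self, species_id: str) -> tuple[str, ...]:
        return tuple(
            r.individual_id for r in self.records if r.species_id == species_id
        )

    def populations_of_species(self, species_id: str) -> tuple[str, ...]:
        out: list[str] = []
        for r in self.records:
            if r.species_id == species_id and r.population_id not in out:
                out.append(r.population_id)
        return tuple(out)

    def individuals_in_population(self, population_id: str) -> tuple[str, ...]:
        return tuple(
            r.individual_id for r in self.records if r.population_id == population_id
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual": [r.individual_id for r in self.records],
                "population": [r.population_id for r in self.records],
                "species": [r.species_id for r in self.records],
            }
        )


def read_alignment(path: str | Path, format: str = "aligned-fasta") -> AlignedLocus:
    """Parse a pre-aligned multi-FASTA into an :class:`AlignedLocus`.

    Bases are uppercased; ``.`` and ``~`` gap spellings are normalised to
    ``-``. Input order is preserved.
    """
    if format != "aligned-fasta":
        raise ValueError(f"unsupported alignment format {format!r}")
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    ids = tuple(r.id for r in records)
    rows = tuple(
        str(r.seq).upper().replace(".", "-").replace("~", "-") for r in records
    )
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentError(
            f"{path}: sequences have differing lengths {sorted(lengths)}; "
            "input must be a pre-computed alignment"
        )
    return AlignedLocus(locus_name=path.stem, ids=ids, rows=rows)


def write_alignment(locus: AlignedLocus, path: str | Path) -> None:
    """Write an aligned locus back to FASTA (one line per sequence)."""
    with open(path, "w") as fh:
        for sid, row in zip(locus.ids, locus.rows):
            fh.write(f">{sid}\n{row}\n")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a TSV/CSV metadata table with columns individual, population, species.

    The delimiter is sniffed from the header line (tab beats comma).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty metadata file")
    header = text.splitlines()[0]
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    required = {"individual", "population", "species"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    recs = tuple(
        MetadataRecord(str(r.individual), str(r.population), str(r.species))
        for r in df.itertuples(index=False)
    )
    return SampleMetadata(records=recs)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.to_dataframe().to_csv(path, sep="\t", index=False)


_NEXUS_SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUV"


def _nexus_safe(label: str) -> str:
    if re.fullmatch(r"[\w.\-]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_nexus(matrix: "ExtendedMatrix", path: str | Path) -> None:
    """Write an extended matrix as NEXUS with a mixed DNA/standard partition.

    Coded indel characters occupy the final columns; CHARSETs label the two
    partitions and, for MCIC, each multistate character's symmetric step
    matrix is emitted as a USERTYPE in an ASSUMPTIONS block so parsimony
    programs can honour the event costs.
    """
    from .indel_coding import INAPPLICABLE, MISSING  # local import avoids cycle

    nloc = matrix.nucleotides
    n_nuc = nloc.length
    n_coded = len(matrix.coded.characters) if matrix.coded else 0
    total = n_nuc + n_coded
    lines = ["#NEXUS", ""]
    lines.append("BEGIN DATA;")
    lines.append(f"    DIMENSIONS NTAX={nloc.n_seqs} NCHAR={total};")
    if n_coded:
        fmt = (
            f"    FORMAT DATATYPE=MIXED(DNA:1-{n_nuc},STANDARD:{n_nuc + 1}-{total}) "
            f'MISSING=? GAP=- SYMBOLS="{_NEXUS_SYMBOLS[:10]}";'
        )
    else:
        fmt = "    FORMAT DATATYPE=DNA MISSING=? GAP=-;"
    lines.append(fmt)
    lines.append("    MATRIX")
    width = max(len(_nexus_safe(i)) for i in nloc.ids) + 2
    for si, (sid, row) in enumerate(zip(nloc.ids, nloc.rows)):
        coded_part = ""
        if matrix.coded:
            cells = []
            for ch in matrix.coded.characters:
                st = int(ch.states[si])
                if st == INAPPLICABLE:
                    cells.append("-")
                elif st == MISSING:
                    cells.append("?")
                else:
                    cells.append(_NEXUS_SYMBOLS[st])
            coded_part = "".join(cells)
        lines.append(f"    {_nexus_safe(sid):<{width}}{row}{coded_part}")
    lines.append("    ;")
    lines.append("END;")
    lines.append("")
    lines.append("BEGIN SETS;")
    lines.append(f"    CHARSET nucleotides = 1-{n_nuc};")
    if n_coded:
        lines.append(f"    CHARSET indels = {n_nuc + 1}-{total};")
    lines.append("END;")
    if matrix.coded and matrix.scheme == "MCIC":
        lines.append("")
        lines.append("BEGIN ASSUMPTIONS;")
        for ci, ch in enumerate(matrix.coded.characters):
            if ch.step_matrix is None:
                continue
            k = ch.step_matrix.shape[0]
            sym = " ".join(_NEXUS_SYMBOLS[:k])
            lines.append(f"    USERTYPE indel_char_{n_nuc + ci + 1} (STEPMATRIX) = {k}")
            lines.append(f"        {sym}")
            for a in range(k):
                cells = [
                    "." if a == b else str(int(ch.step_matrix[a, b])) for b in range(k)
                ]
                lines.append("        " + " ".join(cells))
            lines.append("    ;")
        lines.append("END;")
    lines.append("")
    try:
        Path(path).write_text("\n".join(lines))
    except OSError as exc:
        raise IOError(f"cannot write NEXUS to {path}: {exc}") from exc


def write_tree(tree: "SupportTree", path: str | Path) -> None:
    """Write a support tree as newick, supports as internal node labels."""
    try:
        Path(path).write_text(tree.to_newick() + "\n")
    except OSError as exc:
        raise IOError(f"cannot write tree to {path}: {exc}") from exc


def read_tree(path: str | Path) -> "SupportTree":
    """Parse a newick file (internal labels read as bootstrap supports)."""
    import dendropy

    from .tree_inference import Node, SupportTree

    dtree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            return Node(
                name=dnode.taxon.label if dnode.taxon else dnode.label,
                length=dnode.edge.length,
            )
        support = None
        if dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                support = None
        return Node(
            name=None,
            length=dnode.edge.length,
            support=support,
            children=[convert(c) for c in dnode.child_nodes()],
        )

    root = convert(dtree.seed_node)
    return SupportTree(root=root)
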