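"""Synthetic aligned datasets with planted indel structure and a truth record.

The generator emulates a hierarchical barcoding study of closely related
taxa: several species, each sampled as 3–8 populations with 2–3 individuals
per population; low substitution divergence (intraspecific p-distances near
zero, interspecific a few parts per thousand); species-diagnostic indels
planted on species stems; optional nuisance indels on random clades
(producing shared/nested/overlapping gaps) and homoplasious mononucleotide
repeat slippage on terminal branches.  Indels are simulated directly in
alignment coordinates (gap columns), so the emitted matrix is a valid
alignment with exact homology by construction — no realignment step exists
or is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .io_formats import AlignedLocus, MetadataRecord, SampleMetadata

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one simulated dataset.

    Defaults mirror the sampling design being emulated: nine species, three
    to eight populations per species, two to three individuals per
    population, two noncoding chloroplast-spacer-like loci, interspecific
    divergence of a few per mille and near-zero intraspecific divergence,
    one species-diagnostic indel per species per locus.
    """

    n_species: int = 9
    pops_per_species: tuple[int, int] = (3, 8)
    inds_per_pop: tuple[int, int] = (2, 3)
    locus_lengths: dict = field(
        default_factory=lambda: {"spacer_A": 820, "spacer_B": 950}
    )
    species_tree_newick: str | None = None
    stem_sub_prob: float = 0.0012  # per-site, per species-tree branch
    pop_sub_prob: float = 0.00025  # per-site, species tip -> population
    tip_sub_prob: float = 0.00015  # per-site, population -> individual
    diagnostic_indels_per_species: int = 1
    diagnostic_indel_length: tuple[int, int] = (1, 60)
    nuisance_indels_per_locus: int = 0
    nuisance_indel_length: tuple[int, int] = (1, 12)
    slippage_sites_per_locus: int = 0
    slippage_rate: float = 0.02  # per terminal branch, per slippage site
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ConfigError("n_species must be positive")
        for lo, hi, name in (
            (*self.pops_per_species, "pops_per_species"),
            (*self.inds_per_pop, "inds_per_pop"),
            (*self.diagnostic_indel_length, "diagnostic_indel_length"),
            (*self.nuisance_indel_length, "nuisance_indel_length"),
        ):
            if lo < 1 or hi < lo:
                raise ConfigError(f"invalid range for {name}: ({lo}, {hi})")
        for p, name in (
            (self.stem_sub_prob, "stem_sub_prob"),
            (self.pop_sub_prob, "pop_sub_prob"),
            (self.tip_sub_prob, "tip_sub_prob"),
            (self.slippage_rate, "slippage_rate"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {p}")
        for locus, L in self.locus_lengths.items():
            if self.diagnostic_indel_length[1] >= L:
                raise ConfigError(
                    f"diagnostic indel length {self.diagnostic_indel_length[1]} "
                    f"does not fit inside locus {locus!r} of length {L}"
                )


@dataclass(frozen=True)
class IndelEvent:
    locus: str
    branch: str  # species id, clade label, or individual id
    start: int  # 1-based, inclusive
    end: int
    kind: str  # "diagnostic" | "nuisance" | "slippage"


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth of one simulated dataset, for recovery tests."""

    assignments: tuple[MetadataRecord, ...]
    events: tuple[IndelEvent, ...]
    expected_diagnostics: dict  # locus -> species -> list of (start, end)
    species_tree_newick: str

    def diagnostic_spans(self, locus: str, species: str) -> tuple[tuple[int, int], ...]:
        return tuple(
            (s, e) for s, e in self.expected_diagnostics.get(locus, {}).get(species, ())
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "assignments": [asdict(r) for r in self.assignments],
            "events": [asdict(e) for e in self.events],
            "expected_diagnostics": {
                loc: {sp: [list(s) for s in spans] for sp, spans in d.items()}
                for loc, d in self.expected_diagnostics.items()
            },
            "species_tree_newick": self.species_tree_newick,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


class _TreeNode:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []

    def newick(self) -> str:
        if not self.children:
            return self.label
        return "(" + ",".join(c.newick() for c in self.children) + ")"

    def leaf_labels(self) -> list[str]:
        if not self.children:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaf_labels())
        return out


def _random_species_tree(species: list[str], rng: np.random.Generator) -> _TreeNode:
    """Random bifurcating topology by sequential random joins."""
    nodes = [_TreeNode(label=sp) for sp in species]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = _TreeNode(children=[nodes[i], nodes[j]])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0]


def _parse_newick(text: str) -> _TreeNode:
    """Minimal newick topology parser (labels only; lengths ignored)."""
    pos = 0
    text = text.strip().rstrip(";")

    def parse() -> _TreeNode:
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            children = [parse()]
            while text[pos] == ",":
                pos += 1
                children.append(parse())
            assert text[pos] == ")"
            pos += 1
            # swallow internal label / branch length
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            return _TreeNode(children=children)
        start = pos
        while pos < len(text) and text[pos] not in ",():":
            pos += 1
        label = text[start:pos]
        while pos < len(text) and text[pos] not in ",()":
            pos += 1
        return _TreeNode(label=label)

    return parse()


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    if p <= 0:
        return out
    mask = rng.random(seq.size) < p
    k = int(mask.sum())
    if k:
        out[mask] = (out[mask] + rng.integers(1, 4, size=k)) % 4
    return out


def _place_spans(
    n: int,
    lengths: np.ndarray,
    L: int,
    rng: np.random.Generator,
    margin: int = 2,
) -> list[tuple[int, int]]:
    """Place n non-overlapping spans with >=1 spacer column between them and
    a margin away from the alignment ends (keeps every event internal and
    every pair of termini distinct, with no run merging)."""
    total = int(lengths.sum()) + (n + 1) + 2 * margin
    if total > L:
        raise ConfigError(
            f"cannot place {n} indel events of total length {int(lengths.sum())} "
            f"in a locus of length {L}"
        )
    slack = L - total
    extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    spans = []
    cursor = margin
    for i in range(n):
        cursor += 1 + int(extra[i])  # spacer + slack
        start = cursor + 1  # 1-based
        end = start + int(lengths[i]) - 1
        spans.append((start, end))
        cursor = end
    return spans


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[dict[str, AlignedLocus], SampleMetadata, TruthRecord]:
    """Simulate aligned loci, metadata and ground truth under the config.

    Sequences evolve down the species tree (per-branch Bernoulli
    substitutions, uniform among the three alternative bases), then through
    population and individual branches.  Diagnostic indels gap all
    individuals of one species over a planted span; nuisance indels gap a
    random species-tree clade; slippage removes one repeat unit at a
    mononucleotide site independently per terminal branch.  Deterministic
    per seed.
    """
    rng = np.random.default_rng(config.seed)
    species = [f"sp{k + 1:02d}" for k in range(config.n_species)]

    records: list[MetadataRecord] = []
    for sp in species:
        n_pops = int(rng.integers(config.pops_per_species[0], config.pops_per_species[1] + 1))
        for p in range(n_pops):
            pop = f"{sp}_p{p + 1}"
            n_inds = int(rng.integers(config.inds_per_pop[0], config.inds_per_pop[1] + 1))
            for i in range(n_inds):
                records.append(MetadataRecord(f"{pop}_i{i + 1}", pop, sp))
    meta = SampleMetadata(records=tuple(records))

    if config.species_tree_newick:
        tree = _parse_newick(config.species_tree_newick)
        if sorted(tree.leaf_labels()) != sorted(species):
            raise ConfigError(
                "species_tree_newick leaves must be exactly the simulated species"
            )
    else:
        tree = _random_species_tree(species, rng)

    loci: dict[str, AlignedLocus] = {}
    events: list[IndelEvent] = []
    expected: dict[str, dict[str, list[tuple[int, int]]]] = {}

    for locus_name, L in config.locus_lengths.items():
        anc = rng.integers(0, 4, size=L)

        # species-diagnostic indels: non-overlapping spans on species stems
        n_diag = config.diagnostic_indels_per_species * len(species)
        diag_spans: list[tuple[int, int]] = []
        if n_diag:
            lengths = rng.integers(
                config.diagnostic_indel_length[0],
                config.diagnostic_indel_length[1] + 1,
                size=n_diag,
            )
            diag_spans = _place_spans(n_diag, lengths, L, rng)

        # mononucleotide repeat sites: a 5-base run whose last column can slip.
        # Kept clear of diagnostic spans (plus one flanking column) so slippage
        # gaps never merge with a planted diagnostic gap run.
        slip_cols: list[int] = []
        if config.slippage_sites_per_locus:
            blocked = np.zeros(L + 2, dtype=bool)
            for s, e in diag_spans:
                blocked[max(0, s - 2) : min(L, e + 1) + 1] = True
            candidates = [
                s
                for s in range(6, L - 6)
                if not blocked[s - 1 : s + 6].any()  # run plus one flank, 0-based
            ]
            starts = rng.choice(
                np.asarray(candidates),
                size=config.slippage_sites_per_locus,
                replace=False,
            )
            for s in np.sort(starts):
                anc[s : s + 5] = anc[s]
                slip_cols.append(int(s) + 5)  # 1-based last column of the run
        expected[locus_name] = {sp: [] for sp in species}
        span_iter = iter(diag_spans)
        for sp in species:
            for _ in range(config.diagnostic_indels_per_species):
                span = next(span_iter)
                expected[locus_name][sp].append(span)
                events.append(
                    IndelEvent(locus_name, sp, span[0], span[1], "diagnostic")
                )

        # evolve substitutions down the species tree
        species_seq: dict[str, np.ndarray] = {}

        def evolve(node: _TreeNode, seq: np.ndarray) -> None:
            derived = _mutate(seq, config.stem_sub_prob, rng)
            if not node.children:
                species_seq[node.label] = derived
                return
            for child in node.children:
                evolve(child, derived)

        evolve(tree, anc)

        ind_seq: dict[str, np.ndarray] = {}
        for sp in species:
            for pop in meta.populations_of_species(sp):
                pop_seq = _mutate(species_seq[sp], config.pop_sub_prob, rng)
                for ind in meta.individuals_in_population(pop):
                    ind_seq[ind] = _mutate(pop_seq, config.tip_sub_prob, rng)

        gap = {ind: np.zeros(L, dtype=bool) for ind in meta.individuals}
        for sp in species:
            for span in expected[locus_name][sp]:
                for ind in meta.individuals_of_species(sp):
                    gap[ind][span[0] - 1 : span[1]] = True

        # nuisance indels on random species-tree clades
        if config.nuisance_indels_per_locus:
            internal: list[_TreeNode] = []

            def collect(node: _TreeNode) -> None:
                internal.append(node)
                for c in node.children:
                    collect(c)

            collect(tree)
            for _ in range(config.nuisance_indels_per_locus):
                node = internal[int(rng.integers(0, len(internal)))]
                length = int(
                    rng.integers(
                        config.nuisance_indel_length[0],
                        config.nuisance_indel_length[1] + 1,
                    )
                )
                start = int(rng.integers(2, L - length))  # internal placement
                end = start + length - 1
                carriers = node.leaf_labels()
                for sp in carriers:
                    for ind in meta.individuals_of_species(sp):
                        gap[ind][start - 1 : end] = True
                events.append(
                    IndelEvent(
                        locus_name, "clade:" + "+".join(carriers), start, end, "nuisance"
                    )
                )

        # mononucleotide slippage: one-unit contraction per terminal branch
        for col in slip_cols:
            for ind in meta.individuals:
                if rng.random() < config.slippage_rate:
                    gap[ind][col - 1] = True
                    events.append(IndelEvent(locus_name, ind, col, col, "slippage"))

        rows = []
        for ind in meta.individuals:
            chars = _BASES[ind_seq[ind]]
            chars = np.where(gap[ind], "-", chars)
            rows.append("".join(chars))
        loci[locus_name] = AlignedLocus(
            locus_name=locus_name, ids=meta.individuals, rows=tuple(rows)
        )

    truth = TruthRecord(
        assignments=meta.records,
        events=tuple(events),
        expected_diagnostics={
            loc: {sp: [tuple(s) for s in spans] for sp, spans in d.items()}
            for loc, d in expected.items()
        },
        species_tree_newick=tree.newick() + ";",
    )
    return loci, meta, truth


def alignment_with_indels(
    length: int,
    n_indels: int,
    n_seqs: int = 8,
    max_indel_length: int = 20,
    seed: int | None = 0,
) -> AlignedLocus:
    """A random alignment of the given length containing exactly ``n_indels``
    internal gap events with pairwise-distinct termini.

    Events are non-overlapping with a spacer column between them, each
    carried by a proper subset of sequences, so the distinct-indel inventory
    of the result has exactly ``n_indels`` entries.
    """
    rng = np.random.default_rng(seed)
    lengths = rng.integers(1, max_indel_length + 1, size=n_indels)
    spans = _place_spans(n_indels, lengths, length, rng)
    base = rng.integers(0, 4, size=length)
    rows = [np.array(_BASES[base]) for _ in range(n_seqs)]
    for span in spans:
        k = int(rng.integers(1, n_seqs))  # proper subset of carriers
        carriers = rng.choice(n_seqs, size=k, replace=False)
        for c in carriers:
            rows[c][span[0] - 1 : span[1]] = "-"
    return AlignedLocus(
        locus_name=f"synthetic_{length}_{n_indels}",
        ids=tuple(f"s{i + 1}" for i in range(n_seqs)),
        rows=tuple("".join(r) for r in rows),
    )
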