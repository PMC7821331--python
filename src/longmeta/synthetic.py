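"""Seeded synthetic world: taxonomy, marker references, community templates.

This module fabricates the statistical structure the long-metabarcoding
method assumes: a ranked taxonomy spanning plants, invertebrates and
vertebrates; per-marker reference sequences whose divergence is calibrated
so that conspecific matches sit near 100% identity while congeners fall in
the ~90–98% band (which is what makes a 97.6% identity gate discriminative);
and community template pools for mock communities (pool-then-amplify MC1 vs
amplify-then-pool MC2), feeding trials and field-style samples.

Everything is driven by explicit integer seeds and is byte-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pcr import Primer, PrimerPair, Template, revcomp
from .taxonomy import Rank, TaxonNode, TaxonomyTree

GROUPS = ("plant", "invertebrate", "vertebrate")

BASES = np.array(list("ACGT"))

# One clade scaffold per target group: (kingdom, phylum, classes).
_GROUP_CLADES = {
    "plant": ("Viridiplantae", "Streptophyta", ("Magnoliopsida", "Liliopsida")),
    "invertebrate": ("Metazoa", "Arthropoda", ("Insecta", "Malacostraca")),
    "vertebrate": ("Metazoa", "Chordata", ("Actinopterygii", "Mammalia")),
}

_SYLLABLES = [
    "ba", "ce", "da", "fe", "ga", "hi", "ko", "lu", "ma", "ne",
    "or", "pa", "qui", "ra", "sa", "ti", "ul", "ve", "xa", "zo",
]


def _latinish(rng: np.random.Generator, n_syl: int) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(n_syl))


# ---------------------------------------------------------------------------
# Taxonomy simulation

@dataclass(frozen=True)
class TaxonomyShape:
    """Branching controls for the simulated tree."""

    max_species_per_genus: int = 3
    genera_per_family: int = 2
    families_per_order: int = 2
    group_weights: tuple[float, float, float] = (0.4, 0.4, 0.2)  # plant/invert/vert


def _allocate_groups(n_species: int, weights: Sequence[float]) -> dict[str, int]:
    """Split species across groups; every group represented when n >= 3."""
    counts = {g: 0 for g in GROUPS}
    order = [g for _, g in sorted(zip(weights, GROUPS), key=lambda t: -t[0])]
    # seed each group once (largest-weight first), then fill proportionally
    for g in order[: min(n_species, 3)]:
        counts[g] += 1
    remaining = n_species - sum(counts.values())
    if remaining > 0:
        w = np.asarray(weights, dtype=float)
        extra = np.floor(remaining * w / w.sum()).astype(int)
        for g, e in zip(GROUPS, extra):
            counts[g] += int(e)
        i = 0
        while sum(counts.values()) < n_species:
            counts[order[i % len(order)]] += 1
            i += 1
    return counts


def simulate_taxonomy(
    n_species: int,
    seed: int = 0,
    shape: TaxonomyShape = TaxonomyShape(),
    named_species: Sequence[tuple[str, str]] | None = None,
) -> TaxonomyTree:
    """Simulate a ranked tree with ``n_species`` species leaves.

    ``named_species`` optionally fixes the species names and their target
    groups as ``(binomial_name, group)`` pairs (``n_species`` is then
    ignored); species sharing the same genus epithet are placed in the same
    genus.  Without it, pseudo-Latin binomials are generated and species are
    spread across plant, invertebrate and vertebrate clades.
    """
    if named_species is not None:
        n_species = len(named_species)
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)

    nodes: list[TaxonNode] = [
        TaxonNode("t0001", "root", Rank.ROOT, None),
        TaxonNode("t0002", "Eukaryota", Rank.SUPERKINGDOM, "t0001"),
    ]
    next_id = [3]

    def new_node(name: str, rank: Rank, parent: str) -> str:
        tid = f"t{next_id[0]:04d}"
        next_id[0] += 1
        nodes.append(TaxonNode(tid, name, rank, parent))
        return tid

    kingdoms: dict[str, str] = {}
    group_phyla: dict[str, str] = {}
    group_classes: dict[str, list[str]] = {}

    if named_species is not None:
        plan: dict[str, list[list[str]]] = {g: [] for g in GROUPS}  # genus -> species names
        for g in GROUPS:
            genera: dict[str, list[str]] = {}
            for name, grp in named_species:
                if grp == g:
                    genera.setdefault(name.split()[0], []).append(name)
            plan[g] = list(genera.values())
    else:
        counts = _allocate_groups(n_species, shape.group_weights)
        plan = {g: [] for g in GROUPS}
        used_names: set[str] = set()
        for g in GROUPS:
            remaining = counts[g]
            while remaining > 0:
                size = int(rng.integers(1, shape.max_species_per_genus + 1))
                size = min(size, remaining)
                while True:
                    genus_name = _latinish(rng, 3).capitalize()
                    if genus_name not in used_names:
                        used_names.add(genus_name)
                        break
                species_names = []
                for _ in range(size):
                    while True:
                        sp = f"{genus_name} {_latinish(rng, 3)}"
                        if sp not in used_names:
                            used_names.add(sp)
                            break
                    species_names.append(sp)
                plan[g].append(species_names)
                remaining -= size

    for g in GROUPS:
        genera = plan[g]
        if not genera:
            continue
        kingdom, phylum, classes = _GROUP_CLADES[g]
        if kingdom not in kingdoms:
            kingdoms[kingdom] = new_node(kingdom, Rank.KINGDOM, "t0002")
        group_phyla[g] = new_node(phylum, Rank.PHYLUM, kingdoms[kingdom])
        group_classes[g] = []
        n_classes = 1 if len(genera) < 3 else min(len(classes), 2)
        for c in classes[:n_classes]:
            group_classes[g].append(new_node(c, Rank.CLASS, group_phyla[g]))
        # walk genera into a fresh order/family scaffold
        order_id = family_id = None
        for gi, species_names in enumerate(genera):
            class_id = group_classes[g][gi % len(group_classes[g])]
            if gi % (shape.genera_per_family * shape.families_per_order) == 0:
                order_id = new_node(f"{_latinish(rng, 2).capitalize()}iformes",
                                    Rank.ORDER, class_id)
            if gi % shape.genera_per_family == 0:
                family_id = new_node(f"{_latinish(rng, 2).capitalize()}idae",
                                     Rank.FAMILY, order_id)
            genus_name = species_names[0].split()[0]
            genus_id = new_node(genus_name, Rank.GENUS, family_id)
            for sp in species_names:
                new_node(sp, Rank.SPECIES, genus_id)

    return TaxonomyTree.from_nodes(nodes)


def species_group(tree: TaxonomyTree, taxon_id: str) -> str:
    """Target group of a taxon, derived from its lineage."""
    names = {n.name for n in tree.lineage(taxon_id)}
    if "Viridiplantae" in names:
        return "plant"
    if "Chordata" in names:
        return "vertebrate"
    return "invertebrate"


# ---------------------------------------------------------------------------
# Marker reference evolution

@dataclass(frozen=True)
class MarkerSpec:
    marker_name: str
    target_group: str
    amplicon_length_bp: int
    per_site_divergence: float
    primer_pair: PrimerPair

    def __post_init__(self) -> None:
        if not 350 <= self.amplicon_length_bp <= 1400:
            raise ValueError(
                f"{self.marker_name}: amplicon length {self.amplicon_length_bp} "
                "outside [350, 1400]"
            )
        if not 0 < self.per_site_divergence < 0.3:
            raise ValueError(f"{self.marker_name}: per_site_divergence out of range")


@dataclass(frozen=True)
class ReferenceRecord:
    accession: str
    taxon_id: str
    marker_name: str
    sequence: str


def default_markers(panel: Sequence[PrimerPair]) -> list[MarkerSpec]:
    """One marker per primer pair; amplicon length = the pair's expected size."""
    return [
        MarkerSpec(
            marker_name=p.marker_name,
            target_group=p.target_group,
            amplicon_length_bp=max(350, p.expected_length_bp),
            per_site_divergence=0.05,
            primer_pair=p,
        )
        for p in sorted(panel, key=lambda p: p.marker_name)
    ]


def realize_primer(primer: Primer, rng: np.random.Generator) -> str:
    """Concrete A/C/G/T realization of a degenerate primer."""
    from .pcr import IUPAC

    return "".join(sorted(IUPAC[c])[int(rng.integers(len(IUPAC[c])))] for c in primer.sequence)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only mutation at per-site probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        idx = np.flatnonzero(hit)
        for i in idx:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


# substitution probability applied along each edge entering a node of the
# given rank; species edges draw from SPECIES_RATE_RANGE instead, which
# pins congeneric divergence to roughly 2.4-8.8% of sites.
_EDGE_RATES = {
    Rank.KINGDOM: 0.12,
    Rank.PHYLUM: 0.10,
    Rank.CLASS: 0.08,
    Rank.ORDER: 0.06,
    Rank.FAMILY: 0.05,
    Rank.GENUS: 0.04,
}
SPECIES_RATE_RANGE = (0.012, 0.045)


def evolve_references(
    tree: TaxonomyTree,
    markers: Sequence[MarkerSpec],
    seed: int = 0,
    flank_pad_bp: int = 30,
) -> list[ReferenceRecord]:
    """One reference per (species, applicable marker).

    Each marker's amplicon is a realized forward-primer site, an evolved
    marker core and the reverse-complemented reverse-primer site; the core
    evolves by substitution down the taxonomy so shared ancestry translates
    into sequence similarity.  Primer flanks are conserved (identical across
    species), so every reference is amplifiable by its own pair.  References
    carry ``flank_pad_bp`` of random padding on both sides, standing in for
    the genomic context of a database entry.

    Markers whose target group has no species in the tree are skipped with
    a warning.
    """
    import warnings

    records: list[ReferenceRecord] = []
    groups = {sp.taxon_id: species_group(tree, sp.taxon_id) for sp in tree.species()}
    acc = 0
    for marker in sorted(markers, key=lambda m: m.marker_name):
        marker_tag = zlib.crc32(marker.marker_name.encode()) % (2**31)
        rng = np.random.default_rng([seed, marker_tag])
        wanted = [tid for tid, g in sorted(groups.items()) if g == marker.target_group]
        if not wanted:
            warnings.warn(
                f"marker {marker.marker_name}: no {marker.target_group} species "
                "in tree; skipped"
            )
            continue
        fwd = realize_primer(marker.primer_pair.forward, rng)
        rev_rc = revcomp(realize_primer(marker.primer_pair.reverse, rng))
        core_len = marker.amplicon_length_bp - len(fwd) - len(rev_rc)
        root_core = random_dna(rng, core_len)
        # evolve cores down the tree, memoized per internal node
        cores: dict[str, str] = {tree.root.taxon_id: root_core}

        def core_for(tid: str) -> str:
            if tid in cores:
                return cores[tid]
            node = tree.node(tid)
            parent_core = core_for(node.parent_id)  # root always memoized
            if node.rank is Rank.SPECIES:
                rate = float(rng.uniform(*SPECIES_RATE_RANGE))
            else:
                rate = _EDGE_RATES.get(node.rank, 0.0)
            cores[tid] = mutate(parent_core, rate, rng)
            return cores[tid]

        for tid in wanted:
            amplicon = fwd + core_for(tid) + rev_rc
            padded = (
                random_dna(rng, flank_pad_bp) + amplicon + random_dna(rng, flank_pad_bp)
            )
            acc += 1
            records.append(
                ReferenceRecord(
                    accession=f"ref{acc:05d}",
                    taxon_id=tid,
                    marker_name=marker.marker_name,
                    sequence=padded,
                )
            )
    return records


def write_references_fasta(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f">{r.accession}|{r.taxon_id}|{r.marker_name}\n{r.sequence}\n")


def load_references_fasta(path: str | Path) -> list[ReferenceRecord]:
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, taxon_id, marker = rec.id.split("|")
        records.append(ReferenceRecord(accession, taxon_id, marker, str(rec.seq).upper()))
    return records


# ---------------------------------------------------------------------------
# Community composition

MODES = ("MC1_pool_then_amplify", "MC2_amplify_then_pool", "feeding_trial", "field_sample")


@dataclass(frozen=True)
class CommunitySpec:
    """A sample's ground truth: members, weights and amplification mode."""

    members: tuple[tuple[str, float], ...]  # (taxon_id, template weight)
    mode: str = "MC1_pool_then_amplify"
    host_taxon: str | None = None
    host_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown community mode {self.mode!r}")
        total = sum(w for _, w in self.members) + self.host_weight
        if total <= 0:
            raise ValueError("community weights must sum > 0")
        if self.host_weight > 0 and self.host_weight / total > 0.2:
            raise ValueError("host_weight must be <= 20% of total template weight")


@dataclass
class CommunitySample:
    spec: CommunitySpec
    truth: pd.DataFrame  # columns: taxon_id, name, weight, group, is_host
    templates: list[Template]


def compose_community(
    spec: CommunitySpec,
    tree: TaxonomyTree,
    refs: Sequence[ReferenceRecord],
    seed: int = 0,
    copies_per_unit: int = 50,
    conspecific_divergence: float = 0.003,
) -> CommunitySample:
    """Emit the truth table and the template pool for one sample.

    Templates are the references of each member mutated at the conspecific
    rate (faecal/specimen DNA is never byte-identical to the database
    entry).  Copy numbers are ``round(weight * copies_per_unit)`` for
    pooled-DNA modes; in MC2 mode every member contributes ``copies_per_unit``
    copies regardless of weight (each member is amplified separately and the
    products pooled equimolar downstream).
    """
    rng = np.random.default_rng([seed, 17])
    by_taxon: dict[str, list[ReferenceRecord]] = {}
    for r in refs:
        by_taxon.setdefault(r.taxon_id, []).append(r)

    entries = [(tid, w, False) for tid, w in spec.members]
    if spec.host_taxon is not None and spec.host_weight > 0:
        entries.append((spec.host_taxon, spec.host_weight, True))

    missing = [tid for tid, _, _ in entries if tid not in by_taxon]
    if missing:
        names = ", ".join(f"{t} ({tree.node(t).name})" for t in missing)
        raise ValueError(f"community members without any marker reference: {names}")

    rows = []
    templates: list[Template] = []
    equalize = spec.mode == "MC2_amplify_then_pool"
    for tid, weight, is_host in entries:
        copies = copies_per_unit if equalize else int(round(weight * copies_per_unit))
        rows.append(
            {
                "taxon_id": tid,
                "name": tree.node(tid).name,
                "weight": weight,
                "group": species_group(tree, tid),
                "is_host": is_host,
            }
        )
        if copies <= 0:
            continue
        for ref in sorted(by_taxon[tid], key=lambda r: r.accession):
            seq = mutate(ref.sequence, conspecific_divergence, rng)
            templates.append(Template(member_taxon=tid, sequence=seq, copies=copies))

    truth = pd.DataFrame(rows, columns=["taxon_id", "name", "weight", "group", "is_host"])
    return CommunitySample(spec=spec, truth=truth, templates=templates)


def write_truth_tsv(sample: CommunitySample, path: str | Path) -> None:
    sample.truth.to_csv(path, sep="\t", index=False)
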