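"""End-to-end orchestration, summary statistics and truth validation.

A sample run chains every stage: community composition, in-silico PCR over
the 11-pair panel, shearing and paired-end read simulation, de novo
assembly with the 150 bp contig filter, top-5/97.6%/LCA assignment and
read-back quantification.  Cohort-level reports reproduce the method's
bookkeeping: species-rank assignment rate over OTUs, per-phylum contig
lengths, host detection rate and host-read fractions, and mock-community /
feeding-trial validation against the truth table.
"""

from __future__ import annotations

import importlib.resources
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import assembly, pcr, quantify, sequencing, synthetic
from .assign import (
    Assignment,
    AssignmentParams,
    RegionalChecklist,
    apply_checklist,
    assign_contig,
    search,
    write_assignments_tsv,
)
from .synthetic import CommunitySample, CommunitySpec, ReferenceRecord, species_group
from .taxonomy import Rank, TaxonomyTree

# ---------------------------------------------------------------------------
# Study rosters (printed community compositions and dietary regimes)

#: 19-member mock community: (species name, target group).
MC1_MEMBERS: tuple[tuple[str, str], ...] = (
    ("Aeshna cyanea", "invertebrate"),
    ("Baetis rhodani", "invertebrate"),
    ("Bufotes viridis", "vertebrate"),
    ("Caenis caenis", "invertebrate"),
    ("Chironomus salinarius", "invertebrate"),
    ("Cloeon dipterum", "invertebrate"),
    ("Esox lucius", "vertebrate"),
    ("Gammarus pulex", "invertebrate"),
    ("Iris pseudacorus", "plant"),
    ("Lycopus europaeus", "plant"),
    ("Mentha spicata", "plant"),
    ("Mus musculus", "vertebrate"),
    ("Notonecta glauca", "invertebrate"),
    ("Nuphar lutea", "plant"),
    ("Nymphaea alba", "plant"),
    ("Potamogeton perfoliatus", "plant"),
    ("Radix balthica", "invertebrate"),
    ("Tinca tinca", "vertebrate"),
    ("Utricularia australis", "plant"),
)

#: Feeding-trial regimes: grams ingested per prey species per sample.
FEEDING_REGIMES: dict[str, dict[str, float]] = {
    "Emys_0": {"Esox lucius": 20, "Chironomus salinarius": 5},
    "Emys_1": {"Mus musculus": 3, "Chironomus salinarius": 8},
    "Emys_2": {
        "Esox lucius": 19, "Oncorhynchus mykiss": 5, "Mus musculus": 6,
        "Chironomus salinarius": 5, "Gammarus pulex": 3,
    },
    "Emys_3": {"Esox lucius": 10, "Mus musculus": 15, "Chironomus salinarius": 5},
    "Emys_4": {"Chironomus salinarius": 8},
    "Emys_5": {"Esox lucius": 13, "Mus musculus": 5, "Gammarus pulex": 3},
}

FEEDING_GROUPS: dict[str, str] = {
    "Esox lucius": "vertebrate",
    "Oncorhynchus mykiss": "vertebrate",
    "Mus musculus": "vertebrate",
    "Chironomus salinarius": "invertebrate",
    "Gammarus pulex": "invertebrate",
}

HOST_SPECIES = ("Emys orbicularis", "vertebrate")


# ---------------------------------------------------------------------------
# Configuration and world building

@dataclass(frozen=True)
class RunConfig:
    """Tunable knobs of a synthetic end-to-end run (defaults = study conditions)."""

    n_extra_species: int = 12       # database-only species beyond the community
    copies_per_unit: int = 50       # template copies per unit weight
    copies_per_pair: int = 200      # amplicon copy budget per primer pair
    efficiency_sigma: float = 0.5   # lognormal amplification noise
    conspecific_divergence: float = 0.003
    mean_fragment_bp: int = 290
    sd_fragment_bp: int = 60
    min_fragment_bp: int = 50
    read_len: int = 150
    substitution_rate: float = 0.002
    k: int = 51
    solid_min_coverage: int = 2
    min_contig_len: int = 150
    assignment: AssignmentParams = AssignmentParams()


@dataclass
class World:
    """Shared synthetic universe: taxonomy, reference DB, panel, host."""

    tree: TaxonomyTree
    refs: list[ReferenceRecord]
    panel: list[pcr.PrimerPair]
    name_to_id: dict[str, str]
    host_taxon: str | None


def build_world(
    members: Sequence[tuple[str, str]],
    seed: int = 0,
    n_extra_species: int = 12,
    include_host: bool = True,
    panel: Sequence[pcr.PrimerPair] | None = None,
) -> World:
    """Simulate the taxonomy and reference database around a community.

    The reference database deliberately contains more species than the
    community (``n_extra_species`` synthetic bystanders), as any public
    nucleotide database would.
    """
    rng = np.random.default_rng([seed, 3])
    named = list(members)
    if include_host:
        named.append(HOST_SPECIES)
    groups = ("plant", "invertebrate", "vertebrate")
    existing = {n for n, _ in named}
    for i in range(n_extra_species):
        g = groups[i % 3]
        while True:
            name = f"{synthetic._latinish(rng, 3).capitalize()} {synthetic._latinish(rng, 3)}"
            if name not in existing:
                existing.add(name)
                break
        named.append((name, g))
    tree = synthetic.simulate_taxonomy(len(named), seed=seed, named_species=named)
    panel = list(panel) if panel is not None else pcr.load_panel()
    markers = synthetic.default_markers(panel)
    refs = synthetic.evolve_references(tree, markers, seed=seed)
    name_to_id = {}
    for sp in tree.species():
        name_to_id[sp.name] = sp.taxon_id
    host_taxon = name_to_id[HOST_SPECIES[0]] if include_host else None
    return World(tree=tree, refs=refs, panel=panel, name_to_id=name_to_id,
                 host_taxon=host_taxon)


def community_spec(
    world: World,
    weights: dict[str, float],
    mode: str = "MC1_pool_then_amplify",
    host_weight: float = 0.0,
) -> CommunitySpec:
    """Build a CommunitySpec from species names and weights."""
    members = tuple(
        (world.name_to_id[name], float(w)) for name, w in sorted(weights.items())
    )
    return CommunitySpec(
        members=members,
        mode=mode,
        host_taxon=world.host_taxon if host_weight > 0 else None,
        host_weight=host_weight,
    )


# ---------------------------------------------------------------------------
# Sample execution

@dataclass
class SampleResult:
    sample_id: str
    community: CommunitySample
    amplicons: list[pcr.Amplicon]
    n_read_pairs: int
    contigs: list[assembly.Contig]
    removed_contig_fraction: float
    assignments: list[Assignment]
    contig_markers: dict[str, str]
    mapping: quantify.MappingResult
    abundance: list[quantify.AbundanceRecord]
    host_report: quantify.HostReport | None
    log: list[str] = field(default_factory=list)

    @property
    def otus(self) -> list[str]:
        """Distinct assigned taxa in this sample (one OTU per unique taxon)."""
        return sorted({a.assigned_taxon for a in self.assignments if a.assigned_taxon})


def run_sample(
    world: World,
    spec: CommunitySpec,
    seed: int = 0,
    config: RunConfig = RunConfig(),
    sample_id: str = "sample",
    checklist: RegionalChecklist | None = None,
    outdir: str | Path | None = None,
) -> SampleResult:
    """Execute every stage for one sample; idempotent under a fixed seed."""
    log: list[str] = []

    def stage(name: str, t0: float, detail: str) -> None:
        log.append(f"{name}\t{time.time() - t0:.2f}s\t{detail}")

    t = time.time()
    community = synthetic.compose_community(
        spec, world.tree, world.refs, seed=seed,
        copies_per_unit=config.copies_per_unit,
        conspecific_divergence=config.conspecific_divergence,
    )
    stage("compose", t, f"members={len(spec.members)} templates={len(community.templates)}")

    t = time.time()
    amplicons = pcr.run_panel(
        community.templates, world.panel, mode=spec.mode, seed=seed,
        copies_per_pair=config.copies_per_pair,
        efficiency_sigma=config.efficiency_sigma,
    )
    stage("amplify", t, f"amplicons={len(amplicons)}")

    t = time.time()
    fragments = sequencing.shear(
        amplicons, mean_bp=config.mean_fragment_bp, sd_bp=config.sd_fragment_bp,
        min_bp=config.min_fragment_bp, seed=seed,
    )
    model = sequencing.ErrorModel(substitution_rate=config.substitution_rate)
    reads = sequencing.sequence_reads(
        fragments, read_len=config.read_len, model=model, seed=seed
    )
    stage("sequence", t, f"fragments={len(fragments)} read_pairs={len(reads)}")

    t = time.time()
    contigs, removed_fraction = assembly.assemble(
        reads, k=config.k, solid_min_coverage=config.solid_min_coverage,
        min_contig_len=config.min_contig_len,
    )
    stage("assemble", t, f"contigs={len(contigs)} removed_frac={removed_fraction:.4f}")

    t = time.time()
    acc_marker = {r.accession: r.marker_name for r in world.refs}
    db_len = sum(len(r.sequence) for r in world.refs)
    assignments: list[Assignment] = []
    contig_markers: dict[str, str] = {}
    for contig in contigs:
        hits = search(contig, world.refs, config.assignment, db_len=db_len)
        a = assign_contig(hits, config.assignment, world.tree)
        a = replace(a, contig_id=contig.contig_id)
        if checklist is not None:
            a = apply_checklist(a, checklist, world.tree)
        assignments.append(a)
        if hits:
            contig_markers[contig.contig_id] = acc_marker[hits[0].accession]
    stage("assign", t, f"assigned={sum(1 for a in assignments if a.assigned_taxon)}")

    t = time.time()
    if contigs:
        mapping = quantify.map_reads(reads, contigs)
    else:
        mapping = quantify.MappingResult(counts={}, unmapped=len(reads), total=len(reads))
    abundance = quantify.abundance_table(
        mapping, assignments, sample_id=sample_id, contig_markers=contig_markers
    )
    host_report = None
    if spec.host_taxon is not None:
        host_report = quantify.host_fraction(
            mapping, assignments, spec.host_taxon, sample_id=sample_id
        )
    stage("quantify", t, f"mapped={sum(mapping.counts.values())} unmapped={mapping.unmapped}")

    result = SampleResult(
        sample_id=sample_id,
        community=community,
        amplicons=amplicons,
        n_read_pairs=len(reads),
        contigs=contigs,
        removed_contig_fraction=removed_fraction,
        assignments=assignments,
        contig_markers=contig_markers,
        mapping=mapping,
        abundance=abundance,
        host_report=host_report,
        log=log,
    )
    if outdir is not None:
        _write_sample_outputs(result, world, Path(outdir))
    return result


def _write_sample_outputs(result: SampleResult, world: World, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    synthetic.write_truth_tsv(result.community, outdir / "truth.tsv")
    with open(outdir / "contigs.fasta", "w") as fh:
        for c in result.contigs:
            fh.write(f">{c.contig_id} cov={c.mean_kmer_coverage:.1f}\n{c.sequence}\n")
    write_assignments_tsv(result.assignments, outdir / "assignments.tsv", world.tree)
    quantify.write_abundance_tsv(result.abundance, outdir / "abundance.tsv")
    with open(outdir / "otu_table.tsv", "w") as fh:
        fh.write("taxon_id\tname\trank\n")
        for tid in result.otus:
            node = world.tree.node(tid)
            fh.write(f"{tid}\t{node.name}\t{node.rank.label}\n")
    (outdir / "run_log.txt").write_text(
        "\n".join(f"{result.sample_id}\t{line}" for line in result.log) + "\n"
    )


# ---------------------------------------------------------------------------
# Rounding conventions of the reports

def percentage(part: float, whole: float, decimals: int = 1) -> float:
    """Report-style percentage (e.g. 192/233 -> 82.4)."""
    if whole == 0:
        return 0.0
    return round(100.0 * part / whole, decimals)


def cohort_mean(values: Sequence[float], decimals: int = 2) -> float:
    """Cohort average of per-sample fractions (zeros included)."""
    if len(values) == 0:
        return 0.0
    return round(float(np.mean(values)), decimals)


# ---------------------------------------------------------------------------
# Diet summary

@dataclass
class DietReport:
    n_samples: int
    n_otus: int
    n_species_rank_otus: int
    species_rank_rate: float          # percent, 1 decimal
    group_presence: pd.DataFrame      # sample x group booleans
    group_fractions: dict[str, float]  # percent of samples containing group
    phylum_lengths: pd.DataFrame      # phylum, n, mean_bp, sd_bp


def diet_summary(results: Sequence[SampleResult], tree: TaxonomyTree) -> DietReport:
    """Cohort bookkeeping over per-sample OTUs.

    An OTU is one distinct assigned taxon within one sample; the
    species-rank rate is species-rank OTUs over all OTUs.  Group presence
    flags derive from the kingdom/phylum membership of assigned taxa; the
    host (when known) is excluded from diet groups.  Contig lengths are
    summarized per phylum over assigned contigs only.
    """
    if not results:
        raise ValueError("diet_summary needs >= 1 sample")
    presence_rows = []
    n_otus = 0
    n_species = 0
    length_rows = []
    for res in results:
        host = res.community.spec.host_taxon
        flags = {"plant": False, "vertebrate": False, "macro_invertebrate": False}
        for tid in res.otus:
            if tid == host:
                continue
            n_otus += 1
            if tree.reported_rank(tid) is Rank.SPECIES:
                n_species += 1
            grp = species_group(tree, tid)
            key = "macro_invertebrate" if grp == "invertebrate" else grp
            flags[key] = True
        presence_rows.append({"sample_id": res.sample_id, **flags})
        contig_len = {c.contig_id: c.length_bp for c in res.contigs}
        for a in res.assignments:
            if a.assigned_taxon and a.assigned_taxon != host:
                phylum = tree.ancestor_at(a.assigned_taxon, Rank.PHYLUM)
                length_rows.append(
                    {
                        "phylum": phylum.name if phylum else "unplaced",
                        "length_bp": contig_len[a.contig_id],
                    }
                )
    presence = pd.DataFrame(presence_rows).set_index("sample_id")
    fractions = {
        g: percentage(int(presence[g].sum()), len(presence)) for g in presence.columns
    }
    if length_rows:
        ldf = pd.DataFrame(length_rows)
        phylum_lengths = (
            ldf.groupby("phylum")["length_bp"]
            .agg(n="count", mean_bp="mean", sd_bp=lambda s: s.std(ddof=1))
            .reset_index()
        )
    else:
        phylum_lengths = pd.DataFrame(columns=["phylum", "n", "mean_bp", "sd_bp"])
    return DietReport(
        n_samples=len(results),
        n_otus=n_otus,
        n_species_rank_otus=n_species,
        species_rank_rate=percentage(n_species, n_otus),
        group_presence=presence,
        group_fractions=fractions,
        phylum_lengths=phylum_lengths,
    )


# ---------------------------------------------------------------------------
# Truth validation

@dataclass
class ValidationReport:
    table: pd.DataFrame  # member, detected, achieved_rank, best identity/length
    species_rank_recall: float
    precision: float
    mean_alignment_length: float
    min_identity: float


def summarize_alignment_table(
    df: pd.DataFrame,
    identity_col: str = "percent_identity",
    length_col: str = "alignment_length_bp",
) -> tuple[float, float]:
    """(mean alignment length, minimum identity) over non-missing rows."""
    sub = df[[identity_col, length_col]].apply(pd.to_numeric, errors="coerce").dropna()
    return float(sub[length_col].mean()), float(sub[identity_col].min())


def validate_truth(result: SampleResult, truth: pd.DataFrame | None = None,
                   tree: TaxonomyTree | None = None) -> ValidationReport:
    """Score a sample's assignments against its truth table.

    Detection means some contig was assigned to the member or to one of its
    ancestors (a genus-level call still detects the member); species-rank
    recall requires the exact species.  Precision counts species-rank calls
    to taxa outside the truth as false positives.  Host entries are scored
    separately and excluded from recall/precision.
    """
    truth = result.community.truth if truth is None else truth
    assigned = {a.assigned_taxon for a in result.assignments if a.assigned_taxon}
    best_by_taxon: dict[str, tuple[float, int]] = {}
    rank_by_taxon: dict[str, Rank] = {}
    for a in result.assignments:
        if not a.assigned_taxon:
            continue
        for h in a.hits:
            cur = best_by_taxon.get(h.taxon_id, (0.0, 0))
            if (h.percent_identity, h.alignment_length_bp) > cur:
                best_by_taxon[h.taxon_id] = (h.percent_identity, h.alignment_length_bp)
        rank_by_taxon[a.assigned_taxon] = (
            a.achieved_rank if a.achieved_rank is not None else Rank.ROOT
        )
    rows = []
    n_species_hits = 0
    members = truth[~truth["is_host"]] if "is_host" in truth.columns else truth
    for _, m in members.iterrows():
        tid = m["taxon_id"]
        species_hit = tid in assigned and rank_by_taxon.get(tid) is Rank.SPECIES
        detected = species_hit
        if not detected and tree is not None:
            ancestors = {n.taxon_id for n in tree.lineage(tid)}
            detected = bool(ancestors & assigned)
        best_i, best_l = best_by_taxon.get(tid, (float("nan"), 0))
        rows.append(
            {
                "taxon_id": tid,
                "name": m.get("name", tid),
                "detected": detected,
                "species_rank": species_hit,
                "percent_identity": round(best_i, 2),
                "alignment_length_bp": best_l,
            }
        )
        n_species_hits += int(species_hit)
    table = pd.DataFrame(rows)
    n_members = len(table)
    truth_ids = set(members["taxon_id"])
    host = result.community.spec.host_taxon
    species_calls = {
        tid for tid, rk in rank_by_taxon.items()
        if rk is Rank.SPECIES and tid != host
    }
    fp = len(species_calls - truth_ids)
    tp = len(species_calls & truth_ids)
    detected_df = table[table["species_rank"]]
    mean_len, min_ident = (
        summarize_alignment_table(detected_df)
        if len(detected_df) else (float("nan"), float("nan"))
    )
    return ValidationReport(
        table=table,
        species_rank_recall=0.0 if n_members == 0 else n_species_hits / n_members,
        precision=1.0 if (tp + fp) == 0 else tp / (tp + fp),
        mean_alignment_length=mean_len,
        min_identity=min_ident,
    )


# ---------------------------------------------------------------------------
# Printed-table fixtures

def _load_data_tsv(filename: str) -> pd.DataFrame:
    ref = importlib.resources.files("longmeta.data") / filename
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", na_values=["—", "-", ""])


def load_feeding_trial_table() -> pd.DataFrame:
    """Feeding-trial detections: sample, species, grams, identity, length."""
    return _load_data_tsv("feeding_trial_table.tsv")


def load_mock_community_table() -> pd.DataFrame:
    """Mock-community composition with per-member identity and length."""
    return _load_data_tsv("mock_community_table.tsv")
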