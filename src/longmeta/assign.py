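"""Contig-vs-reference search and the top-5 / 97.6% / LCA assignment rule.

Each contig is aligned locally against every reference (affine-gap
Smith-Waterman via Biopython's PairwiseAligner, both strands), hits are
gated by a Karlin-Altschul e-value surrogate and ranked by bit score, and
the five most significant references are retained.  Distinct taxa among
gate-passing hits (identity >= 97.6%, inclusive — the boundary case is
retained) decide the call: a single taxon is assigned directly; several
taxa collapse to their lowest common ancestor; no gate-passing hit leaves
the contig unassigned.  A regional checklist can afterwards promote a
supra-species call to the only species of that clade known from the study
area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
from Bio import Align

from .assembly import Contig
from .pcr import revcomp
from .synthetic import ReferenceRecord
from .taxonomy import Rank, TaxonomyTree

# megablast-like affine scoring
MATCH = 1
MISMATCH = -2
GAP_OPEN = -5
GAP_EXTEND = -2

# Karlin-Altschul surrogate constants for the scheme above
LAMBDA = 1.28
K_PARAM = 0.46


@dataclass(frozen=True)
class AlignmentHit:
    contig_id: str
    accession: str
    taxon_id: str
    percent_identity: float  # 2 decimals
    alignment_length_bp: int
    raw_score: int
    bit_score: float
    evalue: float


@dataclass(frozen=True)
class AssignmentParams:
    min_identity: float = 97.6
    max_evalue: float = 1e-20
    top_k: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class Assignment:
    contig_id: str
    assigned_taxon: str | None
    achieved_rank: Rank | None
    basis: str  # unanimous_species | lca_collapse | checklist_promotion | unassigned
    hits: tuple[AlignmentHit, ...] = ()


def _aligner() -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="local",
        match_score=MATCH,
        mismatch_score=MISMATCH,
        open_gap_score=GAP_OPEN,
        extend_gap_score=GAP_EXTEND,
    )


def local_align(query: str, reference: str) -> tuple[int, float, int]:
    """Optimal local alignment -> (raw_score, percent_identity, length).

    Percent identity is matching columns over all alignment columns
    (including gap columns), rounded to 2 decimals; length is the number of
    alignment columns.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner()
    aln = aligner.align(query, reference)[0]
    counts = aln.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    identity = 0.0 if ncols == 0 else round(100.0 * counts.identities / ncols, 2)
    return int(aln.score), identity, int(ncols)


def evalue(raw_score: float, query_len: int, db_len: int,
           lambda_: float = LAMBDA, k: float = K_PARAM) -> float:
    """Closed-form expected chance-hit count: E = K * m * n * exp(-lambda*S)."""
    if query_len < 1 or db_len < 1:
        raise ValueError("lengths must be >= 1")
    return k * query_len * db_len * math.exp(-lambda_ * raw_score)


def bit_score(raw_score: float, lambda_: float = LAMBDA, k: float = K_PARAM) -> float:
    return (lambda_ * raw_score - math.log(k)) / math.log(2.0)


def search(
    contig: Contig,
    refdb: Sequence[ReferenceRecord],
    params: AssignmentParams = AssignmentParams(),
    db_len: int | None = None,
) -> list[AlignmentHit]:
    """Ranked e-value-gated hits of one contig against the reference set.

    Both contig orientations are considered per reference (assembled
    contigs have arbitrary strand); at most one hit per accession.  Ranking
    is bit score descending with deterministic tie-breaks (e-value, percent
    identity, accession).  Traceback statistics are only computed for the
    candidates that can enter the top list.
    """
    if not refdb:
        raise ValueError("reference database is empty")
    db_len = db_len or sum(len(r.sequence) for r in refdb)
    aligner = _aligner()
    qf, qr = contig.sequence, revcomp(contig.sequence)

    scored: list[tuple[float, str, ReferenceRecord]] = []
    for ref in refdb:
        # cheap orientation pick, then one exact score per reference
        df = edlib.align(qf, ref.sequence, mode="HW", task="distance")["editDistance"]
        dr = edlib.align(qr, ref.sequence, mode="HW", task="distance")["editDistance"]
        q = qf if df <= dr else qr
        score = aligner.score(q, ref.sequence)
        scored.append((float(score), q, ref))
    scored.sort(key=lambda t: (-t[0], t[2].accession))

    hits: list[AlignmentHit] = []
    cutoff = params.top_k + 3  # headroom for score ties resolved by identity
    for score, q, ref in scored[: max(cutoff, params.top_k)]:
        e = evalue(score, len(contig.sequence), db_len)
        if e > params.max_evalue:
            continue
        raw, ident, ncols = local_align(q, ref.sequence)
        hits.append(
            AlignmentHit(
                contig_id=contig.contig_id,
                accession=ref.accession,
                taxon_id=ref.taxon_id,
                percent_identity=ident,
                alignment_length_bp=ncols,
                raw_score=raw,
                bit_score=round(bit_score(raw), 2),
                evalue=evalue(raw, len(contig.sequence), db_len),
            )
        )
    hits.sort(
        key=lambda h: (-h.bit_score, h.evalue, -h.percent_identity, h.accession)
    )
    return hits[: params.top_k]


def assign_contig(
    hits: Sequence[AlignmentHit],
    params: AssignmentParams,
    tree: TaxonomyTree,
) -> Assignment:
    """Apply the identity gate and the single-taxon / LCA-collapse rule.

    The taxon census counts distinct taxa among gate-passing hits only
    (identity >= min_identity, inclusive); multiple accessions of one taxon
    count once.  No gate-passing taxon -> unassigned.
    """
    contig_id = hits[0].contig_id if hits else ""
    passing = sorted({h.taxon_id for h in hits if h.percent_identity >= params.min_identity})
    support = tuple(h for h in hits if h.percent_identity >= params.min_identity)
    if not passing:
        return Assignment(contig_id, None, None, "unassigned", tuple(hits))
    for tid in passing:
        tree.node(tid)  # raises UnknownTaxonError naming the taxon
    if len(passing) == 1:
        taxon = passing[0]
        basis = "unanimous_species"
    else:
        taxon = tree.lca(passing).taxon_id
        basis = "lca_collapse"
    return Assignment(
        contig_id, taxon, tree.reported_rank(taxon), basis, support
    )


# ---------------------------------------------------------------------------
# Regional checklist promotion

@dataclass(frozen=True)
class RegionalChecklist:
    """Map from a higher-rank taxon to the single regional species under it."""

    entries: dict[str, str] = field(default_factory=dict)

    def validate(self, tree: TaxonomyTree) -> None:
        for key, sp in self.entries.items():
            node = tree.node(sp)
            if node.rank is not Rank.SPECIES:
                raise ValueError(f"checklist value {sp!r} is not species-rank")
            if all(a.taxon_id != key for a in tree.lineage(sp)):
                raise ValueError(
                    f"checklist species {sp!r} is not a descendant of key {key!r}"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, tree: TaxonomyTree | None = None
                 ) -> "RegionalChecklist":
        entries = {}
        for ln in Path(path).read_text(encoding="utf-8").splitlines():
            if not ln.strip() or ln.startswith("#") or ln.startswith("key_taxon_id"):
                continue
            key, sp, *_ = ln.split("\t")
            entries[key.strip()] = sp.strip()
        cl = cls(entries=entries)
        if tree is not None:
            cl.validate(tree)
        return cl


def apply_checklist(
    assignment: Assignment,
    checklist: RegionalChecklist,
    tree: TaxonomyTree,
) -> Assignment:
    """Promote a supra-species call when the clade has one regional species.

    Species-level assignments are never altered; promotion applies only
    when the assigned taxon itself is a checklist key.
    """
    if assignment.assigned_taxon is None:
        return assignment
    if assignment.achieved_rank is Rank.SPECIES:
        return assignment
    species = checklist.entries.get(assignment.assigned_taxon)
    if species is None:
        return assignment
    return Assignment(
        contig_id=assignment.contig_id,
        assigned_taxon=species,
        achieved_rank=tree.reported_rank(species),
        basis="checklist_promotion",
        hits=assignment.hits,
    )


# ---------------------------------------------------------------------------
# Tabular I/O (BLAST outfmt-6-style)

HITS_COLUMNS = ("qseqid", "sseqid", "pident", "length", "bitscore", "evalue", "staxid")


def write_hits_tsv(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(HITS_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.contig_id}\t{h.accession}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length_bp}\t{h.bit_score:.2f}\t{h.evalue:.2e}\t"
                f"{h.taxon_id}\n"
            )


def write_assignments_tsv(assignments: Iterable[Assignment], path: str | Path,
                          tree: TaxonomyTree | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "contig_id\tassigned_taxon\ttaxon_name\tachieved_rank\tbasis\t"
            "best_identity\tbest_alignment_length\n"
        )
        for a in assignments:
            name = (
                tree.node(a.assigned_taxon).name
                if tree is not None and a.assigned_taxon else ""
            )
            best_i = max((h.percent_identity for h in a.hits), default=0.0)
            best_l = max((h.alignment_length_bp for h in a.hits), default=0)
            fh.write(
                f"{a.contig_id}\t{a.assigned_taxon or ''}\t{name}\t"
                f"{a.achieved_rank.label if a.achieved_rank else ''}\t{a.basis}\t"
                f"{best_i:.2f}\t{best_l}\n"
            )
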