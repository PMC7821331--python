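"""Read-back mapping, per-contig abundances and host-read accounting.

Read counts per contig are the method's only quantitative signal, and the
point of this module is partly negative: primer-efficiency distortion makes
read abundance an unreliable biomass proxy, which the bias report makes
measurable (rank concordance between ingested weight and mapped-read share).
Mapping is a counting step, not an identification step, so its identity
threshold (95% over >= 100 aligned bases per pair) is looser than the
assignment gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .assembly import Contig
from .assign import Assignment
from .pcr import revcomp
from .sequencing import ReadPair

_INDEX_K = 21
_INDEX_STRIDE = 8


@dataclass(frozen=True)
class AbundanceRecord:
    sample_id: str
    contig_id: str
    assigned_taxon: str | None
    marker_name: str | None
    mapped_read_pairs: int
    percent_of_mapped: float


@dataclass(frozen=True)
class HostReport:
    sample_id: str
    host_detected: bool
    host_read_fraction: float  # % of raw read pairs


@dataclass
class MappingResult:
    counts: dict[str, int]  # contig_id -> mapped read pairs
    unmapped: int
    total: int


def _canon(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _mate_distance(mate: str, contig_seq: str) -> int:
    d1 = edlib.align(mate, contig_seq, mode="HW", task="distance")["editDistance"]
    d2 = edlib.align(revcomp(mate), contig_seq, mode="HW", task="distance")["editDistance"]
    return min(d1, d2)


def map_reads(
    read_pairs: Sequence[ReadPair],
    contigs: Sequence[Contig],
    min_identity_map: float = 95.0,
    min_aligned_bp: int = 100,
) -> MappingResult:
    """Best-single-placement mapping of read pairs onto contigs.

    Candidate contigs are found through a shared-k-mer index, then scored by
    infix edit distance of both mates (either orientation).  A pair maps to
    the contig with the smallest combined distance, provided combined
    identity is >= ``min_identity_map`` % over >= ``min_aligned_bp`` aligned
    bases; ties break lexicographically by contig id.  Unmapped pairs are
    counted separately.
    """
    if not contigs:
        raise ValueError("no contigs to map against")
    index: dict[str, set[str]] = {}
    for c in contigs:
        for i in range(0, len(c.sequence) - _INDEX_K + 1):
            index.setdefault(_canon(c.sequence[i: i + _INDEX_K]), set()).add(c.contig_id)
    by_id = {c.contig_id: c.sequence for c in contigs}

    counts = {c.contig_id: 0 for c in contigs}
    unmapped = 0
    for pair in read_pairs:
        candidates: set[str] = set()
        for mate in (pair.mate1, pair.mate2):
            for i in range(0, max(1, len(mate) - _INDEX_K + 1), _INDEX_STRIDE):
                kmer = mate[i: i + _INDEX_K]
                if len(kmer) == _INDEX_K:
                    candidates |= index.get(_canon(kmer), set())
        best: tuple[int, str] | None = None
        aligned = len(pair.mate1) + len(pair.mate2)
        for cid in sorted(candidates):
            d = _mate_distance(pair.mate1, by_id[cid]) + _mate_distance(
                pair.mate2, by_id[cid]
            )
            if best is None or (d, cid) < best:
                best = (d, cid)
        ok = (
            best is not None
            and aligned >= min_aligned_bp
            and 100.0 * (aligned - best[0]) / aligned >= min_identity_map
        )
        if ok:
            counts[best[1]] += 1
        else:
            unmapped += 1
    return MappingResult(counts=counts, unmapped=unmapped, total=len(read_pairs))


def abundance_table(
    mapping: MappingResult,
    assignments: Sequence[Assignment],
    sample_id: str = "sample",
    contig_markers: Mapping[str, str] | None = None,
) -> list[AbundanceRecord]:
    """Per-contig mapped-read shares, sorted by share descending.

    Every contig in the mapping must have an assignment record (possibly
    unassigned).  The same taxon recovered through several markers keeps
    one record per contig — shares are deliberately not merged.
    """
    by_contig = {a.contig_id: a for a in assignments}
    missing = sorted(set(mapping.counts) - set(by_contig))
    if missing:
        raise ValueError(f"contigs without assignment records: {missing}")
    total_mapped = sum(mapping.counts.values())
    records = []
    for cid in sorted(mapping.counts):
        n = mapping.counts[cid]
        pct = 0.0 if total_mapped == 0 else round(100.0 * n / total_mapped, 2)
        records.append(
            AbundanceRecord(
                sample_id=sample_id,
                contig_id=cid,
                assigned_taxon=by_contig[cid].assigned_taxon,
                marker_name=(contig_markers or {}).get(cid),
                mapped_read_pairs=n,
                percent_of_mapped=pct,
            )
        )
    records.sort(key=lambda r: (-r.percent_of_mapped, r.contig_id))
    return records


def host_fraction(
    mapping: MappingResult,
    assignments: Sequence[Assignment],
    host_taxon: str,
    sample_id: str = "sample",
) -> HostReport:
    """Share of raw read pairs on host-assigned contigs (0.0 if none)."""
    host_contigs = {
        a.contig_id for a in assignments if a.assigned_taxon == host_taxon
    }
    host_pairs = sum(mapping.counts.get(c, 0) for c in host_contigs)
    frac = 0.0 if mapping.total == 0 else 100.0 * host_pairs / mapping.total
    return HostReport(
        sample_id=sample_id,
        host_detected=bool(host_contigs),
        host_read_fraction=round(frac, 2),
    )


def quantification_bias_report(
    truth: pd.DataFrame,
    abundance: Sequence[AbundanceRecord],
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Rank concordance between ingested weight and mapped-read share.

    One row per sample with the Spearman correlation over truth members
    (their summed read share across contigs/markers) and a flag set when
    the heaviest ingested taxon is not the most abundant by reads.  With a
    single member the correlation is undefined and reported as NA.
    """
    share: dict[str, float] = {}
    for rec in abundance:
        if rec.assigned_taxon is not None:
            share[rec.assigned_taxon] = share.get(rec.assigned_taxon, 0.0) + (
                rec.percent_of_mapped
            )
    members = truth[~truth["is_host"]] if "is_host" in truth.columns else truth
    weights = members.set_index("taxon_id")["weight"]
    shares = np.array([share.get(t, 0.0) for t in weights.index])
    if len(weights) < 2:
        rho = float("nan")
        applicable = False
    else:
        rho = float(stats.spearmanr(weights.to_numpy(), shares).statistic)
        applicable = True
    top_weight = weights.idxmax() if len(weights) else None
    top_share = (
        weights.index[int(np.argmax(shares))] if len(weights) and shares.max() > 0
        else None
    )
    return pd.DataFrame(
        [
            {
                "sample_id": sample_id,
                "spearman_rho": rho,
                "applicable": applicable,
                "max_weight_taxon": top_weight,
                "max_abundance_taxon": top_share,
                "max_weight_is_max_abundance": (
                    top_weight is not None and top_weight == top_share
                ),
            }
        ]
    )


def write_abundance_tsv(records: Sequence[AbundanceRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t", index=False)
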