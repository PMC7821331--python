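"""In-silico PCR: degenerate primer matching and amplicon extraction.

The panel of 11 primer pairs (four COI pairs for animals, seven pairs over
rbcL/matK/28S/trnL-trnF for plants) is shipped as a TSV fixture and drives
multi-marker amplification of community template pools.  Two pooling
semantics are supported, mirroring how mock communities are built in the
wet lab: pool DNA then amplify (MC1, field and feeding-trial samples) versus
amplify each member separately then pool equimolar (MC2).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

# IUPAC degeneracy codes; inosine (I) pairs promiscuously and is treated as N.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"), "I": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNI", "TGCAYRSWMKVHDBNN")


def revcomp(seq: str) -> str:
    """Reverse complement; degeneracy codes map to their complements."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Primer:
    name: str
    sequence: str  # 5'->3', IUPAC codes allowed
    orientation: Literal["forward", "reverse"]

    def __post_init__(self) -> None:
        if len(self.sequence) < 15:
            raise ValueError(f"primer {self.name}: length < 15")
        bad = set(self.sequence) - set(IUPAC)
        if bad:
            raise ValueError(f"primer {self.name}: invalid codes {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    marker_name: str
    locus: str
    target_group: str  # plant | invertebrate | vertebrate
    expected_length_bp: int

    def __post_init__(self) -> None:
        if self.forward.orientation != "forward" or self.reverse.orientation != "reverse":
            raise ValueError(f"pair {self.marker_name}: orientations wrong")
        if not 168 <= self.expected_length_bp <= 1400:
            raise ValueError(
                f"pair {self.marker_name}: expected length {self.expected_length_bp} "
                "outside [168, 1400]"
            )


@dataclass(frozen=True)
class Amplicon:
    amplicon_id: str
    source_taxon: str
    marker_name: str
    sequence: str
    copy_number: int


def iupac_mismatches(primer: Primer | str, window: str) -> int:
    """Number of window positions incompatible with the primer's code sets."""
    pseq = primer.sequence if isinstance(primer, Primer) else primer
    if len(pseq) != len(window):
        raise ValueError(
            f"window length {len(window)} != primer length {len(pseq)}"
        )
    return sum(1 for p, b in zip(pseq, window) if b not in IUPAC[p])


def _binding_sites(
    template: str, primer_seq: str, max_mismatch: int, clamp_len: int
) -> list[int]:
    """Start offsets where the primer (given 5'->3' on this strand) binds.

    The 3'-terminal ``clamp_len`` bases must match exactly (polymerase
    extension is unforgiving at the 3' end); up to ``max_mismatch``
    mismatches are tolerated elsewhere.
    """
    L = len(primer_seq)
    sites = []
    body, clamp = primer_seq[: L - clamp_len], primer_seq[L - clamp_len:]
    for i in range(len(template) - L + 1):
        win = template[i: i + L]
        if iupac_mismatches(clamp, win[L - clamp_len:]) > 0:
            continue
        if iupac_mismatches(body, win[: L - clamp_len]) <= max_mismatch:
            sites.append(i)
    return sites


def amplify(
    template: str,
    pair: PrimerPair,
    max_mismatch: int = 2,
    clamp_len: int = 3,
    length_tolerance: float = 0.25,
) -> list[str]:
    """All products delimited by a forward site and a downstream reverse site.

    Both strands of the template are scanned; products are reported 5'->3'
    starting at the forward primer.  Product lengths outside
    ``expected_length_bp * (1 ± length_tolerance)`` are dropped.  No product
    is a legal outcome (primers simply fail to amplify off-target groups).
    Results are memoized — site scanning is deterministic and template
    pools are re-amplified across replicate runs.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    return list(
        _amplify_cached(template, pair, max_mismatch, clamp_len, length_tolerance)
    )


@lru_cache(maxsize=16384)
def _amplify_cached(
    template: str,
    pair: PrimerPair,
    max_mismatch: int,
    clamp_len: int,
    length_tolerance: float,
) -> tuple[str, ...]:
    lo = int(pair.expected_length_bp * (1 - length_tolerance))
    hi = int(round(pair.expected_length_bp * (1 + length_tolerance)))
    products: list[str] = []
    for strand in (template, revcomp(template)):
        f_sites = _binding_sites(strand, pair.forward.sequence, max_mismatch, clamp_len)
        r_rc = revcomp(pair.reverse.sequence)
        r_sites = _binding_sites(strand, r_rc, max_mismatch, clamp_len)
        for f in f_sites:
            for r in r_sites:
                end = r + len(r_rc)
                if end <= f:
                    continue
                if lo <= end - f <= hi:
                    products.append(strand[f:end])
    return tuple(products)


# ---------------------------------------------------------------------------
# Panel I/O

PANEL_COLUMNS = (
    "marker_name", "locus", "target_group", "direction", "primer_name",
    "sequence", "expected_length_bp",
)


def load_panel(path: str | Path | None = None) -> list[PrimerPair]:
    """Load a primer panel TSV; defaults to the shipped 11-pair panel."""
    if path is None:
        ref = importlib.resources.files("longmeta.data") / "primer_panel.tsv"
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    rows = [
        ln.split("\t") for ln in text.splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    header = [h.strip() for h in rows[0]]
    if header != list(PANEL_COLUMNS):
        raise ValueError(f"panel TSV columns must be {PANEL_COLUMNS}, got {header}")
    by_marker: dict[str, dict] = {}
    for row in rows[1:]:
        rec = dict(zip(header, (c.strip() for c in row)))
        entry = by_marker.setdefault(
            rec["marker_name"],
            {
                "locus": rec["locus"],
                "target_group": rec["target_group"],
                "expected_length_bp": int(rec["expected_length_bp"]),
            },
        )
        entry[rec["direction"]] = Primer(
            name=rec["primer_name"],
            sequence=rec["sequence"].upper(),
            orientation=rec["direction"],  # type: ignore[arg-type]
        )
    pairs = []
    for marker, entry in by_marker.items():
        pairs.append(
            PrimerPair(
                forward=entry["forward"],
                reverse=entry["reverse"],
                marker_name=marker,
                locus=entry["locus"],
                target_group=entry["target_group"],
                expected_length_bp=entry["expected_length_bp"],
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Panel runs over template pools

@dataclass(frozen=True)
class Template:
    """One template molecule species in a pool (a locus of one community member)."""

    member_taxon: str
    sequence: str
    copies: int


def run_panel(
    templates: Sequence[Template],
    panel: Sequence[PrimerPair],
    mode: str = "MC1_pool_then_amplify",
    seed: int = 0,
    copies_per_pair: int = 200,
    efficiency_sigma: float = 0.5,
    max_mismatch: int = 2,
) -> list[Amplicon]:
    """Amplify a template pool with every pair and pool the products.

    Each pair gets an equal copy budget (equal per-barcode pooling volume).
    MC1/feeding-trial/field mode allocates a pair's budget across members in
    proportion to template copies times a per-(member, pair) lognormal
    efficiency factor — the deliberate distortion that makes read counts a
    poor biomass proxy.  MC2 mode amplifies each member separately and pools
    equimolar, so every producing member gets an equal share of the budget
    regardless of its input weight.
    """
    if not panel:
        raise ValueError("primer panel is empty")
    if not templates:
        raise ValueError("template pool is empty")
    rng = np.random.default_rng(seed)
    equalize = mode == "MC2_amplify_then_pool"
    out: list[Amplicon] = []
    counter = 0
    for pair in sorted(panel, key=lambda p: p.marker_name):
        # products per member, deterministic order
        member_products: dict[str, list[str]] = {}
        member_copies: dict[str, int] = {}
        for tpl in sorted(templates, key=lambda t: (t.member_taxon, t.sequence)):
            prods = amplify(tpl.sequence, pair, max_mismatch=max_mismatch)
            if prods:
                member_products.setdefault(tpl.member_taxon, []).extend(prods)
                member_copies[tpl.member_taxon] = (
                    member_copies.get(tpl.member_taxon, 0) + tpl.copies
                )
        # efficiency factors are drawn for every (member, pair) in a fixed
        # order so MC1 and MC2 runs with the same seed see the same noise
        members = sorted(member_products)
        eff = {
            m: float(np.exp(rng.normal(0.0, efficiency_sigma))) for m in members
        }
        if not members:
            continue
        if equalize:
            weights = {m: 1.0 for m in members}
        else:
            weights = {m: member_copies[m] * eff[m] for m in members}
        total_w = sum(weights.values())
        for m in members:
            share = int(round(copies_per_pair * weights[m] / total_w))
            if share <= 0:
                continue
            prods = member_products[m]
            base, extra = divmod(share, len(prods))
            for j, seq in enumerate(prods):
                copies = base + (1 if j < extra else 0)
                if copies <= 0:
                    continue
                counter += 1
                out.append(
                    Amplicon(
                        amplicon_id=f"amp{counter:05d}",
                        source_taxon=m,
                        marker_name=pair.marker_name,
                        sequence=seq,
                        copy_number=copies,
                    )
                )
    return out


def write_amplicons_fasta(amplicons: Iterable[Amplicon], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in amplicons:
            fh.write(
                f">{a.amplicon_id}|{a.source_taxon}|{a.marker_name}|{a.copy_number}\n"
                f"{a.sequence}\n"
            )
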