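"""Shearing of pooled amplicons and 2x150 bp paired-end read simulation.

Models the sequencing half of the protocol: amplicon pools are mechanically
fragmented (ultrasonication) to a mean fragment size of 290 bp, libraries
are sequenced as 150 bp paired-end reads, and base-call errors are injected
as i.i.d. substitutions.  A truth channel records which amplicon and taxon
every read pair came from, so downstream stages can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .pcr import Amplicon, revcomp

DEFAULT_MEAN_BP = 290
DEFAULT_SD_BP = 60
DEFAULT_MIN_BP = 50


@dataclass(frozen=True)
class Fragment:
    """A sheared slice of one amplicon copy (0-based half-open coords)."""

    fragment_id: str
    amplicon_id: str
    source_taxon: str
    marker_name: str
    start: int
    end: int
    sequence: str


@dataclass(frozen=True)
class ErrorModel:
    substitution_rate: float = 0.002
    q_correct: int = 36
    q_error: int = 14

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate <= 0.05:
            raise ValueError("substitution_rate outside [0, 0.05]")


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    mate1: str
    mate2: str
    qual1: str
    qual2: str
    amplicon_id: str
    source_taxon: str


def draw_fragment_lengths(
    n: int,
    mean_bp: float = DEFAULT_MEAN_BP,
    sd_bp: float = DEFAULT_SD_BP,
    min_bp: float = DEFAULT_MIN_BP,
    max_bp: float = np.inf,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Raw fragment-length draws: normal(mean, sd) truncated to [min, max].

    Rejection sampling, so the draws follow the truncated normal exactly.
    """
    rng = np.random.default_rng() if rng is None else rng
    if max_bp <= min_bp:
        return np.full(n, float(min_bp))
    out = np.empty(n)
    filled = 0
    while filled < n:
        batch = rng.normal(mean_bp, sd_bp, size=max(n - filled, 16))
        ok = batch[(batch >= min_bp) & (batch <= max_bp)]
        take = min(len(ok), n - filled)
        out[filled: filled + take] = ok[:take]
        filled += take
    return out


def _breakpoints(length: int, mean_bp: int, sd_bp: int, min_bp: int,
                 rng: np.random.Generator, max_unsplit_bp: int = 300) -> list[int]:
    """Sequential cut positions tiling [0, length].

    Piece sizes are drawn one after another from the truncated normal
    (clipped so the remainder stays >= ``min_bp``) while the remaining
    molecule exceeds 1.5x the target mean; the final remainder is left as
    the last fragment.  A molecule that would otherwise stay uncut but is
    longer than ``max_unsplit_bp`` receives one cut anyway — an uncut piece
    longer than both mates of a read pair together would carry an interior
    stretch no copy could ever sequence, which ultrasonication does not do.
    """
    if length <= min_bp:
        return [0, length]
    cuts = [0]
    rem = length
    while rem > 1.5 * mean_bp:
        f = int(round(
            draw_fragment_lengths(
                1, mean_bp, sd_bp, min_bp, max_bp=rem - min_bp, rng=rng
            )[0]
        ))
        f = min(max(f, min_bp), rem - min_bp)
        cuts.append(cuts[-1] + f)
        rem -= f
    if len(cuts) == 1 and rem > max_unsplit_bp:
        f = int(round(
            draw_fragment_lengths(
                1, mean_bp, sd_bp, min_bp, max_bp=rem - min_bp, rng=rng
            )[0]
        ))
        f = min(max(f, min_bp), rem - min_bp)
        cuts.append(f)
    cuts.append(length)
    return cuts


def shear(
    amplicons: Sequence[Amplicon],
    mean_bp: int = DEFAULT_MEAN_BP,
    sd_bp: int = DEFAULT_SD_BP,
    min_bp: int = DEFAULT_MIN_BP,
    seed: int = 0,
) -> list[Fragment]:
    """Fragment every copy of every amplicon; fragments tile each copy."""
    if not (mean_bp >= min_bp >= 1):
        raise ValueError("require mean_bp >= min_bp >= 1")
    rng = np.random.default_rng([seed, 29])
    fragments: list[Fragment] = []
    n = 0
    for amp in amplicons:
        L = len(amp.sequence)
        for _copy in range(amp.copy_number):
            cuts = _breakpoints(L, mean_bp, sd_bp, min_bp, rng)
            for s, e in zip(cuts[:-1], cuts[1:]):
                n += 1
                fragments.append(
                    Fragment(
                        fragment_id=f"frag{n:07d}",
                        amplicon_id=amp.amplicon_id,
                        source_taxon=amp.source_taxon,
                        marker_name=amp.marker_name,
                        start=s,
                        end=e,
                        sequence=amp.sequence[s:e],
                    )
                )
    return fragments


_MUT = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def _read_from(template: str, read_len: int, model: ErrorModel,
               rng: np.random.Generator) -> tuple[str, str]:
    n = min(read_len, len(template))
    bases = list(template[:n])
    quals = [model.q_correct] * n
    errs = np.flatnonzero(rng.random(n) < model.substitution_rate)
    for i in errs:
        bases[i] = _MUT[bases[i]][int(rng.integers(3))]
        quals[i] = model.q_error
    return "".join(bases), "".join(chr(q + 33) for q in quals)


def sequence_reads(
    fragments: Sequence[Fragment],
    read_len: int = 150,
    model: ErrorModel = ErrorModel(),
    depth_multiplier: int = 1,
    seed: int = 0,
) -> list[ReadPair]:
    """One read pair per fragment (times ``depth_multiplier``).

    Mate 1 reads the fragment 5' end; mate 2 reads the reverse-complement
    end, as on a paired-end flow cell.  Substitutions are i.i.d. at the
    model's rate; erroneous positions get the low quality score.
    """
    if read_len < 30:
        raise ValueError("read_len must be >= 30")
    rng = np.random.default_rng([seed, 31])
    pairs: list[ReadPair] = []
    n = 0
    for frag in fragments:
        for _rep in range(depth_multiplier):
            n += 1
            m1, q1 = _read_from(frag.sequence, read_len, model, rng)
            m2, q2 = _read_from(revcomp(frag.sequence), read_len, model, rng)
            pairs.append(
                ReadPair(
                    read_id=f"read{n:07d}",
                    mate1=m1, mate2=m2, qual1=q1, qual2=q2,
                    amplicon_id=frag.amplicon_id,
                    source_taxon=frag.source_taxon,
                )
            )
    return pairs


def write_fastq(pairs: Iterable[ReadPair], r1_path: str | Path, r2_path: str | Path,
                truth_path: str | Path | None = None) -> None:
    """Write mates to two FASTQ files (Phred+33) plus an optional truth TSV."""
    pairs = list(pairs)
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.mate1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.mate2}\n+\n{p.qual2}\n")
    if truth_path is not None:
        with open(truth_path, "w") as ft:
            ft.write("read_id\tamplicon_id\tsource_taxon\n")
            for p in pairs:
                ft.write(f"{p.read_id}\t{p.amplicon_id}\t{p.source_taxon}\n")


def load_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    """Load paired FASTQ files produced by this module or externally."""
    from Bio import SeqIO

    r1 = list(SeqIO.parse(str(r1_path), "fastq"))
    r2 = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(r1) != len(r2):
        raise ValueError("R1/R2 read counts differ")
    pairs = []
    for a, b in zip(r1, r2):
        pairs.append(
            ReadPair(
                read_id=a.id.split("/")[0],
                mate1=str(a.seq).upper(),
                mate2=str(b.seq).upper(),
                qual1="".join(chr(q + 33) for q in a.letter_annotations["phred_quality"]),
                qual2="".join(chr(q + 33) for q in b.letter_annotations["phred_quality"]),
                amplicon_id="",
                source_taxon="",
            )
        )
    return pairs
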