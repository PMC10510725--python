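"""Promoter sequence tools: CpG enumeration, density, and density edits.

A CpG is a cytosine immediately followed by a guanine on the forward
strand.  Coordinates throughout are 1-based and local to the supplied
sequence; CpGs are named ``CpG<position-of-C>`` (e.g. CpG793).  Only
forward-strand CG occurrences are counted — CpG is its own reverse
complement, so counting one strand avoids double counting.

CpG density ``c`` is the fraction of bases participating in CG
dinucleotides, reported in percent::

    c = 100 * 2 * (#CG occurrences) / length

Overlapping occurrences are counted independently (``CGCG`` has two).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import (
    DinucleotideMismatchError,
    InvalidAlphabetError,
    UnreachableTargetError,
)

__all__ = [
    "PromoterSequence",
    "enumerate_cpgs",
    "cpg_density",
    "mutate_cpg",
    "lower_cpg_density",
    "random_promoter",
    "read_fasta",
    "write_fasta",
]

_ALPHABET = frozenset("ACGT")


def _validate(sequence: str) -> str:
    """Uppercase and validate a DNA string; IUPAC ambiguity codes are rejected."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    for i, ch in enumerate(seq):
        if ch not in _ALPHABET:
            raise InvalidAlphabetError(ch, i + 1)
    return seq


def enumerate_cpgs(sequence: str) -> list[int]:
    """1-based positions of the C of every CG dinucleotide, ascending.

    >>> enumerate_cpgs("ATCGAT")
    [3]
    >>> enumerate_cpgs("CGCG")
    [1, 3]
    """
    seq = _validate(sequence)
    return [i + 1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def cpg_density(sequence: str) -> float:
    """CpG density in percent: 100 * 2 * #CG / length."""
    seq = _validate(sequence)
    return 100.0 * 2.0 * len(enumerate_cpgs(seq)) / len(seq)


@dataclasses.dataclass(frozen=True)
class PromoterSequence:
    """A named promoter with its CpG positions and CpG density.

    Attributes
    ----------
    name : str
        Identifier (FASTA record id).
    sequence : str
        Uppercase DNA over {A, C, G, T}.
    cpg_positions : tuple of int
        1-based positions of the C of each CG dinucleotide.
    density_c : float
        Percent of bases participating in CG dinucleotides.
    """

    name: str
    sequence: str
    cpg_positions: tuple[int, ...] = dataclasses.field(init=False)
    density_c: float = dataclasses.field(init=False)

    def __post_init__(self):
        seq = _validate(self.sequence)
        object.__setattr__(self, "sequence", seq)
        pos = tuple(enumerate_cpgs(seq))
        object.__setattr__(self, "cpg_positions", pos)
        object.__setattr__(self, "density_c", 100.0 * 2.0 * len(pos) / len(seq))

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    def cpg_name(self, position: int) -> str:
        """Field-style name for a CpG, e.g. ``CpG793``."""
        if position not in self.cpg_positions:
            raise ValueError(f"position {position} is not a CpG of {self.name}")
        return f"CpG{position}"


def mutate_cpg(
    promoter: PromoterSequence, position: int, mode: str
) -> PromoterSequence:
    """Point-mutate the second base of a dinucleotide: CG→CC or CC→CG.

    ``cg_to_cc`` removes a CpG by G→C at ``position + 1``; ``cc_to_cg`` is
    the inverse.  Exactly one base changes; the two modes are mutual
    inverses at the same position.
    """
    if mode not in ("cg_to_cc", "cc_to_cg"):
        raise ValueError(f"unknown mode {mode!r}")
    expected = "CG" if mode == "cg_to_cc" else "CC"
    if position < 1 or position + 1 > promoter.length:
        raise ValueError(f"position {position} out of range for length {promoter.length}")
    found = promoter.sequence[position - 1 : position + 1]
    if found != expected:
        raise DinucleotideMismatchError(position, expected, found)
    new_second = "C" if mode == "cg_to_cc" else "G"
    seq = promoter.sequence[:position] + new_second + promoter.sequence[position + 1 :]
    return PromoterSequence(promoter.name, seq)


#: density-lowering edit strategies, applied left-to-right per CpG
_STRATEGIES = ("cg_to_gc", "c_to_t")


def lower_cpg_density(
    promoter: PromoterSequence,
    target_density: float,
    strategy: Sequence[str] = ("cg_to_gc", "c_to_t"),
) -> tuple[PromoterSequence, list[tuple[int, str]]]:
    """Edit CpGs left-to-right until density drops to ``target_density``.

    ``cg_to_gc`` swaps a CG for GC (base composition preserved);
    ``c_to_t`` replaces the C of a CG with T.  A swap can create a new CG
    with a neighbouring base; a candidate edit is only applied if it
    strictly reduces the CpG count.  Returns the edited promoter and an
    edit log of ``(position, edit_type)``.

    Raises
    ------
    UnreachableTargetError
        If every CpG has been visited and density is still above target.
    """
    for s in strategy:
        if s not in _STRATEGIES:
            raise ValueError(f"unknown strategy {s!r}")
    if target_density > promoter.density_c + 1e-12:
        raise ValueError(
            f"target density {target_density}% above current {promoter.density_c:.3f}%"
        )
    current = promoter
    log: list[tuple[int, str]] = []
    visited: set[int] = set()
    while current.density_c > target_density + 1e-12:
        candidates = [p for p in current.cpg_positions if p not in visited]
        if not candidates:
            raise UnreachableTargetError(target_density, current.density_c)
        pos = candidates[0]
        visited.add(pos)
        seq = current.sequence
        for s in strategy:
            if s == "cg_to_gc":
                edited = seq[: pos - 1] + "GC" + seq[pos + 1 :]
            else:  # c_to_t
                edited = seq[: pos - 1] + "T" + seq[pos:]
            trial = PromoterSequence(current.name, edited)
            if trial.n_cpg < current.n_cpg:
                current = trial
                log.append((pos, s))
                break
    return current, log


def random_promoter(
    name: str,
    length: int,
    target_density: float,
    seed: int | np.random.Generator = 0,
) -> PromoterSequence:
    """Generate a synthetic promoter of given length and CpG density.

    Places ``round(target_density/100 * length / 2)`` non-overlapping CG
    dinucleotides at random positions on an A/T background, so the
    realised density equals the target up to one-CpG granularity.  The
    A/T backbone means base composition is not realistic; only CpG
    placement matters to the analyses here.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_cpg = int(round(target_density / 100.0 * length / 2.0))
    if 2 * n_cpg > length:
        raise ValueError("target density implies more CG bases than sequence length")
    bases = list(rng.choice(["A", "T"], size=length))
    # choose non-adjacent start slots so CGs never overlap or touch
    placed = 0
    order = rng.permutation(length - 1)
    occupied = np.zeros(length, dtype=bool)
    for start in order:
        if placed == n_cpg:
            break
        if occupied[max(0, start - 1) : min(length, start + 3)].any():
            continue
        bases[start] = "C"
        bases[start + 1] = "G"
        occupied[start : start + 2] = True
        placed += 1
    if placed < n_cpg:
        raise ValueError(f"could only place {placed} of {n_cpg} CpGs at length {length}")
    return PromoterSequence(name, "".join(bases))


def read_fasta(path: str | Path) -> list[PromoterSequence]:
    """Read a promoter library from FASTA; record ids become names."""
    return [
        PromoterSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(promoters: Iterable[PromoterSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.name, description="") for p in promoters
    ]
    SeqIO.write(records, str(path), "fasta")
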