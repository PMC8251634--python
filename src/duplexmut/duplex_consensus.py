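"""Strand-aware read grouping and duplex consensus calling.

Reads sharing fragment coordinates and a common molecular tag pair in
both strand orientations are grouped into families; each strand lineage
is collapsed to a single-strand consensus (SSC), and the two SSCs are
combined into a duplex consensus in which a base is emitted only where
both strands agree. Positions failing support or agreement thresholds
become ``N`` and are excluded from the non-ambiguous duplex base count
that serves as the mutant-frequency denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .panel_sim import BASES, ReferencePanel, SimulatedRead

FamilyKey = tuple[str, int, int, tuple[str, str]]


@dataclass
class ReadFamily:
    """All reads from one source molecule, split by strand of origin.

    ``family_key`` is (locus_id, start, end, canonical tag pair) where the
    canonical pair is lexicographically ordered; the strand label of each
    read follows from whether its tag order matches the canonical order.
    """

    family_key: FamilyKey
    top_reads: list[SimulatedRead] = field(default_factory=list)
    bottom_reads: list[SimulatedRead] = field(default_factory=list)


@dataclass
class StrandConsensus:
    sequence: str
    support: np.ndarray  # per-position read count backing the emitted base
    strand: str


@dataclass
class DuplexConsensusSequence:
    """Error-corrected double-strand consensus over one fragment."""

    locus_id: str
    start: int
    end: int
    sequence: str
    family_key: FamilyKey

    @property
    def n_non_ambiguous(self) -> int:
        return len(self.sequence) - self.sequence.count("N")


class DepthTable:
    """Per-site non-ambiguous duplex base counts over the panel."""

    def __init__(self, panel: ReferencePanel):
        self.depth: dict[str, np.ndarray] = {
            l.locus_id: np.zeros(l.length, dtype=np.int64) for l in panel.loci
        }
        self._territory = panel.total_territory

    def total(self) -> int:
        return int(sum(arr.sum() for arr in self.depth.values()))

    def mean_depth(self) -> float:
        return self.total() / self._territory

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("locus\tpos\tdepth\n")
            for locus_id, arr in self.depth.items():
                for pos in np.flatnonzero(arr):
                    fh.write(f"{locus_id}\t{pos}\t{arr[pos]}\n")


def _canonical(tags: tuple[str, str]) -> tuple[str, str]:
    return tags if tags[0] <= tags[1] else (tags[1], tags[0])


def group_reads(reads: Iterable[SimulatedRead]) -> list[ReadFamily]:
    """Partition reads into strand-resolved families.

    Family identity is (coordinates, canonical tag pair) only — never the
    simulator's molecule id. Reads whose tag order equals the canonical
    order go to one strand bucket, the reverse order to the other, so the
    two physical strands of a molecule end up in the same family with
    their origin preserved.
    """
    families: dict[FamilyKey, ReadFamily] = {}
    for read in reads:
        if len(read.umi_pair) != 2 or not all(read.umi_pair):
            raise ValueError(f"malformed tag pair on read {read.read_id!r}")
        canon = _canonical(read.umi_pair)
        key: FamilyKey = (read.locus_id, read.start, read.end, canon)
        fam = families.get(key)
        if fam is None:
            fam = families[key] = ReadFamily(key)
        if read.umi_pair == canon:
            fam.top_reads.append(read)
        else:
            fam.bottom_reads.append(read)
    return list(families.values())


def call_strand_consensus(
    reads: Sequence[SimulatedRead], strand: str,
    min_reads: int = 2, agreement: float = 0.9,
) -> StrandConsensus | None:
    """Collapse one strand lineage to a consensus.

    Returns ``None`` when fewer than ``min_reads`` reads back the strand.
    Per position, the plurality base is emitted only when its fraction of
    reads is at least ``agreement`` (which at family size 2 demands
    unanimity for any agreement > 0.5); otherwise ``N``.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if not (0.5 < agreement <= 1.0):
        raise ValueError("agreement must lie in (0.5, 1]")
    if len(reads) < min_reads:
        return None
    mat = np.stack([
        np.frombuffer(r.sequence.encode(), dtype=np.uint8) for r in reads
    ])
    n = len(reads)
    counts = (mat[:, None, :] == BASES[None, :, None]).sum(axis=0)
    best = counts.argmax(axis=0)
    best_n = counts.max(axis=0)
    seq = BASES[best].copy()
    ambiguous = best_n < agreement * n
    seq[ambiguous] = ord("N")
    return StrandConsensus(
        sequence=seq.tobytes().decode(),
        support=np.where(ambiguous, 0, best_n),
        strand=strand,
    )


def call_duplex_consensus(
    family: ReadFamily, min_reads: int = 2, agreement: float = 0.9,
) -> DuplexConsensusSequence | None:
    """Form the duplex consensus of one family, or ``None`` when either
    strand lacks a consensus. A base is non-N only where both strand
    consensuses are non-N and identical."""
    top = call_strand_consensus(family.top_reads, "top", min_reads, agreement)
    bottom = call_strand_consensus(family.bottom_reads, "bottom",
                                   min_reads, agreement)
    if top is None or bottom is None:
        return None
    if len(top.sequence) != len(bottom.sequence):
        raise RuntimeError(
            f"strand consensus length mismatch in family {family.family_key}")
    t = np.frombuffer(top.sequence.encode(), dtype=np.uint8)
    b = np.frombuffer(bottom.sequence.encode(), dtype=np.uint8)
    seq = t.copy()
    seq[(t != b) | (t == ord("N"))] = ord("N")
    locus_id, start, end, _ = family.family_key
    return DuplexConsensusSequence(
        locus_id=locus_id, start=start, end=end,
        sequence=seq.tobytes().decode(), family_key=family.family_key,
    )


def call_duplexes(
    reads: Iterable[SimulatedRead], min_reads: int = 2, agreement: float = 0.9,
) -> list[DuplexConsensusSequence]:
    """Full grouping + consensus pass over a read set."""
    duplexes = []
    for family in group_reads(reads):
        dup = call_duplex_consensus(family, min_reads, agreement)
        if dup is not None:
            duplexes.append(dup)
    return duplexes


def tabulate_duplex_depth(
    duplexes: Iterable[DuplexConsensusSequence], panel: ReferencePanel,
) -> tuple[DepthTable, list[DuplexConsensusSequence]]:
    """Count non-ambiguous duplex bases per panel site.

    Returns the table and any duplexes falling outside the panel
    territory (flagged, excluded from on-target accounting).
    """
    table = DepthTable(panel)
    off_target: list[DuplexConsensusSequence] = []
    for dup in duplexes:
        arr = table.depth.get(dup.locus_id)
        if arr is None or dup.start < 0 or dup.end > len(arr):
            off_target.append(dup)
            continue
        seq = np.frombuffer(dup.sequence.encode(), dtype=np.uint8)
        arr[dup.start:dup.end] += (seq != ord("N"))
    return table, off_target


def write_duplex_tsv(
    duplexes: Iterable[DuplexConsensusSequence], path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tstart\tend\tsequence\n")
        for d in duplexes:
            fh.write(f"{d.locus_id}\t{d.start}\t{d.end}\t{d.sequence}\n")
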