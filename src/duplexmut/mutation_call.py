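"""Mutation calling on duplex consensus bases and per-sample mutant
frequency with Wilson confidence intervals.

A variant duplex base is a somatic mutation call when its site variant
allele frequency (VAF, fraction of duplex molecules carrying the
alternative allele) is below a germline threshold — by default 1%, which
removes inherited heterozygous polymorphisms sitting near VAF 0.5. The
per-sample mutant frequency is the number of unique mutations divided by
the total number of non-ambiguous duplex consensus bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .duplex_consensus import DepthTable, DuplexConsensusSequence
from .panel_sim import BASE_STR, BASES, ReferencePanel, SourceMolecule

_BASE_INDEX = {b: i for i, b in enumerate(BASE_STR)}


@dataclass(frozen=True)
class DuplexPileupSite:
    """One panel position with duplex depth and alternative-allele counts."""

    locus_id: str
    position: int
    ref: str
    depth: int
    alt_counts: dict[str, int]

    def __post_init__(self) -> None:
        if sum(self.alt_counts.values()) > self.depth:
            raise ValueError("alt counts exceed depth")


@dataclass(frozen=True)
class MutationCall:
    locus_id: str
    position: int
    ref: str
    alt: str
    alt_count: int   # supporting duplex molecules
    depth: int       # non-ambiguous duplex depth at the site
    context: str     # reference 5' + ref + 3' trinucleotide

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth


@dataclass(frozen=True)
class SampleMutationResult:
    """Per-sample mutant-frequency summary with its Wilson interval."""

    sample_id: str
    total_duplex_bases: int
    mutation_count: int
    mutant_frequency: float
    ci_lower: float
    ci_upper: float
    confidence: float = 0.95


class Pileup:
    """Dense per-locus base counts from duplex consensus sequences."""

    def __init__(self, panel: ReferencePanel):
        self.panel = panel
        self.counts: dict[str, np.ndarray] = {
            l.locus_id: np.zeros((l.length, 4), dtype=np.int64)
            for l in panel.loci
        }

    def depth_array(self, locus_id: str) -> np.ndarray:
        return self.counts[locus_id].sum(axis=1)

    def total_bases(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def variant_sites(self) -> list[DuplexPileupSite]:
        """Sites holding at least one non-reference duplex base."""
        sites = []
        for locus in self.panel.loci:
            counts = self.counts[locus.locus_id]
            ref_idx = np.frombuffer(locus.sequence.encode(), dtype=np.uint8)
            ref_idx = np.searchsorted(BASES, ref_idx)
            depth = counts.sum(axis=1)
            alt_total = depth - counts[np.arange(len(counts)), ref_idx]
            for pos in np.flatnonzero(alt_total):
                ref = locus.sequence[pos]
                alts = {
                    BASE_STR[j]: int(counts[pos, j])
                    for j in range(4)
                    if j != ref_idx[pos] and counts[pos, j] > 0
                }
                sites.append(DuplexPileupSite(
                    locus.locus_id, int(pos), ref, int(depth[pos]), alts))
        return sites


def pileup(
    duplexes: Iterable[DuplexConsensusSequence], panel: ReferencePanel,
) -> Pileup:
    """Tally every non-N duplex consensus base into per-site counts."""
    pile = Pileup(panel)
    for dup in duplexes:
        seq = np.frombuffer(dup.sequence.encode(), dtype=np.uint8)
        keep = seq != ord("N")
        pos = np.arange(dup.start, dup.end)[keep]
        base_idx = np.searchsorted(BASES, seq[keep])
        np.add.at(pile.counts[dup.locus_id], (pos, base_idx), 1)
    return pile


def pileup_from_molecules(
    molecules: Sequence[SourceMolecule], panel: ReferencePanel,
) -> Pileup:
    """Exact molecule-level pileup, bypassing read simulation.

    Equivalent to the read-level path when sequencing and PCR error rates
    are zero and every strand satisfies the consensus support threshold:
    each molecule then yields a duplex consensus equal to its own
    sequence. Used for large calibration studies where simulating
    individual reads adds nothing but cost.
    """
    pile = Pileup(panel)
    # Reference coverage via interval difference trick, then move
    # variant bases from the reference row to their alt rows.
    cover: dict[str, np.ndarray] = {
        l.locus_id: np.zeros(l.length + 1, dtype=np.int64) for l in panel.loci
    }
    edits: list[tuple[str, int, str]] = []
    for mol in molecules:
        cov = cover[mol.locus_id]
        cov[mol.start] += 1
        cov[mol.end] -= 1
        for pos, alt in mol.germline_alleles.items():
            edits.append((mol.locus_id, pos, alt))
        for pos, _ref, alt in mol.somatic_mutations:
            edits.append((mol.locus_id, pos, alt))
    for locus in panel.loci:
        depth = np.cumsum(cover[locus.locus_id][:-1])
        ref_idx = np.searchsorted(
            BASES, np.frombuffer(locus.sequence.encode(), dtype=np.uint8))
        counts = pile.counts[locus.locus_id]
        counts[np.arange(locus.length), ref_idx] = depth
    for locus_id, pos, alt in edits:
        locus = panel.locus(locus_id)
        counts = pile.counts[locus_id]
        counts[pos, _BASE_INDEX[locus.sequence[pos]]] -= 1
        counts[pos, _BASE_INDEX[alt]] += 1
    return pile


def _context(panel: ReferencePanel, locus_id: str, pos: int) -> str:
    seq = panel.locus(locus_id).sequence
    five = seq[pos - 1] if pos > 0 else "."
    three = seq[pos + 1] if pos + 1 < len(seq) else "."
    return f"{five}{seq[pos]}{three}"


def call_mutations(
    sites: Iterable[DuplexPileupSite],
    panel: ReferencePanel,
    vaf_threshold: float = 0.01,
) -> list[MutationCall]:
    """Emit somatic mutation calls from variant pileup sites.

    Every (site, alt allele) with VAF strictly below ``vaf_threshold`` is
    one call; alleles at or above the threshold are treated as inherited
    polymorphisms and dropped. Multi-allelic sites yield one potential
    call per alt allele.
    """
    if not (0.0 < vaf_threshold <= 1.0):
        raise ValueError("vaf_threshold must lie in (0, 1]")
    calls = []
    for site in sites:
        if site.depth == 0:
            if site.alt_counts:
                raise RuntimeError(
                    f"zero-depth site with alt bases at "
                    f"{site.locus_id}:{site.position}")
            continue
        for alt, count in sorted(site.alt_counts.items()):
            if count == 0:
                continue
            if count / site.depth < vaf_threshold:
                calls.append(MutationCall(
                    locus_id=site.locus_id,
                    position=site.position,
                    ref=site.ref,
                    alt=alt,
                    alt_count=count,
                    depth=site.depth,
                    context=_context(panel, site.locus_id, site.position),
                ))
    return calls


def count_unique_mutations(
    calls: Iterable[MutationCall],
    mode: Literal["unique", "molecules"] = "unique",
) -> int:
    """Number of mutations in a call set.

    ``unique`` counts each distinct (locus, position, alt) once per
    sample regardless of how many duplex molecules carry it (clonal
    copies de-duplicated); ``molecules`` sums supporting molecule counts.
    """
    if mode == "unique":
        return len({(c.locus_id, c.position, c.alt) for c in calls})
    if mode == "molecules":
        seen: dict[tuple, int] = {}
        for c in calls:
            seen[(c.locus_id, c.position, c.alt)] = c.alt_count
        return sum(seen.values())
    raise ValueError(f"unknown counting mode {mode!r}")


def mutant_frequency(mutation_count: int, total_duplex_bases: int) -> float:
    """Unique mutations per non-ambiguous duplex base."""
    if total_duplex_bases <= 0:
        raise ValueError("total duplex bases must be positive")
    if mutation_count < 0:
        raise ValueError("mutation count must be non-negative")
    return mutation_count / total_duplex_bases


def format_mf_e7(mf: float) -> str:
    """Display convention: two decimals on the x1e-7 scale,
    half-away-from-zero rounding."""
    return str(Decimal(mf * 1e7).quantize(Decimal("0.01"), ROUND_HALF_UP))


def wilson_interval(
    successes: int, trials: int, confidence: float = 0.95,
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie in (0, 1)")
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not (0 <= successes <= trials):
        raise ValueError("successes must lie in [0, trials]")
    lower, upper = proportion_confint(
        successes, trials, alpha=1 - confidence, method="wilson")
    # The score bounds are analytically exact at the extremes; snap them
    # to remove floating-point spill.
    lower = 0.0 if successes == 0 else max(0.0, float(lower))
    upper = 1.0 if successes == trials else min(1.0, float(upper))
    return lower, upper


def sample_result(
    sample_id: str,
    mutation_count: int,
    total_duplex_bases: int,
    confidence: float = 0.95,
) -> SampleMutationResult:
    mf = mutant_frequency(mutation_count, total_duplex_bases)
    lo, hi = wilson_interval(mutation_count, total_duplex_bases, confidence)
    return SampleMutationResult(
        sample_id=sample_id,
        total_duplex_bases=total_duplex_bases,
        mutation_count=mutation_count,
        mutant_frequency=mf,
        ci_lower=lo,
        ci_upper=hi,
        confidence=confidence,
    )


def group_mean_mf(
    frequencies: Sequence[float],
    mode: Literal["arithmetic", "pooled"] = "arithmetic",
    counts: Sequence[int] | None = None,
    bases: Sequence[int] | None = None,
) -> tuple[float, float]:
    """Group summary (mean, SD) of replicate mutant frequencies.

    ``arithmetic`` averages the replicate frequencies (sample SD, ddof=1;
    SD 0 for a single replicate). ``pooled`` divides summed mutation
    counts by summed duplex bases, which weights replicates by their
    sequencing yield; it needs ``counts`` and ``bases``.
    """
    if mode == "pooled":
        if counts is None or bases is None:
            raise ValueError("pooled mode needs counts and bases")
        return sum(counts) / sum(bases), float("nan")
    arr = np.asarray(frequencies, dtype=float)
    if arr.size == 0:
        raise ValueError("at least one replicate required")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def write_calls_tsv(calls: Iterable[MutationCall], path: str | Path) -> None:
    """Minimal VCF-style TSV; POS is 1-based on output."""
    with open(path, "w") as fh:
        fh.write("CHROM\tPOS\tREF\tALT\tDUPLEX_ALT_COUNT\tDUPLEX_DEPTH\tVAF\n")
        for c in calls:
            fh.write(f"{c.locus_id}\t{c.position + 1}\t{c.ref}\t{c.alt}\t"
                     f"{c.alt_count}\t{c.depth}\t{c.vaf:.3e}\n")
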