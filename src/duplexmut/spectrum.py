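"""Pyrimidine-normalized substitution classes and trinucleotide spectra.

Single-nucleotide substitutions are reported with a pyrimidine (C or T)
reference: a purine-reference event is reverse-complemented, alleles and
flanking context alike, giving 6 substitution classes and 96
trinucleotide-context categories. Class proportions between treatment
groups are compared with a two-proportion z-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .mutation_call import MutationCall
from .panel_sim import SUBSTITUTION_CLASSES, ReferencePanel

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = {"C", "T"}

#: All 96 (5' base, class, 3' base) context keys in canonical order.
CONTEXT_KEYS: tuple[tuple[str, str, str], ...] = tuple(
    (five, cls, three)
    for cls in SUBSTITUTION_CLASSES
    for five in "ACGT"
    for three in "ACGT"
)


def normalize_substitution(
    ref: str, alt: str, five_prime: str, three_prime: str,
) -> tuple[str, tuple[str, str]]:
    """Map a substitution to its pyrimidine-normalized class and context.

    Purine-reference events are reverse-complemented: ref, alt and both
    flanks flip, and the flanks swap sides.
    """
    for b in (ref, alt, five_prime, three_prime):
        if b not in "ACGT":
            raise ValueError(f"ambiguous or invalid base {b!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in _PYRIMIDINES:
        return f"{ref}>{alt}", (five_prime, three_prime)
    return (
        f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}",
        (_COMPLEMENT[three_prime], _COMPLEMENT[five_prime]),
    )


@dataclass
class TrinucleotideSpectrum:
    """96-context mutation counts with their 6-class marginal."""

    context_counts: dict[tuple[str, str, str], int] = field(
        default_factory=lambda: {k: 0 for k in CONTEXT_KEYS})
    n_edge_excluded: int = 0

    @property
    def total(self) -> int:
        return sum(self.context_counts.values())

    def class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in SUBSTITUTION_CLASSES}
        for (_, cls, _), n in self.context_counts.items():
            out[cls] += n
        return out

    def class_proportions(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            return {c: 0.0 for c in SUBSTITUTION_CLASSES}
        return {c: n / total for c, n in self.class_counts().items()}

    def context_proportions(self) -> dict[tuple[str, str, str], float]:
        total = self.total
        if total == 0:
            return {k: 0.0 for k in CONTEXT_KEYS}
        return {k: n / total for k, n in self.context_counts.items()}

    def cpg_ct_count(self) -> int:
        """C>T events whose normalized 3' neighbour is G (CpG motif)."""
        return sum(
            n for (_, cls, three), n in self.context_counts.items()
            if cls == "C>T" and three == "G"
        )

    def as_vector(self, proportions: bool = True) -> np.ndarray:
        v = np.array([self.context_counts[k] for k in CONTEXT_KEYS], dtype=float)
        if proportions and v.sum() > 0:
            v = v / v.sum()
        return v

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("context\tclass\tcount\tproportion\n")
            props = self.context_proportions()
            for key in CONTEXT_KEYS:
                five, cls, three = key
                label = f"{five}[{cls}]{three}"
                fh.write(f"{label}\t{cls}\t{self.context_counts[key]}\t"
                         f"{props[key]:.6f}\n")


def build_spectrum(
    calls: Iterable[MutationCall], panel: ReferencePanel,
) -> TrinucleotideSpectrum:
    """Classify calls into the 96 normalized trinucleotide categories.

    Calls at a locus edge, lacking a flanking reference base, are
    excluded from the spectrum and counted in ``n_edge_excluded``.
    """
    spec = TrinucleotideSpectrum()
    for call in calls:
        seq = panel.locus(call.locus_id).sequence
        pos = call.position
        if pos == 0 or pos + 1 >= len(seq):
            spec.n_edge_excluded += 1
            continue
        cls, (five, three) = normalize_substitution(
            call.ref, call.alt, seq[pos - 1], seq[pos + 1])
        spec.context_counts[(five, cls, three)] += 1
    return spec


def panel_context_availability(panel: ReferencePanel) -> dict[str, float]:
    """Availability of mutation opportunities in the panel.

    Returns the fraction of pyrimidine-normalized C sites (reference C or
    G) whose normalized 3' neighbour is G — the CpG opportunity fraction
    a context-blind C>T process would hit by chance.
    """
    c_sites = 0
    cpg_sites = 0
    for locus in panel.loci:
        seq = locus.sequence
        for i in range(1, len(seq) - 1):
            if seq[i] == "C":
                c_sites += 1
                if seq[i + 1] == "G":
                    cpg_sites += 1
            elif seq[i] == "G":
                c_sites += 1
                if seq[i - 1] == "C":
                    cpg_sites += 1
    return {
        "c_sites": float(c_sites),
        "cpg_sites": float(cpg_sites),
        "cpg_fraction": cpg_sites / c_sites if c_sites else 0.0,
    }


def compare_class_proportion(
    spectrum_a: TrinucleotideSpectrum,
    spectrum_b: TrinucleotideSpectrum,
    sub_class: str,
) -> tuple[float, float, float]:
    """Two-proportion z-test on one class's share of all mutations.

    Returns (difference a-b, z statistic, two-sided p).
    """
    n_a, n_b = spectrum_a.total, spectrum_b.total
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups need at least one classified mutation")
    x_a = spectrum_a.class_counts()[sub_class]
    x_b = spectrum_b.class_counts()[sub_class]
    p_a, p_b = x_a / n_a, x_b / n_b
    pooled = (x_a + x_b) / (n_a + n_b)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n_a + 1 / n_b))
    if se == 0:
        return p_a - p_b, 0.0, 1.0
    z = (p_a - p_b) / se
    p = 2 * stats.norm.sf(abs(z))
    return p_a - p_b, float(z), float(p)


def cosine_similarity(
    spec_a: TrinucleotideSpectrum | np.ndarray,
    spec_b: TrinucleotideSpectrum | np.ndarray,
) -> float:
    """Cosine similarity of two spectra (1 = proportional)."""
    a = spec_a.as_vector() if isinstance(spec_a, TrinucleotideSpectrum) else np.asarray(spec_a, float)
    b = spec_b.as_vector() if isinstance(spec_b, TrinucleotideSpectrum) else np.asarray(spec_b, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero spectrum")
    return float(np.dot(a, b) / (na * nb))
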