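"""Synthetic hybrid-capture panel and duplex-sequencing read simulator.

Emulates the measurement design of a duplex-sequencing mutagenesis assay:
a genome-representative capture panel (by default twenty 2.4-kb loci,
48 kb of territory), double-stranded source molecules carrying inherited
heterozygous variants (VAF ~0.5) and a programmed somatic mutation load
with a chosen substitution spectrum, and tagged reads from both strands
of each molecule with PCR- and sequencing-error processes.

Every downstream stage (consensus calling, mutation calling, spectra,
dose-response statistics) is exercised against the truth tables this
module records, so the whole pipeline is testable without any external
data download.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
BASE_STR = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Six pyrimidine-normalized single-nucleotide substitution classes.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Default class weights emulating an alkylating-agent exposure:
#: C>T dominant, spread uniformly over trinucleotide contexts.
EMS_LIKE_WEIGHTS = {
    "C>A": 0.06, "C>G": 0.06, "C>T": 0.70, "T>A": 0.06, "T>C": 0.06, "T>G": 0.06,
}

#: Default class weights emulating an unexposed (ageing) background:
#: moderate C>T share, concentrated at CpG dinucleotides (spontaneous
#: deamination of 5-methylcytosine).
CONTROL_LIKE_WEIGHTS = {
    "C>A": 0.10, "C>G": 0.08, "C>T": 0.45, "T>A": 0.10, "T>C": 0.17, "T>G": 0.10,
}

#: Fraction of control-like C>T events that are forced into CpG context.
CONTROL_LIKE_CPG_FRACTION = 0.7


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class PanelLocus:
    """One capture-panel target interval with its reference sequence."""

    locus_id: str
    contig_name: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"{self.locus_id}: interval length {self.end - self.start} "
                f"!= sequence length {len(self.sequence)}"
            )
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.locus_id}: sequence alphabet must be ACGT")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReferencePanel:
    """Ordered collection of panel loci; the denominator territory."""

    loci: tuple[PanelLocus, ...]

    def __post_init__(self) -> None:
        ids = [l.locus_id for l in self.loci]
        if len(ids) != len(set(ids)):
            raise ValueError("locus_id values must be unique within the panel")

    @property
    def total_territory(self) -> int:
        return sum(l.length for l in self.loci)

    def locus(self, locus_id: str) -> PanelLocus:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)

    def write_fasta(self, path: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(l.sequence), id=l.locus_id, description="")
            for l in self.loci
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for l in self.loci:
                fh.write(f"{l.contig_name}\t{l.start}\t{l.end}\t{l.locus_id}\n")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "ReferencePanel":
        from Bio import SeqIO

        loci = []
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            loci.append(PanelLocus(rec.id, rec.id, 0, len(seq), seq))
        return cls(tuple(loci))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults mirroring the
    emulated assay design: 20 loci x 2,400 bp, human-like 41% GC,
    fragment sizes around 300 bp, and a germline heterozygote load that
    the 1% VAF filter must remove.

    ``duplex_depth`` is the target mean number of duplex source molecules
    covering a panel position, before strand-family dropout.
    """

    n_loci: int = 20
    locus_length: int = 2400
    gc_fraction: float = 0.41
    cpg_weight: float = 1.0
    duplex_depth: float = 50.0
    fragment_length_mean: float = 300.0
    fragment_length_sd: float = 30.0
    reads_per_strand_mean: float = 3.0
    seq_error_rate: float = 1e-3
    pcr_error_rate: float = 1e-5
    n_germline_hets: int = 20
    germline_vaf: float = 0.5
    true_mutant_frequency: float = 0.0
    spectrum_mode: str = "ems_like"
    spectrum_weights: dict[str, float] | None = None
    cpg_ct_fraction: float | None = None
    umi_length: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_fraction < 1.0):
            raise ConfigurationError("gc_fraction must lie in (0, 1)")
        for name in ("seq_error_rate", "pcr_error_rate", "germline_vaf",
                     "true_mutant_frequency"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("n_loci", "locus_length", "umi_length"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.spectrum_mode not in ("ems_like", "control_like", "custom"):
            raise ConfigurationError(f"unknown spectrum_mode {self.spectrum_mode!r}")
        if self.spectrum_mode == "custom" and self.spectrum_weights is None:
            raise ConfigurationError("custom spectrum_mode needs spectrum_weights")

    def class_weights(self) -> dict[str, float]:
        if self.spectrum_weights is not None:
            w = dict(self.spectrum_weights)
        elif self.spectrum_mode == "ems_like":
            w = dict(EMS_LIKE_WEIGHTS)
        else:
            w = dict(CONTROL_LIKE_WEIGHTS)
        total = sum(w.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ConfigurationError("spectrum_weights must sum to 1")
        if set(w) != set(SUBSTITUTION_CLASSES):
            raise ConfigurationError("spectrum_weights must key the 6 classes")
        return w

    def cpg_fraction(self) -> float:
        """Fraction of C>T events placed specifically at CpG sites."""
        if self.cpg_ct_fraction is not None:
            return self.cpg_ct_fraction
        return CONTROL_LIKE_CPG_FRACTION if self.spectrum_mode == "control_like" else 0.0


@dataclass
class SourceMolecule:
    """A ground-truth double-stranded DNA fragment before amplification."""

    molecule_id: str
    locus_id: str
    start: int
    end: int
    umi_pair: tuple[str, str]
    haplotype: int
    germline_alleles: dict[int, str] = field(default_factory=dict)
    somatic_mutations: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimulatedRead:
    """One sequencing read, oriented to the reference strand.

    The strand of origin is encoded redundantly: in the ``strand`` label
    and in the order of ``umi_pair`` (top-strand reads present the tags
    as (tagA, tagB), bottom-strand reads as (tagB, tagA)).
    """

    read_id: str
    locus_id: str
    start: int
    end: int
    umi_pair: tuple[str, str]
    strand: str  # "top" | "bottom"
    sequence: str
    quality: str = ""

    def __post_init__(self) -> None:
        if not self.quality:
            self.quality = "I" * len(self.sequence)


@dataclass
class TruthSet:
    """Programmed ground truth accompanying a simulated read set."""

    germline_variants: list[tuple[str, int, str, str, float]]
    somatic_truth: list[tuple[str, str, int, str, str]]
    programmed_mf: float
    total_molecule_bases: int

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#programmed_mf\t{self.programmed_mf!r}\n")
            fh.write(f"#total_molecule_bases\t{self.total_molecule_bases}\n")
            for locus, pos, ref, alt, vaf in self.germline_variants:
                fh.write(f"germline\t{locus}\t{pos}\t{ref}\t{alt}\t{vaf!r}\n")
            for mol, locus, pos, ref, alt in self.somatic_truth:
                fh.write(f"somatic\t{mol}\t{locus}\t{pos}\t{ref}\t{alt}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthSet":
        germ: list = []
        som: list = []
        mf = 0.0
        total = 0
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "#programmed_mf":
                    mf = float(parts[1])
                elif parts[0] == "#total_molecule_bases":
                    total = int(parts[1])
                elif parts[0] == "germline":
                    germ.append((parts[1], int(parts[2]), parts[3], parts[4],
                                 float(parts[5])))
                elif parts[0] == "somatic":
                    som.append((parts[1], parts[2], int(parts[3]), parts[4],
                                parts[5]))
        return cls(germ, som, mf, total)


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------

def generate_panel(config: SimulationConfig) -> ReferencePanel:
    """Generate a synthetic reference panel.

    Sequences are drawn from a first-order Markov chain whose stationary
    composition follows ``gc_fraction`` and whose C->G transition is
    multiplied by ``cpg_weight``, so CpG dinucleotide density can be
    enriched (weight > 1) or depleted (weight < 1) relative to
    independence. Deterministic for a fixed ``rng_seed``.
    """
    if config.locus_length < 10:
        raise ConfigurationError("locus_length must be >= 10")
    rng = np.random.default_rng(config.rng_seed)
    base_p = np.array([
        (1 - config.gc_fraction) / 2, config.gc_fraction / 2,
        config.gc_fraction / 2, (1 - config.gc_fraction) / 2,
    ])
    # Per-previous-base transition rows; only the C row is reweighted.
    trans = np.tile(base_p, (4, 1))
    c_row = base_p.copy()
    c_row[2] *= config.cpg_weight  # index 2 == G
    trans[1] = c_row / c_row.sum()
    cum = np.cumsum(trans, axis=1)

    loci = []
    for i in range(config.n_loci):
        u = rng.random(config.locus_length)
        seq_idx = np.empty(config.locus_length, dtype=np.int64)
        seq_idx[0] = np.searchsorted(np.cumsum(base_p), u[0])
        prev = seq_idx[0]
        row = cum
        for j in range(1, config.locus_length):
            prev = int(np.searchsorted(row[prev], u[j]))
            seq_idx[j] = prev
        seq = "".join(BASE_STR[k] for k in seq_idx)
        locus_id = f"locus{i + 1:02d}"
        loci.append(PanelLocus(locus_id, locus_id, 0, config.locus_length, seq))
    return ReferencePanel(tuple(loci))


# ---------------------------------------------------------------------------
# Molecule simulation
# ---------------------------------------------------------------------------

def _site_catalogue(panel: ReferencePanel):
    """Per-locus index arrays of pyrimidine-normalized C and T sites and
    the CpG subset (C followed by G, or G preceded by C)."""
    catalogue = {}
    for locus in panel.loci:
        arr = np.frombuffer(locus.sequence.encode(), dtype=np.uint8)
        is_c = (arr == ord("C")) | (arr == ord("G"))
        is_t = (arr == ord("T")) | (arr == ord("A"))
        cpg = np.zeros(len(arr), dtype=bool)
        c_mask = arr == ord("C")
        g_mask = arr == ord("G")
        cpg[:-1] |= c_mask[:-1] & g_mask[1:]   # C of a CG
        cpg[1:] |= g_mask[1:] & c_mask[:-1]    # G of a CG (bottom-strand C)
        catalogue[locus.locus_id] = {
            "C": np.flatnonzero(is_c),
            "T": np.flatnonzero(is_t),
            "CpG": np.flatnonzero(cpg),
        }
    return catalogue


def _alt_for(ref: str, sub_class: str) -> str:
    """Alt allele on the reference strand for a pyrimidine-normalized class."""
    pyr, alt = sub_class.split(">")
    if ref == pyr:
        return alt
    if ref == _COMPLEMENT[pyr]:
        return _COMPLEMENT[alt]
    raise ValueError(f"reference base {ref} incompatible with class {sub_class}")


def _draw_umi(rng: np.random.Generator, k: int) -> str:
    return BASES[rng.integers(0, 4, size=k)].tobytes().decode()


def _draw_umis(rng: np.random.Generator, n: int, k: int) -> list[str]:
    """Vectorized batch of n random fixed-length tags."""
    arr = BASES[rng.integers(0, 4, size=(n, k))]
    return [row.tobytes().decode() for row in np.ascontiguousarray(arr)]


def simulate_molecules(
    panel: ReferencePanel, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[SourceMolecule], TruthSet]:
    """Draw double-stranded source molecules with germline and somatic
    variants programmed in.

    The number of molecules targets ``duplex_depth`` x territory /
    fragment_length_mean. Somatic events are Poisson with expectation
    ``true_mutant_frequency`` x total molecule bases; each event picks a
    substitution class from the configured spectrum, then a compatible
    reference site within one molecule (CpG-constrained for the
    configured fraction of C>T events). Germline heterozygotes occupy
    distinct panel sites; a site collision triggers a re-draw.
    """
    if not panel.loci:
        raise ValueError("panel must be non-empty")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)

    territory = panel.total_territory
    n_molecules = max(1, int(round(
        config.duplex_depth * territory / config.fragment_length_mean)))

    locus_lengths = np.array([l.length for l in panel.loci], dtype=float)
    locus_p = locus_lengths / locus_lengths.sum()
    locus_idx = rng.choice(len(panel.loci), size=n_molecules, p=locus_p)
    frag_len = np.clip(
        np.round(rng.normal(config.fragment_length_mean,
                            config.fragment_length_sd, n_molecules)),
        10, None).astype(np.int64)
    frag_len = np.minimum(frag_len, locus_lengths[locus_idx].astype(np.int64))
    max_start = locus_lengths[locus_idx].astype(np.int64) - frag_len
    starts = (rng.random(n_molecules) * (max_start + 1)).astype(np.int64)
    haplotypes = (rng.random(n_molecules) < 0.5).astype(np.int64)

    # Germline heterozygous sites: distinct panel positions, re-draw on
    # collision; each tied to one haplotype at VAF 0.5, otherwise an
    # independent per-molecule carrier draw at the programmed VAF.
    germline: list[tuple[str, int, str, str, float]] = []
    germ_hap: dict[tuple[str, int], int] = {}
    taken: set[tuple[str, int]] = set()
    while len(germline) < config.n_germline_hets:
        li = int(rng.choice(len(panel.loci), p=locus_p))
        locus = panel.loci[li]
        pos = int(rng.integers(0, locus.length))
        key = (locus.locus_id, pos)
        if key in taken:
            continue
        taken.add(key)
        ref = locus.sequence[pos]
        alt = rng.choice([b for b in BASE_STR if b != ref])
        germline.append((locus.locus_id, pos, ref, str(alt), config.germline_vaf))
        germ_hap[key] = int(rng.integers(0, 2))

    all_tags = _draw_umis(rng, 2 * n_molecules, config.umi_length)
    molecules: list[SourceMolecule] = []
    for i in range(n_molecules):
        locus = panel.loci[locus_idx[i]]
        start = int(starts[i])
        end = start + int(frag_len[i])
        tag_a = all_tags[2 * i]
        tag_b = all_tags[2 * i + 1]
        mol = SourceMolecule(
            molecule_id=f"m{i:07d}",
            locus_id=locus.locus_id,
            start=start,
            end=end,
            umi_pair=(tag_a, tag_b),
            haplotype=int(haplotypes[i]),
        )
        molecules.append(mol)

    # Germline carriers: one pass over molecules, hets indexed by locus.
    use_hap_rule = abs(config.germline_vaf - 0.5) < 1e-9
    hets_by_locus: dict[str, list[tuple[int, str, int, float]]] = {}
    for locus_id, pos, _ref, alt, vaf in germline:
        hets_by_locus.setdefault(locus_id, []).append(
            (pos, alt, germ_hap[(locus_id, pos)], vaf))
    for mol in molecules:
        for pos, alt, hap, vaf in hets_by_locus.get(mol.locus_id, ()):
            if not (mol.start <= pos < mol.end):
                continue
            carrier = (mol.haplotype == hap) if use_hap_rule \
                else (rng.random() < vaf)
            if carrier:
                mol.germline_alleles[pos] = alt

    # Somatic mutations.
    total_bases = int(frag_len.sum())
    somatic: list[tuple[str, str, int, str, str]] = []
    if config.true_mutant_frequency > 0:
        catalogue = _site_catalogue(panel)
        weights = config.class_weights()
        classes = list(weights)
        class_p = np.array([weights[c] for c in classes])
        cpg_frac = config.cpg_fraction()
        n_events = int(rng.poisson(config.true_mutant_frequency * total_bases))
        mol_p = frag_len / frag_len.sum()
        germ_sites = set(taken)
        attempts = 0
        placed = 0
        while placed < n_events and attempts < 50 * n_events + 1000:
            attempts += 1
            mi = int(rng.choice(n_molecules, p=mol_p))
            mol = molecules[mi]
            sub_class = classes[int(rng.choice(len(classes), p=class_p))]
            pyr = sub_class.split(">")[0]
            cat = catalogue[mol.locus_id]
            if sub_class == "C>T" and rng.random() < cpg_frac:
                pool = cat["CpG"]
            else:
                pool = cat[pyr]
            pool = pool[(pool >= mol.start) & (pool < mol.end)]
            if pool.size == 0:
                continue
            pos = int(pool[int(rng.integers(0, pool.size))])
            if (mol.locus_id, pos) in germ_sites:
                continue
            if any(p == pos for p, _, _ in mol.somatic_mutations):
                continue
            ref = panel.locus(mol.locus_id).sequence[pos]
            alt = _alt_for(ref, sub_class)
            mol.somatic_mutations.append((pos, ref, alt))
            somatic.append((mol.molecule_id, mol.locus_id, pos, ref, alt))
            placed += 1

    truth = TruthSet(
        germline_variants=germline,
        somatic_truth=somatic,
        programmed_mf=config.true_mutant_frequency,
        total_molecule_bases=total_bases,
    )
    return molecules, truth


def molecule_sequence(mol: SourceMolecule, panel: ReferencePanel) -> str:
    """Top-strand sequence of a molecule with its variants applied."""
    locus = panel.locus(mol.locus_id)
    seq = np.frombuffer(
        locus.sequence[mol.start:mol.end].encode(), dtype=np.uint8).copy()
    for pos, alt in mol.germline_alleles.items():
        seq[pos - mol.start] = ord(alt)
    for pos, _ref, alt in mol.somatic_mutations:
        seq[pos - mol.start] = ord(alt)
    return seq.tobytes().decode()


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _inject_errors(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Return a copy of ``seq`` with substitution errors at ``rate``."""
    out = seq.copy()
    n_err = rng.binomial(len(seq), rate)
    if n_err:
        pos = rng.choice(len(seq), size=n_err, replace=False)
        # Shift each hit base by 1-3 positions in the base alphabet.
        cur = np.searchsorted(BASES, out[pos])
        out[pos] = BASES[(cur + rng.integers(1, 4, size=n_err)) % 4]
    return out


def simulate_reads(
    molecules: Sequence[SourceMolecule],
    panel: ReferencePanel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[SimulatedRead]:
    """Emit tagged reads from both strands of each molecule.

    Per-strand family sizes are Poisson(``reads_per_strand_mean``) and may
    be zero. PCR errors are applied once per strand lineage (shared by
    every read of that strand); sequencing errors are applied
    independently per read base. All reads are reported in reference
    orientation; the strand of origin survives only in the tag order.
    """
    if not molecules:
        raise ValueError("no molecules to sequence")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 2)

    reads: list[SimulatedRead] = []
    for mol in molecules:
        base_seq = np.frombuffer(
            molecule_sequence(mol, panel).encode(), dtype=np.uint8)
        for strand in ("top", "bottom"):
            n_reads = int(rng.poisson(config.reads_per_strand_mean))
            if n_reads == 0:
                continue
            strand_template = _inject_errors(base_seq, config.pcr_error_rate, rng)
            tags = mol.umi_pair if strand == "top" else mol.umi_pair[::-1]
            for r in range(n_reads):
                read_seq = _inject_errors(strand_template,
                                          config.seq_error_rate, rng)
                reads.append(SimulatedRead(
                    read_id=f"{mol.molecule_id}.{strand[0]}{r}:"
                            f"{tags[0]}+{tags[1]}:{strand}",
                    locus_id=mol.locus_id,
                    start=mol.start,
                    end=mol.end,
                    umi_pair=tags,
                    strand=strand,
                    sequence=read_seq.tobytes().decode(),
                ))
    return reads


# ---------------------------------------------------------------------------
# FASTQ round trip
# ---------------------------------------------------------------------------

def write_fastq(reads: Iterable[SimulatedRead], path: str | Path) -> None:
    """Write reads as plain FASTQ; panel coordinates ride in the
    description so no aligner is needed downstream."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} locus={r.locus_id} start={r.start} "
                     f"end={r.end}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[SimulatedRead]:
    """Reload reads written by :func:`write_fastq`."""
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ record: {header!r}")
            name, _, desc = header[1:].partition(" ")
            fields = dict(kv.split("=", 1) for kv in desc.split())
            parts = name.split(":")
            if len(parts) != 3 or "+" not in parts[1]:
                raise ValueError(f"malformed read identifier: {name!r}")
            tag_a, tag_b = parts[1].split("+", 1)
            reads.append(SimulatedRead(
                read_id=name,
                locus_id=fields["locus"],
                start=int(fields["start"]),
                end=int(fields["end"]),
                umi_pair=(tag_a, tag_b),
                strand=parts[2],
                sequence=seq,
                quality=qual,
            ))
    return reads


def write_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1)


def read_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig(**json.load(fh))
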