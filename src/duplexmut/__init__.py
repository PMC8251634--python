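"""duplexmut: duplex-sequencing mutagenesis and comet-assay genotoxicity
analysis on synthetic airway-culture data.

The package implements, end to end and against programmed ground truth:

* a synthetic capture panel (twenty 2.4-kb loci by default) and a
  duplex-sequencing read simulator with germline heterozygotes, a
  programmed somatic mutation load/spectrum, and PCR/sequencing error
  processes (:mod:`duplexmut.panel_sim`);
* strand-aware read grouping and duplex consensus calling
  (:mod:`duplexmut.duplex_consensus`);
* mutation calling with VAF-based germline exclusion and per-sample
  mutant frequency with Wilson intervals (:mod:`duplexmut.mutation_call`);
* pyrimidine-normalized trinucleotide mutation spectra
  (:mod:`duplexmut.spectrum`);
* linear trend / ANOVA / Monte-Carlo Dunnett dose-response statistics
  (:mod:`duplexmut.dose_response`);
* a synthetic comet-chip %DNA-in-Tail scorer (:mod:`duplexmut.comet`).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import (comet, datasets, dose_response, duplex_consensus,
               mutation_call, panel_sim, spectrum)
from .duplex_consensus import call_duplexes, group_reads, tabulate_duplex_depth
from .mutation_call import (MutationCall, SampleMutationResult, call_mutations,
                            count_unique_mutations, group_mean_mf,
                            mutant_frequency, pileup, pileup_from_molecules,
                            sample_result, wilson_interval)
from .panel_sim import (ReferencePanel, SimulationConfig, TruthSet,
                        generate_panel, simulate_molecules, simulate_reads)

__version__ = "0.1.0"


@dataclass(frozen=True)
class PipelineOutput:
    """Everything one simulated sample produces on its way to a mutant
    frequency."""

    panel: ReferencePanel
    truth: TruthSet
    n_reads: int
    n_duplexes: int
    total_duplex_bases: int
    calls: tuple[MutationCall, ...]
    result: SampleMutationResult


def run_sample(
    config: SimulationConfig,
    sample_id: str = "sample",
    panel: ReferencePanel | None = None,
    min_reads: int = 2,
    agreement: float = 0.9,
    vaf_threshold: float = 0.01,
) -> PipelineOutput:
    """Simulate one sample and push it through the full pipeline:
    molecules -> tagged reads -> read families -> duplex consensus ->
    pileup -> VAF-filtered mutation calls -> mutant frequency with its
    Wilson interval."""
    if panel is None:
        panel = generate_panel(config)
    molecules, truth = simulate_molecules(panel, config)
    reads = simulate_reads(molecules, panel, config)
    duplexes = call_duplexes(reads, min_reads=min_reads, agreement=agreement)
    pile = pileup(duplexes, panel)
    calls = call_mutations(pile.variant_sites(), panel,
                           vaf_threshold=vaf_threshold)
    total = pile.total_bases()
    n_mut = count_unique_mutations(calls)
    return PipelineOutput(
        panel=panel,
        truth=truth,
        n_reads=len(reads),
        n_duplexes=len(duplexes),
        total_duplex_bases=total,
        calls=tuple(calls),
        result=sample_result(sample_id, n_mut, total),
    )


def run_sample_exact(
    config: SimulationConfig,
    sample_id: str = "sample",
    panel: ReferencePanel | None = None,
    vaf_threshold: float = 0.01,
) -> PipelineOutput:
    """Molecule-level variant of :func:`run_sample` that skips read
    simulation and consensus: each molecule stands in for its own duplex
    consensus, which is exact when error rates are zero and family sizes
    clear the consensus thresholds. Used for large calibration studies."""
    if panel is None:
        panel = generate_panel(config)
    molecules, truth = simulate_molecules(panel, config)
    pile = pileup_from_molecules(molecules, panel)
    calls = call_mutations(pile.variant_sites(), panel,
                           vaf_threshold=vaf_threshold)
    total = pile.total_bases()
    n_mut = count_unique_mutations(calls)
    return PipelineOutput(
        panel=panel,
        truth=truth,
        n_reads=0,
        n_duplexes=len(molecules),
        total_duplex_bases=total,
        calls=tuple(calls),
        result=sample_result(sample_id, n_mut, total),
    )
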