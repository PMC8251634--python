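"""Simulator: panel geometry, programmed variant loads, error processes,
and file round-trips, each checked against an independent oracle."""

import numpy as np
import pytest

from duplexmut import SimulationConfig, generate_panel, simulate_molecules
from duplexmut.panel_sim import (ConfigurationError, SourceMolecule,
                                 TruthSet, molecule_sequence, read_fastq,
                                 simulate_reads, write_fastq)


class TestGeneratePanel:
    def test_default_geometry_is_20_loci_of_2400bp(self, default_panel):
        assert len(default_panel.loci) == 20
        assert all(l.length == 2400 for l in default_panel.loci)
        assert default_panel.total_territory == 48_000

    def test_single_minimal_locus(self):
        panel = generate_panel(SimulationConfig(n_loci=1, locus_length=10))
        assert len(panel.loci) == 1
        assert panel.loci[0].end - panel.loci[0].start == 10

    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(n_loci=2, locus_length=300, rng_seed=5)
        a = generate_panel(cfg)
        b = generate_panel(cfg)
        assert [l.sequence for l in a.loci] == [l.sequence for l in b.loci]

    def test_invalid_gc_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(gc_fraction=1.5)

    def test_cpg_weight_enriches_cpg_dinucleotides(self):
        # Independent oracle: direct string count of CG dinucleotides,
        # compared with the expected count under the generating Markov
        # chain (stationary C frequency x reweighted C->G transition).
        L = 100_000
        counts = {}
        for w in (1.0, 3.0):
            cfg = SimulationConfig(n_loci=1, locus_length=L, gc_fraction=0.5,
                                   cpg_weight=w, rng_seed=9)
            seq = generate_panel(cfg).loci[0].sequence
            counts[w] = seq.count("CG")
            # expected CG rate: pi_C * P(G|C) from the chain itself
            p = np.array([0.25, 0.25, 0.25, 0.25])
            trans = np.tile(p, (4, 1))
            row = p.copy()
            row[2] *= w
            trans[1] = row / row.sum()
            evals, evecs = np.linalg.eig(trans.T)
            pi = np.real(evecs[:, np.argmin(np.abs(evals - 1))])
            pi = pi / pi.sum()
            expect = pi[1] * trans[1, 2] * L
            assert abs(counts[w] - expect) < 4 * np.sqrt(expect)
        assert counts[3.0] > counts[1.0]


class TestSimulateMolecules:
    def test_zero_mutant_frequency_gives_empty_somatic_truth(self, small_panel,
                                                             small_config):
        _, truth = simulate_molecules(small_panel, small_config)
        assert truth.somatic_truth == []

    def test_somatic_count_follows_poisson_oracle(self, default_panel):
        cfg = SimulationConfig(duplex_depth=100, true_mutant_frequency=2e-5,
                               n_germline_hets=0, rng_seed=13)
        _, truth = simulate_molecules(default_panel, cfg)
        lam = 2e-5 * truth.total_molecule_bases
        assert abs(len(truth.somatic_truth) - lam) < 4 * np.sqrt(lam)

    def test_germline_molecular_fraction_matches_binomial_oracle(
            self, default_panel):
        cfg = SimulationConfig(duplex_depth=200, n_germline_hets=10,
                               germline_vaf=0.5, rng_seed=17)
        molecules, truth = simulate_molecules(default_panel, cfg)
        assert len(truth.germline_variants) == 10
        for locus_id, pos, _ref, alt, _vaf in truth.germline_variants:
            covering = [m for m in molecules
                        if m.locus_id == locus_id and m.start <= pos < m.end]
            carriers = sum(1 for m in covering
                           if m.germline_alleles.get(pos) == alt)
            n = len(covering)
            assert n > 0
            assert abs(carriers / n - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_germline_sites_are_distinct(self, default_panel):
        cfg = SimulationConfig(n_germline_hets=50, rng_seed=3)
        _, truth = simulate_molecules(default_panel, cfg)
        sites = [(l, p) for l, p, *_ in truth.germline_variants]
        assert len(sites) == len(set(sites))

    def test_somatic_positions_lie_within_their_molecule(self, default_panel):
        cfg = SimulationConfig(duplex_depth=30, true_mutant_frequency=1e-5,
                               rng_seed=23)
        molecules, truth = simulate_molecules(default_panel, cfg)
        by_id = {m.molecule_id: m for m in molecules}
        for mol_id, locus, pos, ref, alt in truth.somatic_truth:
            mol = by_id[mol_id]
            assert mol.locus_id == locus
            assert mol.start <= pos < mol.end
            assert default_panel.locus(locus).sequence[pos] == ref
            assert ref != alt


class TestSimulateReads:
    def test_error_free_reads_match_reference(self, small_panel):
        cfg = SimulationConfig(n_loci=4, locus_length=600, duplex_depth=10,
                               seq_error_rate=0, pcr_error_rate=0,
                               n_germline_hets=0, rng_seed=31)
        molecules, _ = simulate_molecules(small_panel, cfg)
        reads = simulate_reads(molecules, small_panel, cfg)
        assert reads
        for r in reads[:200]:
            ref = small_panel.locus(r.locus_id).sequence[r.start:r.end]
            assert r.sequence == ref

    def test_family_size_distribution_oracle(self, small_panel):
        cfg = SimulationConfig(duplex_depth=40, reads_per_strand_mean=3.0,
                               n_germline_hets=0, rng_seed=37)
        molecules, _ = simulate_molecules(small_panel, cfg)
        reads = simulate_reads(molecules, small_panel, cfg)
        # mean reads per strand lineage over 2x n_molecules lineages
        n_lineages = 2 * len(molecules)
        mean = len(reads) / n_lineages
        assert abs(mean - 3.0) < 4 * np.sqrt(3.0 / n_lineages)

    def test_somatic_variant_propagates_to_both_strands(self, toy_panel):
        mol = SourceMolecule("m0000001", "locusA", 0, 24,
                             ("AAAAACCCCC", "GGGGGTTTTT"), 0,
                             somatic_mutations=[(3, "T", "A")])
        cfg = SimulationConfig(n_loci=1, locus_length=24,
                               seq_error_rate=0, pcr_error_rate=0,
                               reads_per_strand_mean=4, rng_seed=5)
        reads = simulate_reads([mol], toy_panel, cfg)
        strands = {r.strand for r in reads}
        assert strands == {"top", "bottom"}
        for r in reads:
            assert r.sequence[3] == "A"

    def test_tag_orientation_encodes_strand(self, toy_panel):
        mol = SourceMolecule("m0000001", "locusA", 0, 24,
                             ("AAAAACCCCC", "GGGGGTTTTT"), 0)
        cfg = SimulationConfig(n_loci=1, locus_length=24,
                               reads_per_strand_mean=5, rng_seed=6)
        reads = simulate_reads([mol], toy_panel, cfg)
        for r in reads:
            if r.strand == "top":
                assert r.umi_pair == ("AAAAACCCCC", "GGGGGTTTTT")
            else:
                assert r.umi_pair == ("GGGGGTTTTT", "AAAAACCCCC")

    def test_molecule_sequence_applies_variants(self, toy_panel):
        mol = SourceMolecule("m1", "locusB", 2, 12, ("A" * 10, "C" * 10), 1,
                             germline_alleles={5: "A"},
                             somatic_mutations=[(8, "G", "T")])
        seq = molecule_sequence(mol, toy_panel)
        ref = toy_panel.locus("locusB").sequence[2:12]
        assert seq[5 - 2] == "A"
        assert seq[8 - 2] == "T"
        assert all(seq[i] == ref[i] for i in range(10) if i not in (3, 6))


class TestRoundTrips:
    def test_fastq_round_trip(self, tmp_path, small_panel):
        cfg = SimulationConfig(duplex_depth=5, rng_seed=41)
        molecules, _ = simulate_molecules(small_panel, cfg)
        reads = simulate_reads(molecules[:50], small_panel, cfg)
        path = tmp_path / "reads.fastq"
        write_fastq(reads, path)
        back = read_fastq(path)
        assert back == reads

    def test_truth_round_trip(self, tmp_path, default_panel):
        cfg = SimulationConfig(duplex_depth=20, true_mutant_frequency=1e-5,
                               n_germline_hets=5, rng_seed=43)
        _, truth = simulate_molecules(default_panel, cfg)
        path = tmp_path / "truth.tsv"
        truth.write_tsv(path)
        back = TruthSet.read_tsv(path)
        assert back == truth

    def test_panel_fasta_bed_round_trip(self, tmp_path, small_panel):
        fasta = tmp_path / "panel.fasta"
        bed = tmp_path / "panel.bed"
        small_panel.write_fasta(fasta)
        small_panel.write_bed(bed)
        from duplexmut.panel_sim import ReferencePanel
        back = ReferencePanel.read_fasta(fasta)
        assert [l.sequence for l in back.loci] == \
               [l.sequence for l in small_panel.loci]
        lines = bed.read_text().splitlines()
        assert len(lines) == len(small_panel.loci)
        assert lines[0].split("\t")[1:3] == ["0", "600"]

    def test_malformed_fastq_identifier_rejected(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@oops locus=l start=0 end=4\nACGT\n+\nIIII\n")
        with pytest.raises(ValueError, match="malformed read identifier"):
            read_fastq(path)
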