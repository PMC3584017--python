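"""The synthetic dataset generator and its truth table."""

import numpy as np
import pytest

from barcodekit.distance import distance_matrix, divergence_summary
from barcodekit.align import Alignment
from barcodekit.qc import overlap_coverage, pair_usable, window_trim
from barcodekit.simulate import (
    SyntheticSpec,
    generate,
    generate_quality_reads,
    write_fastq,
)


def aligned(coll):
    """Indel-free simulated sequences are position-homologous already."""
    return Alignment(coll.locus, coll.sample_ids,
                     [r.residues for r in coll])


class TestGenerate:
    def test_zero_divergence_gives_identical_sequences(self):
        spec = SyntheticSpec(n_genera=1, species_per_genus=3,
                             accessions_per_species=2,
                             locus_lengths={"ITS": 100},
                             inter_divergence=0.0, intra_divergence=0.0,
                             seed=1)
        colls, _ = generate(spec)
        seqs = {r.residues for r in colls["ITS"]}
        assert len(seqs) == 1

    def test_same_seed_reproduces_byte_identical_output(self, tmp_path):
        from barcodekit.io import write_fasta

        spec = SyntheticSpec(seed=123, indel_rate=0.01, ambiguity_rate=0.01)
        for run in ("a", "b"):
            colls, _ = generate(spec)
            for locus, coll in colls.items():
                write_fasta(coll, tmp_path / f"{locus}.{run}.fasta")
        for locus in spec.locus_lengths:
            a = (tmp_path / f"{locus}.a.fasta").read_bytes()
            b = (tmp_path / f"{locus}.b.fasta").read_bytes()
            assert a == b

    def test_intra_below_inter_across_seeds(self):
        # Monte-Carlo: realized mean intra < realized mean inter
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            spec = SyntheticSpec(n_genera=5, species_per_genus=2,
                                 accessions_per_species=3,
                                 locus_lengths={"ITS": 300},
                                 inter_divergence=0.05,
                                 intra_divergence=0.005, seed=seed)
            colls, _ = generate(spec)
            coll = colls["ITS"]
            summ = divergence_summary(distance_matrix(aligned(coll)),
                                      coll.species_of)
            wins += summ.mean_intraspecific < summ.mean_interspecific
        assert wins == n_seeds

    def test_realized_intra_near_twice_branch_rate(self):
        # two accessions each carry ~intra substitutions/site from their
        # shared ancestor: pairwise distance ~ 2 * intra (within 20%)
        rates = []
        for seed in range(10):
            spec = SyntheticSpec(n_genera=2, species_per_genus=2,
                                 accessions_per_species=4,
                                 locus_lengths={"ITS": 800},
                                 inter_divergence=0.05,
                                 intra_divergence=0.01, seed=seed)
            colls, _ = generate(spec)
            coll = colls["ITS"]
            summ = divergence_summary(distance_matrix(aligned(coll)),
                                      coll.species_of)
            rates.append(summ.mean_intraspecific)
        assert np.mean(rates) == pytest.approx(2 * 0.01, rel=0.20)

    def test_truth_table_consistent_with_recomputation(self):
        spec = SyntheticSpec(n_genera=3, species_per_genus=2,
                             accessions_per_species=2,
                             locus_lengths={"ITS": 200}, seed=6)
        colls, truth = generate(spec)
        coll = colls["ITS"]
        dm = distance_matrix(aligned(coll))
        from barcodekit.resolution import gap_resolution

        summaries, _ = gap_resolution(dm, coll.species_of)
        truth_its = truth.frame[truth.frame.locus == "ITS"].set_index("species")
        for s in summaries:
            assert truth_its.loc[s.species, "max_intra"] == pytest.approx(
                s.max_intra)
            assert truth_its.loc[s.species, "min_inter"] == pytest.approx(
                s.min_inter)
            assert bool(truth_its.loc[s.species, "resolvable"]) == s.resolved

    def test_singletons_and_dropout(self):
        spec = SyntheticSpec(n_genera=2, species_per_genus=2,
                             accessions_per_species=[1, 3, 2, 1],
                             locus_lengths={"ITS": 60, "rbcL": 60},
                             locus_dropout=0.3, seed=8)
        colls, _ = generate(spec)
        counts = colls["ITS"].species_counts()
        assert sum(counts.values()) <= 7  # dropout removed some records
        spec0 = SyntheticSpec(n_genera=2, species_per_genus=2,
                              accessions_per_species=[1, 3, 2, 1],
                              locus_lengths={"ITS": 60}, seed=8)
        colls0, _ = generate(spec0)
        assert sorted(colls0["ITS"].species_counts().values()) == [1, 1, 2, 3]

    def test_ambiguity_rate_introduces_Ns(self):
        spec = SyntheticSpec(n_genera=1, species_per_genus=2,
                             accessions_per_species=2,
                             locus_lengths={"ITS": 500},
                             ambiguity_rate=0.05, seed=2)
        colls, _ = generate(spec)
        frac_n = np.mean([r.residues.count("N") / len(r.residues)
                          for r in colls["ITS"]])
        assert frac_n == pytest.approx(0.05, rel=0.5)

    def test_invalid_spec_lists_offending_fields(self):
        spec = SyntheticSpec(n_genera=0, locus_lengths={"ITS": 10},
                             inter_divergence=0.9)
        with pytest.raises(ValueError) as err:
            spec.validate()
        msg = str(err.value)
        assert "n_genera" in msg and "length" in msg and "inter" in msg


class TestQualityReads:
    def coll(self):
        spec = SyntheticSpec(n_genera=1, species_per_genus=2,
                             accessions_per_species=2,
                             locus_lengths={"ITS": 400}, seed=3)
        return generate(spec)[0]["ITS"]

    def test_clean_profile_passes_all_screens(self):
        pairs = generate_quality_reads(self.coll(), "clean", seed=0)
        for fwd, rev in pairs:
            assert window_trim(fwd).accepted
            assert window_trim(rev).accepted
            assert pair_usable(overlap_coverage(fwd.residues, rev.residues))

    def test_noisy_ends_get_trimmed(self):
        pairs = generate_quality_reads(self.coll(), "noisy_ends", seed=0,
                                       noisy_tail=25)
        fwd, _ = pairs[0]
        v = window_trim(fwd)
        assert v.trimmed_span[1] <= len(fwd.residues) - 25
        assert v.accepted  # still >= 60% kept

    def test_low_overlap_fraction_flagged_at_strict_rule(self):
        pairs = generate_quality_reads(self.coll(), "clean", seed=0,
                                       overlap_fraction=0.6)
        for fwd, rev in pairs:
            cov = overlap_coverage(fwd.residues, rev.residues)
            assert not pair_usable(cov)          # 0.6 < strict 0.70
            assert pair_usable(cov, min_overlap=0.50)

    def test_fastq_round_trip(self, tmp_path):
        from barcodekit.qc import read_fastq

        pairs = generate_quality_reads(self.coll(), "noisy_ends", seed=0)
        fwd_reads = [f for f, _ in pairs]
        path = tmp_path / "fwd.fastq"
        write_fastq(fwd_reads, path)
        back = read_fastq(path)
        assert [r.read_id for r in back] == [r.read_id for r in fwd_reads]
        assert back[0].qualities == fwd_reads[0].qualities
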