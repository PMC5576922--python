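import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spacerscope.io_core import RunConfig
from spacerscope.protospacer_scan import hamming_windows
from spacerscope.synthetic_data import (
    ProtospacerSpec,
    SynthHostSpec,
    generate_host,
    generate_phage,
    mutate_phage,
    random_repeat_pair,
    simulate_acquired_spacers,
    simulate_crrna_reads,
)


class TestGenerateHost:
    def test_annotated_fraction_near_requested(self, host):
        _genome, _arrays, truth = host
        assert abs((1 - truth.annotated_fraction) - 0.114) <= 0.01

    def test_array_run_length_arithmetic(self, repeats):
        r1, _ = repeats
        spec = SynthHostSpec(genome_length=20_000, n_genes=10, arrays=[(r1, 8, 32)])
        _g, arrays, _t = generate_host(spec, seed=1)
        assert len(arrays[0]) == 8 * 32 + 9 * 28

    def test_arrays_planted_verbatim_in_genome(self, host):
        genome, arrays, _ = host
        for a in arrays:
            assert genome.sequence[a.start : a.start + len(a)] == a.sequence

    def test_no_genes_means_fully_intergenic(self):
        spec = SynthHostSpec(genome_length=5_000, n_genes=0)
        g, _arrays, truth = generate_host(spec, seed=2)
        assert len(g.annotation.genes) == 0
        assert truth.annotated_fraction == 0.0
        assert len(g) == 5_000

    def test_genes_do_not_overlap(self, host):
        _g, _a, truth = host
        df = truth.genes.sort_values("start")
        assert (df.start.values[1:] >= df.end.values[:-1]).all()

    def test_spacers_unique_within_array(self, host):
        _g, arrays, _t = host
        for a in arrays:
            assert len(set(a.spacers)) == len(a.spacers)

    def test_too_small_genome_raises(self, repeats):
        r1, _ = repeats
        with pytest.raises(ValueError, match="too small"):
            generate_host(
                SynthHostSpec(genome_length=1000, n_genes=50, arrays=[(r1, 8, 32)]),
                seed=1,
            )

    def test_reproducible_from_seed(self, repeats):
        r1, r2 = repeats
        spec = SynthHostSpec(genome_length=30_000, n_genes=20, arrays=[(r1, 4, 32)])
        g1, _, _ = generate_host(spec, seed=9)
        g2, _, _ = generate_host(spec, seed=9)
        assert g1.sequence == g2.sequence

    def test_repeat_pair_dissimilar(self, repeats):
        r1, r2 = repeats
        ident = sum(a == b for a, b in zip(r1, r2)) / len(r1)
        assert ident < 0.6


class TestAcquiredSpacers:
    def test_dna_source_has_no_strand_bias(self, host):
        genome, _a, _t = host
        _reads, truth = simulate_acquired_spacers(
            genome, 4000, "DNA", antisense_bias=1.0, seed=3
        )
        mapped = truth[truth.orientation != "unassignable"]
        anti = (mapped.orientation == "antisense").mean()
        assert abs(anti - 0.5) < 3 * np.sqrt(0.25 / len(mapped))

    def test_full_bias_all_antisense_when_no_intergenic(self):
        spec = SynthHostSpec(genome_length=20_000, intergenic_fraction=0.0, n_genes=20)
        g, _a, _t = generate_host(spec, seed=4)
        _reads, truth = simulate_acquired_spacers(g, 300, "RNA", 1.0, seed=5)
        assert (truth.orientation == "antisense").all()

    def test_rna_counts_track_length_times_expression(self, host):
        genome, _a, _t = host
        _reads, truth = simulate_acquired_spacers(genome, 5000, "RNA", 0.5, seed=6)
        counts = truth[truth.source != "intergenic"].source.value_counts()
        genes = {g.gene_id: g for g in genome.annotation.genes}
        weights = pd.Series(
            {gid: genes[gid].length * genes[gid].expression for gid in genes}
        )
        counts = counts.reindex(weights.index, fill_value=0)
        rho = stats.spearmanr(counts, weights).statistic
        assert rho > 0.8

    def test_spacer_sequences_match_their_loci(self, host):
        genome, _a, _t = host
        reads, truth = simulate_acquired_spacers(genome, 50, "RNA", 0.5, seed=7)
        for (rid, seq), row in zip(reads, truth.itertuples()):
            mm = hamming_windows(genome.sequence, seq)
            rc = hamming_windows(
                genome.sequence, seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            )
            assert min(mm.min(), rc.min()) == 0

    def test_empty_request_is_valid(self, host):
        genome, _a, _t = host
        reads, truth = simulate_acquired_spacers(genome, 0, "RNA", 0.5, seed=8)
        assert reads == [] and len(truth) == 0


class TestCrrnaReads:
    def test_mature_read_structure(self, host):
        _g, arrays, _t = host
        reads, truth = simulate_crrna_reads(arrays, 20, 0, [], seed=9)
        for (rid, seq), row in zip(reads, truth.itertuples()):
            a = next(x for x in arrays if x.array_id == row.array_id)
            sp = a.spacers[row.spacer_index]
            assert seq == a.repeat[-8:] + sp + a.repeat[: row.stub_len]
            assert row.trimmed_len == 8 + len(sp)

    def test_no_mature_reads(self, host, trna_set):
        _g, arrays, _t = host
        reads, truth = simulate_crrna_reads(arrays, 0, 50, trna_set, seed=10)
        assert (truth.kind != "mature").all()

    def test_designated_trna_is_modal_species(self, host, trna_set):
        _g, arrays, _t = host
        reads, truth = simulate_crrna_reads(arrays, 100, 600, trna_set, seed=11)
        counts = truth[truth.kind == "trna"].trna_id.value_counts()
        assert counts.idxmax() == "tRNA-Ile"


class TestGeneratePhage:
    def test_planted_pam_readable_at_truth_coordinates(self, escape_phage, config):
        phage, truth = escape_phage
        from spacerscope.io_core import revcomp

        for row in truth.itertuples():
            if row.strand == "+":
                pam = phage.sequence[row.start - 2 : row.start]
            else:
                pam = revcomp(phage.sequence[row.end : row.end + 2])
            assert pam == row.pam

    def test_zero_mismatch_protospacer_recovered_exactly(self, host, escape_phage):
        _g, arrays, _t = host
        phage, truth = escape_phage
        row = truth[truth.n_mismatches == 0].iloc[0]
        spacer = arrays[0].spacers[row.spacer_index]
        from spacerscope.io_core import revcomp

        seg = phage.sequence[row.start : row.end]
        proto = seg if row.strand == "+" else revcomp(seg)
        assert proto == spacer

    def test_mismatch_positions_match_plant(self, host, escape_phage):
        _g, arrays, _t = host
        phage, truth = escape_phage
        from spacerscope.io_core import revcomp

        for row in truth.itertuples():
            spacer = arrays[0].spacers[row.spacer_index]
            seg = phage.sequence[row.start : row.end]
            proto = seg if row.strand == "+" else revcomp(seg)
            observed = [i + 1 for i in range(32) if proto[i] != spacer[i]]
            expected = (
                [int(x) for x in row.mismatch_positions.split(",")]
                if row.mismatch_positions
                else []
            )
            assert observed == expected

    def test_overfull_genome_rejected(self, host, config):
        _g, arrays, _t = host
        specs = [ProtospacerSpec((arrays[0].array_id, i)) for i in range(4)]
        with pytest.raises(ValueError, match="too small"):
            generate_phage(arrays, specs, 2_000, seed=1, config=config)


class TestMutatePhage:
    def test_empty_event_list_is_identity(self, escape_phage):
        phage, _ = escape_phage
        out, calls = mutate_phage(phage, [], seed=1)
        assert out == phage.sequence and calls == []

    def test_six_snvs_plus_insertion_is_seven_sites(self, escape_phage):
        phage, _ = escape_phage
        ev = [("snv", p) for p in (100, 700, 5000, 9000, 20000, 33000)]
        ev.append(("insertion", 1808, 1))
        out, calls = mutate_phage(phage, ev, seed=2)
        assert len(calls) == 7
        assert sum(c.type == "SNV" for c in calls) == 6
        assert sum(c.type == "insertion" for c in calls) == 1

    def test_overlapping_events_rejected(self, escape_phage):
        phage, _ = escape_phage
        with pytest.raises(ValueError, match="overlap"):
            mutate_phage(phage, [("deletion", 100, 50), ("snv", 120)], seed=3)

    def test_out_of_bounds_event_rejected(self, escape_phage):
        phage, _ = escape_phage
        with pytest.raises(ValueError, match="bounds"):
            mutate_phage(phage, [("snv", len(phage.sequence))], seed=4)
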