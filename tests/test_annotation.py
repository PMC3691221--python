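"""Local alignment, placement, consensus, ORF scan and motif/CR partitioning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitocomp.annotation import (
    AmbiguousStrandError,
    ControlRegionError,
    DEFAULT_MOTIFS,
    Placement,
    RefFeature,
    annotate_genome,
    consensus_annotation,
    find_motif_approx,
    local_align,
    partition_control_region,
    place_feature,
    scan_orfs,
)
from mitocomp.genome_model import Mitogenome, extract_feature_seq, reverse_complement
from mitocomp.synthetic_data import (
    SimulationConfig,
    random_coalescent_tree,
    simulate_mitogenome_set,
)

# Control-region motif variants of the second study species, used to check
# approximate matching against the default (first-species) motif set.
TM_TAS = "ACGCAATGCATATATGTATTATCACCATTATTTTATATCAAACAT"
TM_CSB_E = "AGAGTGTGGCGGGT"
TM_CSB3 = "TGCAAACCCCCCGGAAACAG"


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestLocalAlign:
    def test_identical_sequences(self):
        aln = local_align("ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT")
        assert aln.identity == 1.0
        assert (aln.target_start, aln.target_end) == (1, 20)
        assert (aln.query_start, aln.query_end) == (1, 20)

    def test_embedded_query_with_substitutions(self):
        """A 60-mer planted in 2 kb background with 3 substitutions is found
        at the planted window with identity 57/60."""
        rng = np.random.default_rng(3)
        insert = list(_random_seq(rng, 60))
        for pos in (10, 30, 50):
            insert[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[insert[pos]]
        background = _random_seq(rng, 2000)
        target = background[:800] + "".join(insert) + background[800:]
        aln = local_align("".join(_restore(insert, (10, 30, 50))), target)
        assert aln.n_matches >= 57
        assert abs(aln.target_start - 801) <= 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")


def _restore(mutated, positions):
    # rebuild the original query by undoing the complement substitutions
    out = list(mutated)
    for pos in positions:
        out[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[pos]]
    return out


class TestPlaceFeature:
    def test_self_placement_is_exact(self, simulated_genomes):
        genomes, truth = simulated_genomes
        g = genomes[0]
        coords = {n: (s, e, st) for n, s, e, st in truth.feature_coordinates[g.taxon]}
        for f in g.features:
            if f.length() < 20:
                continue
            p = place_feature(extract_feature_seq(g, f), g, feature_name=f.name)
            assert p is not None
            assert (p.start, p.stop, p.strand) == coords[f.name]
            assert p.percent_identity == 1.0

    def test_reverse_strand_found(self):
        rng = np.random.default_rng(8)
        core = _random_seq(rng, 120)
        genome = Mitogenome("t", _random_seq(rng, 400) + reverse_complement(core) + _random_seq(rng, 400))
        p = place_feature(core, genome)
        assert p is not None
        assert p.strand == "L"
        assert (p.start, p.stop) == (401, 520)

    def test_placement_across_origin(self):
        rng = np.random.default_rng(9)
        core = _random_seq(rng, 100)
        filler = _random_seq(rng, 500)
        genome = Mitogenome("t", core[40:] + filler + core[:40])
        p = place_feature(core, genome)
        assert p is not None
        assert (p.start, p.stop) == (561, 60)  # wraps the origin

    def test_unrelated_sequence_not_found(self, simulated_genomes):
        genomes, _ = simulated_genomes
        rng = np.random.default_rng(10)
        assert place_feature(_random_seq(rng, 300), genomes[0]) is None


class TestConsensus:
    def _placements(self, starts, stops=None, scores=None, strands=None):
        stops = stops or [s + 99 for s in starts]
        scores = scores or [0.9] * len(starts)
        strands = strands or ["H"] * len(starts)
        return [
            Placement("f", f"ref{i}", s, e, st, sc, 1.0)
            for i, (s, e, st, sc) in enumerate(zip(starts, stops, strands, scores))
        ]

    def test_unanimous(self):
        cons = consensus_annotation(self._placements([100, 100, 100]))
        assert (cons.start, cons.support_start) == (100, 3)

    def test_majority_beats_outlier(self):
        cons = consensus_annotation(self._placements([100, 100, 103]))
        assert cons.start == 100
        assert cons.support_start == 2

    def test_tie_broken_by_score(self):
        cons = consensus_annotation(self._placements([100, 103], scores=[0.99, 0.80]))
        assert cons.start == 100

    def test_order_invariance(self):
        placements = self._placements([100, 100, 103, 103, 103], scores=[0.9, 0.8, 0.7, 0.6, 0.5])
        expected = consensus_annotation(placements)
        rng = np.random.default_rng(0)
        for _ in range(10):
            perm = list(rng.permutation(len(placements)))
            shuffled = [placements[i] for i in perm]
            got = consensus_annotation(shuffled)
            assert (got.start, got.stop, got.strand) == (expected.start, expected.stop, expected.strand)

    def test_strand_disagreement_raises(self):
        with pytest.raises(AmbiguousStrandError):
            consensus_annotation(self._placements([100, 100], strands=["H", "L"]))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            consensus_annotation([])


class TestAnnotateGenome:
    def test_self_annotation_recovers_all_coordinates(self, simulated_genomes):
        genomes, truth = simulated_genomes
        g = genomes[0]
        refs = [
            RefFeature(g.taxon, f.name, f.feature_class, extract_feature_seq(g, f))
            for f in g.features
            if f.length() >= 20
        ]
        result = annotate_genome(g, refs)
        assert not result.not_found and not result.issues
        coords = {n: (s, e, st) for n, s, e, st in truth.feature_coordinates[g.taxon]}
        for rec in result.records:
            assert (rec.start, rec.stop, rec.strand) == coords[rec.name]

    def test_cross_annotation_boundary_accuracy(self, small_genome_partitions):
        """At <= 5% divergence and no CDS/rRNA indels, >= 95% of placements
        land within +/- 2 nt of the true boundaries."""
        rng = np.random.default_rng(77)
        within = total = 0
        for rep in range(20):
            tree = random_coalescent_tree(3, rng, mean_pairwise=0.05)
            config = SimulationConfig(tree=tree, partitions=small_genome_partitions,
                                      seed=int(rng.integers(2**31)))
            genomes, truth = simulate_mitogenome_set(config)
            donor, target = genomes[0], genomes[1]
            true_coords = {n: (s, e) for n, s, e, st in truth.feature_coordinates[target.taxon]}
            for f in donor.features:
                if f.feature_class not in ("CDS", "rRNA"):
                    continue
                p = place_feature(extract_feature_seq(donor, f), target, feature_name=f.name)
                total += 1
                if p is not None:
                    s, e = true_coords[f.name]
                    if abs(p.start - s) <= 2 and abs(p.stop - e) <= 2:
                        within += 1
        assert within / total >= 0.95


class TestScanOrfs:
    def test_single_orf_in_background(self):
        rng = np.random.default_rng(4)
        body = "".join(rng.choice(["GCA", "CTC", "TTC"], size=60))  # stop/start-free codons
        genome = Mitogenome("t", "CCC" * 30 + "ATG" + body + "TAA" + "CCC" * 30)
        orfs = scan_orfs(genome, min_length=60)
        forward = [o for o in orfs if o.strand == "H"]
        assert any(o.start == 91 and o.length == 186 and o.start_codon == "ATG" for o in forward)

    def test_simulated_cds_recovered(self, simulated_genomes):
        genomes, _ = simulated_genomes
        g = genomes[0]
        orfs = scan_orfs(g, min_length=150)
        spans = {(o.start, o.stop, o.strand) for o in orfs}
        for f in g.features:
            if f.feature_class == "CDS" and f.stop_class in ("TAA", "TAG"):
                assert (f.start, f.stop, f.strand) in spans

    def test_homopolymer_genome_has_no_orfs(self):
        assert scan_orfs(Mitogenome("t", "A" * 500), min_length=60) == []

    def test_orf_across_origin(self):
        rng = np.random.default_rng(6)
        body = "".join(rng.choice(["GCA", "CTC", "TTC"], size=40))
        seq = "ATG" + body + "TAA"  # 126 nt ORF
        genome_seq = seq[50:] + "CCC" * 40 + seq[:50]
        orfs = scan_orfs(Mitogenome("t", genome_seq), min_length=120)
        L = len(genome_seq)
        assert any(o.start == L - 49 and o.length == 126 for o in orfs)


class TestMotifs:
    @pytest.mark.parametrize(
        "seq,motif,budget,expected",
        [
            ("AAACCC", "ACC", 0, [(3, 0)]),
            ("AAAA", "TTT", 0, []),
        ],
    )
    def test_exact_examples(self, seq, motif, budget, expected):
        assert find_motif_approx(seq, motif, budget) == expected

    def test_tas_motifs_of_both_species_differ_by_three(self):
        """The two study species' TAS sequences differ at exactly 3 positions,
        so the default TAS motif hits the other species within budget 3."""
        hits = find_motif_approx(TM_TAS, DEFAULT_MOTIFS.motifs["TAS"], 3)
        assert hits == [(1, 3)]
        assert find_motif_approx(TM_TAS, DEFAULT_MOTIFS.motifs["TAS"], 2) == []

    def test_other_species_variants_within_default_budgets(self):
        for name, variant in (("CSB-E", TM_CSB_E), ("CSB3", TM_CSB3)):
            budget = DEFAULT_MOTIFS.max_mismatches[name]
            assert find_motif_approx(variant, DEFAULT_MOTIFS.motifs[name], budget)

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_hamming_oracle(self, data):
        seq = data.draw(st.text(alphabet="ACGT", min_size=5, max_size=60))
        m = data.draw(st.integers(1, min(8, len(seq))))
        motif = data.draw(st.text(alphabet="ACGT", min_size=m, max_size=m))
        budget = data.draw(st.integers(0, m))
        expected = []
        for i in range(len(seq) - m + 1):
            mm = sum(a != b for a, b in zip(seq[i : i + m], motif))
            if mm <= budget:
                expected.append((i + 1, mm))
        assert find_motif_approx(seq, motif, budget) == expected


class TestControlRegionPartition:
    def test_synthetic_construction(self):
        rng = np.random.default_rng(12)
        csbf = DEFAULT_MOTIFS.motifs["CSB-F"]
        csb1 = DEFAULT_MOTIFS.motifs["CSB1"]
        cr = _random_seq(rng, 279) + csbf + _random_seq(rng, 340) + csb1 + _random_seq(rng, 230)
        part = partition_control_region(cr)
        assert part.domains[1] == (1, 279)
        assert part.domains[2][0] == 280
        assert part.domains[3][0] == 280 + len(csbf) + 340
        assert part.motif_hits["CSB-F"] == (280, 0)

    def test_missing_anchor_is_descriptive_error(self):
        rng = np.random.default_rng(13)
        cr = _random_seq(rng, 200) + DEFAULT_MOTIFS.motifs["CSB-F"] + _random_seq(rng, 200)
        with pytest.raises(ControlRegionError, match="CSB1"):
            partition_control_region(cr)
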