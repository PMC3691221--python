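"""Gap-weighted distances, partition handling and the DR regression."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitocomp.genome_model import VERTEBRATE_MITO
from mitocomp.rates import (
    DistanceTable,
    GeneAlignment,
    UndefinedDistanceError,
    codon_position_split,
    consensus_sequence,
    fourfold_degenerate_sites,
    gap_column_filter,
    gene_distances,
    group_means,
    p_distance,
    rate_table,
    relative_rate_regression,
)

aligned_pair = st.integers(1, 80).flatmap(
    lambda n: st.tuples(
        st.text(alphabet="ACGTN-", min_size=n, max_size=n),
        st.text(alphabet="ACGTN-", min_size=n, max_size=n),
    )
)


def _oracle_p_distance(a, b, gap_mode):
    diffs = counted = 0
    for ca, cb in zip(a, b):
        if ca == "-" and cb == "-":
            continue
        if ca == "N" and cb == "N":
            continue
        if gap_mode == "ignore" and "-" in (ca, cb):
            continue
        counted += 1
        diffs += ca != cb
    return None if counted == 0 else diffs / counted


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,mode,expected",
        [
            ("AAAA", "AAAT", "full_weight", 0.25),
            ("AA-A", "AATA", "full_weight", 0.25),  # gap vs T is one difference over 4
            ("AA-A", "AATA", "ignore", 0.0),
            ("A-CA", "A-CG", "full_weight", 1 / 3),  # shared gap column excluded
            ("ANAA", "ACAA", "full_weight", 0.25),  # N vs base is a difference
        ],
    )
    def test_examples(self, a, b, mode, expected):
        assert p_distance(a, b, mode) == pytest.approx(expected)

    def test_all_shared_gaps_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            p_distance("--", "--")

    @given(aligned_pair, st.sampled_from(["full_weight", "ignore"]))
    @settings(max_examples=150, deadline=None)
    def test_matches_counting_oracle_and_axioms(self, pair, mode):
        a, b = pair
        expected = _oracle_p_distance(a, b, mode)
        if expected is None:
            with pytest.raises(UndefinedDistanceError):
                p_distance(a, b, mode)
            return
        d = p_distance(a, b, mode)
        assert d == pytest.approx(expected)
        assert 0.0 <= d <= 1.0
        assert p_distance(b, a, mode) == pytest.approx(d)  # symmetry
        if _oracle_p_distance(a, a, mode) is not None:
            assert p_distance(a, a, mode) == 0.0


class TestConsensus:
    def test_plurality(self):
        aln = GeneAlignment("g", ["a", "b", "c"], ["AAT", "AAT", "AAA"])
        assert consensus_sequence(aln) == "AAT"

    def test_gap_competes(self):
        aln = GeneAlignment("g", ["a", "b"], ["A-", "A-"])
        assert consensus_sequence(aln) == "A-"

    def test_plurality_vs_counting_oracle(self):
        rng = np.random.default_rng(21)
        rows = ["".join(rng.choice(list("ACGT-"), size=40)) for _ in range(50)]
        aln = GeneAlignment("g", [f"t{i}" for i in range(50)], rows)
        cons = consensus_sequence(aln)
        for i, col in enumerate(zip(*rows)):
            counts = {c: col.count(c) for c in set(col)}
            assert counts[cons[i]] == max(counts.values())


class TestGeneDistances:
    def test_identical_rows_all_zero(self):
        aln = GeneAlignment("g", list("abcd"), ["ACGT"] * 4)
        table = gene_distances(aln, "pairwise")
        assert len(table.entries) == 6
        assert all(v == 0.0 for v in table.entries.values())

    def test_hand_counted_pairwise(self):
        aln = GeneAlignment("g", ["a", "b", "c"], ["AAAA", "AAAT", "TTAA"])
        t = gene_distances(aln, "pairwise")
        assert t.entries[("a", "b")] == 0.25
        assert t.entries[("a", "c")] == 0.5
        assert t.entries[("b", "c")] == 0.75

    def test_vs_consensus(self):
        aln = GeneAlignment("g", ["a", "b", "c"], ["AAT", "AAT", "AAA"])
        t = gene_distances(aln, "vs_consensus")
        assert t.entries == {"a": 0.0, "b": 0.0, "c": pytest.approx(1 / 3)}


class TestCodonPositions:
    def test_split_and_reassembly(self):
        aln = GeneAlignment("g", ["a", "b"], ["ACGTTA", "ACGTTG"])
        p1, p2, p3 = codon_position_split(aln)
        assert p1.rows == ["AT", "AT"]
        assert p2.rows == ["CT", "CT"]
        assert p3.rows == ["GA", "GG"]
        # interleaving the three partitions restores the original
        rebuilt = [
            "".join(itertools.chain.from_iterable(zip(r1, r2, r3)))
            for r1, r2, r3 in zip(p1.rows, p2.rows, p3.rows)
        ]
        assert rebuilt == aln.rows

    def test_non_codon_length_rejected(self):
        with pytest.raises(ValueError):
            codon_position_split(GeneAlignment("g", ["a"], ["ACGTA"]))

    def test_random_alignment_index_oracle(self):
        rng = np.random.default_rng(2)
        rows = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(4)]
        aln = GeneAlignment("g", list("abcd"), rows)
        parts = codon_position_split(aln)
        for pos, part in enumerate(parts):
            for orig, sub in zip(rows, part.rows):
                assert sub == orig[pos::3]


class TestFourfoldSites:
    def test_leucine_ctn_included(self):
        aln = GeneAlignment("g", ["a", "b"], ["CTACTG", "CTGCTT"])
        assert fourfold_degenerate_sites(aln) == [2, 5]

    def test_isoleucine_family_excluded(self):
        # ATx splits Ile/Met by the third base, so the codon disqualifies the site
        aln = GeneAlignment("g", ["a", "b"], ["CTAATA", "CTAATT"])
        assert fourfold_degenerate_sites(aln) == [2]

    def test_gap_codon_abstains(self):
        aln = GeneAlignment("g", ["a", "b"], ["CTA", "C-A"])
        assert fourfold_degenerate_sites(aln) == [2]

    def test_subset_of_third_positions(self):
        rng = np.random.default_rng(14)
        rows = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(5)]
        aln = GeneAlignment("g", [f"t{i}" for i in range(5)], rows)
        sites = fourfold_degenerate_sites(aln)
        assert all(s % 3 == 2 for s in sites)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(15)
        rows = ["".join(rng.choice(list("ACGTN-"), p=[0.23] * 4 + [0.04, 0.04], size=90)) for _ in range(6)]
        aln = GeneAlignment("g", [f"t{i}" for i in range(6)], rows)
        expected = []
        for c in range(0, 90, 3):
            votes = 0
            ok = True
            for row in rows:
                codon = row[c : c + 3]
                if "-" in codon or "N" in codon:
                    continue
                aas = {VERTEBRATE_MITO.amino_acid(codon[:2] + b) for b in "ACGT"}
                if len(aas) != 1 or "*" in aas:
                    ok = False
                    break
                votes += 1
            if ok and votes:
                expected.append(c + 2)
        assert fourfold_degenerate_sites(aln) == expected


class TestGapColumnFilter:
    def test_all_gap_column_removed(self):
        aln = GeneAlignment("g", ["a", "b"], ["A-C", "A-C"])
        assert gap_column_filter(aln).rows == ["AC", "AC"]

    def test_gap_free_unchanged(self):
        aln = GeneAlignment("g", ["a", "b"], ["ACG", "ACG"])
        assert gap_column_filter(aln).rows == aln.rows

    def test_threshold_selects_planted_columns(self):
        # columns with gap fractions 0, 0.2, 0.6 and threshold 0.5
        rows = ["ACG", "ACG", "AC-", "A--", "AC-"]
        aln = GeneAlignment("g", list("abcde"), rows)
        out = gap_column_filter(aln, max_gap_fraction=0.5)
        assert out.rows == [r[:2] for r in rows]

    def test_output_never_exceeds_threshold(self):
        rng = np.random.default_rng(16)
        rows = ["".join(rng.choice(list("ACGT-"), p=[0.15] * 4 + [0.4], size=50)) for _ in range(8)]
        aln = GeneAlignment("g", [f"t{i}" for i in range(8)], rows)
        for thr in (0.0, 0.25, 0.5):
            out = gap_column_filter(aln, thr)
            for col in zip(*out.rows):
                assert col.count("-") / 8 <= thr

    def test_everything_removed_is_error(self):
        with pytest.raises(ValueError):
            gap_column_filter(GeneAlignment("g", ["a", "b"], ["-A", "A-"]))


def _table(gene, entries):
    return DistanceTable(gene=gene, mode="pairwise", entries=entries)


class TestRegression:
    def test_identity_slope(self):
        x = _table("12S", {("a", "b"): 0.1, ("a", "c"): 0.2, ("b", "c"): 0.3})
        est = relative_rate_regression(x, x)
        assert est.slope == pytest.approx(1.0)
        assert est.r_squared == pytest.approx(1.0)

    def test_doubling_slope_and_linearity(self):
        x = _table("12S", {("a", "b"): 0.1, ("a", "c"): 0.2, ("b", "c"): 0.35})
        y = _table("g", {k: 2 * v for k, v in x.entries.items()})
        assert relative_rate_regression(y, x).slope == pytest.approx(2.0)
        y3 = _table("g", {k: 3 * v for k, v in y.entries.items()})
        assert relative_rate_regression(y3, x).slope == pytest.approx(
            3 * relative_rate_regression(y, x).slope
        )

    @pytest.mark.parametrize("through_origin", [True, False])
    def test_matches_normal_equation_oracle(self, through_origin):
        rng = np.random.default_rng(17)
        keys = [("t", str(i)) for i in range(25)]
        xv = rng.random(25) * 0.3
        yv = 1.7 * xv + rng.normal(0, 0.02, 25) + (0.0 if through_origin else 0.05)
        x = _table("12S", dict(zip(keys, xv)))
        y = _table("g", dict(zip(keys, yv)))
        est = relative_rate_regression(y, x, through_origin=through_origin)
        if through_origin:
            assert est.slope == pytest.approx(np.sum(xv * yv) / np.sum(xv**2), abs=1e-10)
        else:
            X = np.column_stack([xv, np.ones(25)])
            beta = np.linalg.solve(X.T @ X, X.T @ yv)
            assert est.slope == pytest.approx(beta[0], abs=1e-10)
            assert est.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_insufficient_keys(self):
        x = _table("12S", {("a", "b"): 0.1, ("a", "c"): 0.2})
        with pytest.raises(ValueError):
            relative_rate_regression(x, x)


class TestRateTable:
    def _alignments(self, seed=18):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(6)]
        base = "".join(rng.choice(list("ACGT"), size=120))

        def mutate(p):
            rows = []
            for _ in taxa:
                chars = [
                    c if rng.random() > p else rng.choice([x for x in "ACGT" if x != c])
                    for c in base
                ]
                rows.append("".join(chars))
            return rows

        return {
            "12S": GeneAlignment("12S", taxa, mutate(0.05)),
            "ND1": GeneAlignment("ND1", taxa, mutate(0.1)),
            "CR": GeneAlignment("CR", taxa, mutate(0.2)),
        }

    def test_reference_slope_is_one(self):
        ests = {e.gene_or_partition: e for e in rate_table(self._alignments(), "12S",
                                                           feature_classes={"CR": "CR"})}
        assert ests["12S"].slope == pytest.approx(1.0)

    def test_partitions_present_and_grouped(self):
        ests = rate_table(self._alignments(), "12S", dloop_gene="CR",
                          feature_classes={"CR": "CR"})
        labels = {e.gene_or_partition for e in ests}
        assert {"12S", "ND1", "CR", "ND1_pos1", "ND1_pos2", "ND1_pos3", "CR_gapfiltered"} <= labels
        means = group_means(ests)
        assert "rRNA" in means and "CDS" in means

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            rate_table({"ND1": self._alignments()["ND1"]}, "12S")
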