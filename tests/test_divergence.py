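"""Ortholog pairing, codon-aware alignment, and NG86 Ka/Ks counting."""

import itertools
import math

import numpy as np
import pytest

from codonuse import (
    GeneRecord,
    HitRecord,
    align_proteins,
    backtranslate_alignment,
    build_ortholog_pair,
    filter_and_correlate,
    import_hits,
    kaks_ng86,
    ng86_counts,
    reciprocal_best_hits,
    simulate_ortholog_pair,
    translate,
)
from codonuse.divergence import (
    alignment_identity,
    pathway_differences,
    synonymous_site_count,
    write_hits,
)

from conftest import random_gene


def make_hit(q, s, pident=90.0, length=200, evalue=1e-50, bitscore=300.0):
    return HitRecord(q, s, pident, length, 5, 0, 1, length, 1, length, evalue, bitscore)


class TestHitIO:
    def test_round_trip(self, tmp_path):
        hits = [make_hit("a1", "b1"), make_hit("a2", "b2", evalue=1e-5)]
        p = tmp_path / "hits.tsv"
        write_hits(hits, p)
        assert import_hits(p) == hits

    def test_malformed_lines_skipped(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("a\tb\t90\t200\t5\t0\t1\t200\t1\t200\t1e-5\t300\nbroken line\n")
        hits = import_hits(p)
        assert len(hits) == 1 and hits[0].evalue == 1e-5

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        with pytest.raises(ValueError):
            import_hits(p)


class TestRbh:
    LENGTHS_A = {"a1": 200, "a2": 200, "a3": 200}
    LENGTHS_B = {"b1": 200, "b2": 200, "b3": 200}

    def test_mutual_best_pair_found(self):
        ab = [make_hit("a1", "b1", bitscore=500), make_hit("a1", "b2", bitscore=100)]
        ba = [make_hit("b1", "a1", bitscore=500), make_hit("b2", "a3", bitscore=90)]
        pairs = reciprocal_best_hits(ab, ba, self.LENGTHS_A, self.LENGTHS_B)
        assert pairs == [("a1", "b1")]

    def test_non_reciprocal_best_excluded(self):
        ab = [make_hit("a1", "b1", bitscore=500)]
        ba = [make_hit("b1", "a2", bitscore=600), make_hit("b1", "a1", bitscore=100)]
        assert reciprocal_best_hits(ab, ba, self.LENGTHS_A, self.LENGTHS_B) == []

    @pytest.mark.parametrize(
        "kw",
        [
            {"pident": 50.0},                # below 60% identity
            {"evalue": 1e-3},                # above 1e-5
            {"length": 100},                 # coverage 0.5 < 0.6
        ],
        ids=["identity", "evalue", "coverage"],
    )
    def test_threshold_filters(self, kw):
        ab = [make_hit("a1", "b1", **kw)]
        ba = [make_hit("b1", "a1", **kw)]
        assert reciprocal_best_hits(ab, ba, self.LENGTHS_A, self.LENGTHS_B) == []

    def test_short_proteins_excluded(self):
        ab, ba = [make_hit("a1", "b1")], [make_hit("b1", "a1")]
        assert (
            reciprocal_best_hits(ab, ba, {"a1": 80}, {"b1": 200}) == []
        )

    def test_symmetric_under_genome_swap(self):
        ab = [make_hit("a1", "b1", bitscore=500), make_hit("a2", "b2", bitscore=400)]
        ba = [make_hit("b1", "a1", bitscore=500), make_hit("b2", "a2", bitscore=400)]
        fwd = reciprocal_best_hits(ab, ba, self.LENGTHS_A, self.LENGTHS_B)
        rev = reciprocal_best_hits(ba, ab, self.LENGTHS_B, self.LENGTHS_A)
        assert {frozenset(p) for p in fwd} == {frozenset(p) for p in rev}

    def test_planted_orthologs_with_decoy_paralogs(self):
        ab, ba = [], []
        truth = []
        for i in range(5):
            a, b, decoy = f"a{i}", f"b{i}", f"b{(i + 1) % 5}"
            ab += [make_hit(a, b, bitscore=500), make_hit(a, decoy, bitscore=200)]
            ba += [make_hit(b, a, bitscore=500), make_hit(b, f"a{(i + 2) % 5}", bitscore=150)]
            truth.append((a, b))
        la = {f"a{i}": 200 for i in range(5)}
        lb = {f"b{i}": 200 for i in range(5)}
        assert reciprocal_best_hits(ab, ba, la, lb) == sorted(truth)


def gotoh_score(a, b, matrix, open_cost=11.0, extend_cost=1.0):
    """Independent affine-gap global alignment score (first gap residue
    costs open, later residues extend)."""
    inf = float("inf")
    n, m = len(a), len(b)
    M = [[-inf] * (m + 1) for _ in range(n + 1)]
    X = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Y = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -open_cost - (i - 1) * extend_cost
    for j in range(1, m + 1):
        Y[0][j] = -open_cost - (j - 1) * extend_cost
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - open_cost, X[i - 1][j] - extend_cost)
            Y[i][j] = max(M[i][j - 1] - open_cost, Y[i][j - 1] - extend_cost)
    return max(M[n][m], X[n][m], Y[n][m])


class TestAlignment:
    def test_identical_sequences_gapless(self):
        a, b = align_proteins("MKVLA", "MKVLA")
        assert a == b == "MKVLA"
        assert alignment_identity(a, b) == 100.0

    def test_single_residue_gap(self):
        a, b = align_proteins("ACDE", "ACE")
        assert a == "ACDE"
        assert b in ("AC-E", "A-CE")
        assert b.count("-") == 1

    def test_score_matches_independent_dp(self, rng):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        residues = "ARNDCQEGHILKMFPSTWYV"
        aligner_scores = []
        for _ in range(20):
            a = "".join(residues[i] for i in rng.integers(0, 20, size=int(rng.integers(4, 12))))
            b = "".join(residues[i] for i in rng.integers(0, 20, size=int(rng.integers(4, 12))))
            aln_a, aln_b = align_proteins(a, b)
            score = 0.0
            in_gap_a = in_gap_b = False
            for x, y in zip(aln_a, aln_b):
                if x == "-":
                    score -= 1.0 if in_gap_a else 11.0
                    in_gap_a, in_gap_b = True, False
                elif y == "-":
                    score -= 1.0 if in_gap_b else 11.0
                    in_gap_b, in_gap_a = True, False
                else:
                    score += blosum[x, y]
                    in_gap_a = in_gap_b = False
            assert score == pytest.approx(gotoh_score(a, b, blosum))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_proteins("", "MKV")


class TestBacktranslate:
    def test_gapless(self, code):
        cod_a, cod_b = backtranslate_alignment("ME", "ME", ("ATG", "GAA"), ("ATG", "GAG"), code)
        assert cod_a == ("ATG", "GAA") and cod_b == ("ATG", "GAG")

    def test_gap_becomes_triplet_gap(self, code):
        cod_a, cod_b = backtranslate_alignment(
            "MEF", "M-F", ("ATG", "GAA", "TTT"), ("ATG", "TTC"), code
        )
        assert cod_b == ("ATG", "---", "TTC")
        assert len(cod_a) * 3 == 3 * len("MEF")

    def test_degapping_inverts(self, rng, code):
        g = random_gene(rng, 60)
        pair, _ = simulate_ortholog_pair(g, 0.1, 0.3, code, seed=1)
        aln_a, aln_b = align_proteins(translate(g, code), translate(pair, code))
        cod_a, cod_b = backtranslate_alignment(aln_a, aln_b, g.codons[:-1], pair.codons[:-1], code)
        assert tuple(c for c in cod_a if c != "---") == g.codons[:-1]
        assert tuple(c for c in cod_b if c != "---") == pair.codons[:-1]

    def test_translation_mismatch_names_position(self, code):
        with pytest.raises(ValueError, match="position 2"):
            backtranslate_alignment("ME", "ME", ("ATG", "TTT"), ("ATG", "GAA"), code)


def enumeration_oracle(c1, c2, code):
    """Exhaustive pathway enumeration for codon differences, written
    independently of the implementation: walk every permutation of the
    differing positions as explicit codon paths."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    all_paths, open_paths = [], []
    for order in itertools.permutations(positions):
        path = [c1]
        for pos in order:
            path.append(path[-1][:pos] + c2[pos] + path[-1][pos + 1 :])
        steps = list(zip(path, path[1:]))
        open_paths.append(steps)
        if all(not code.is_stop(c) for c in path[1:-1]):
            all_paths.append(steps)
    chosen = all_paths or open_paths
    sd = nd = 0.0
    for steps in chosen:
        for x, y in steps:
            if code.amino_acid(x) == code.amino_acid(y):
                sd += 1
            else:
                nd += 1
    return sd / len(chosen), nd / len(chosen)


class TestNg86:
    def test_identical_sequences_zero(self, rng, code):
        g = random_gene(rng, 100)
        ka, ks = kaks_ng86(g.codons[:-1], g.codons[:-1], code)
        assert ka == 0.0 and ks == 0.0

    def test_single_synonymous_codon_pair(self, code):
        """GAA vs GAG: one synonymous difference over 1/3 synonymous site,
        so pS saturates the JC correction while Ka stays 0."""
        counts = ng86_counts(["GAA"], ["GAG"], code)
        assert counts.syn_sites == pytest.approx(1 / 3)
        assert counts.syn_diffs == 1.0 and counts.nonsyn_diffs == 0.0
        ka, ks = kaks_ng86(["GAA"], ["GAG"], code)
        assert ka == 0.0 and math.isnan(ks)

    def test_sites_sum_to_three_per_codon(self, code):
        for codon in code.sense_codons:
            s = synonymous_site_count(codon, code)
            assert 0.0 <= s <= 3.0
        counts = ng86_counts(["ATG", "GCT"], ["ATG", "GCG"], code)
        assert counts.syn_sites + counts.nonsyn_sites == pytest.approx(6.0)

    def test_all_ordered_codon_pairs_match_enumeration(self, code):
        """Difference counts equal the independent exhaustive pathway oracle
        on all 61 x 61 sense-codon pairs."""
        for c1 in code.sense_codons:
            for c2 in code.sense_codons:
                sd, nd = pathway_differences(c1, c2, code)
                esd, end_ = enumeration_oracle(c1, c2, code)
                assert sd == pytest.approx(esd), (c1, c2)
                assert nd == pytest.approx(end_), (c1, c2)

    def test_symmetry(self, rng, code):
        g = random_gene(rng, 120)
        pair, _ = simulate_ortholog_pair(g, 0.3, 0.3, code, seed=5)
        a, b = g.codons[:-1], pair.codons[:-1]
        assert kaks_ng86(a, b, code) == pytest.approx(kaks_ng86(b, a, code))

    def test_gap_and_stop_columns_skipped(self, code):
        counts = ng86_counts(["ATG", "---", "TAA", "GCT"], ["ATG", "GGG", "GCT", "GCC"], code)
        assert counts.n_codons == 2  # ATG and GCT/GCC columns only

    def test_estimator_recovers_realised_rates(self, rng, code):
        """On a 5,000-codon pair with omega = 0, Ks matches the realised
        synonymous divergence and Ka stays at 0."""
        g = random_gene(rng, 5_000)
        pair, truth = simulate_ortholog_pair(g, 0.3, 0.0, code, seed=7)
        ka, ks = kaks_ng86(g.codons[:-1], pair.codons[:-1], code)
        assert truth.nonsyn_substitutions == 0
        # pathway averaging over double-hit codons leaks a little Nd even
        # under purely synonymous evolution, so Ka is near zero, not zero
        assert ka < 0.005
        assert ks == pytest.approx(truth.realised_ks, rel=0.15)


class TestFilterAndCorrelate:
    def _pairs(self, rng, code, n=12, ks_values=None):
        pairs = []
        import pandas as pd

        prof_rows = []
        for i in range(n):
            g = random_gene(rng, 150, gene_id=f"g{i}")
            target = ks_values[i] if ks_values else float(rng.uniform(0.05, 0.6))
            div, _ = simulate_ortholog_pair(g, target, 0.2, code, seed=i)
            pairs.append(
                build_ortholog_pair(
                    g.gene_id, div.gene_id, translate(g, code), translate(div, code),
                    g.codons[:-1], div.codons[:-1], code,
                )
            )
            prof_rows.append({"gene_id": g.gene_id, "cai": 0.9 - 0.8 * target, "fop": 0.5})
        prof = pd.DataFrame(prof_rows).set_index("gene_id")
        return pairs, prof

    def test_filter_semantics(self, rng, code):
        pairs, prof = self._pairs(rng, code)
        kept, _ = filter_and_correlate(pairs, prof, ks_max=0.3)
        expected = sum(1 for p in pairs if not math.isnan(p.ks) and p.ks < 0.3)
        assert len(kept) == expected

    def test_all_saturated_gives_undefined(self, rng, code):
        pairs, prof = self._pairs(rng, code, n=4)
        kept, report = filter_and_correlate(pairs, prof, ks_max=0.0)
        assert kept.empty
        assert report["r"].isna().all()

    def test_planted_negative_ks_cai_correlation(self, rng, code):
        """Genes given high CAI were diverged less: r(Ks, CAI) < 0."""
        pairs, prof = self._pairs(rng, code, n=15)
        _, report = filter_and_correlate(pairs, prof, ks_max=2.0)
        row = report[(report.x == "ks") & (report.y == "cai")].iloc[0]
        assert row.r < -0.5
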