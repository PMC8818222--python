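"""Sponge network: probe construction, the duplex scorer against an
ungapped-enumeration oracle, seed matching, co-expression edges, network
assembly and over-representation."""

import numpy as np
import pandas as pd
import pytest

from csfcirc import sponge
from csfcirc.genes import GeneModel
from csfcirc.simulate import coupled_counts
from csfcirc.sponge import (
    JunctionProbe,
    assemble_network,
    build_probe,
    coexpression_edges,
    duplex_score,
    hypergeom_enrichment,
    predict_circ_mirna,
    predict_mirna_mrna,
    revcomp_rna,
    seed_site,
    spliced_circ_sequence,
    to_rna,
)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestProbe:
    def test_long_circ_probe_and_offset(self):
        seq = "A" * 170 + "C" * 30  # 200-nt single-exon circ
        probe = build_probe("c", seq, flank_nt=30)
        assert len(probe.sequence) == 60
        assert probe.junction_offset == 30
        assert probe.sequence == "C" * 30 + "A" * 30

    def test_short_circ_no_duplication(self):
        seq = "ACGU" * 10  # 40 nt
        probe = build_probe("c", seq, flank_nt=30)
        assert len(probe.sequence) == 40
        assert sorted(probe.sequence) == sorted(to_rna(seq))

    def test_minus_strand_equals_revcomp_oracle(self):
        gene = GeneModel(
            "G", "chr1", 100, 400, "-", ((100, 160), (220, 280), (340, 400))
        )
        genome = {"chr1": "".join(
            np.random.default_rng(0).choice(list("ACGT"), size=500)
        )}
        seq_minus = spliced_circ_sequence(
            "c", "chr1", 100, 400, "-", gene, genome
        )
        # independent path: plus-strand splice, then reverse complement
        plus = to_rna("".join(genome["chr1"][s:e] for s, e in gene.exons))
        assert seq_minus == revcomp_rna(plus)

    def test_junction_off_exon_boundary_rejected(self):
        gene = GeneModel("G", "chr1", 100, 400, "+", ((100, 200), (300, 400)))
        with pytest.raises(ValueError, match="exon boundaries"):
            spliced_circ_sequence("c", "chr1", 150, 400, "+", gene,
                                  {"chr1": "A" * 500})


class TestDuplexScorer:
    def perfect_pair(self, rng, probe_len=60, site_at=19):
        probe_seq = random_rna(rng, probe_len)
        window = probe_seq[site_at:site_at + 22]
        mirna = revcomp_rna(window)
        return mirna, JunctionProbe("c", probe_seq, junction_offset=30)

    def test_perfect_complement_closed_form(self):
        """22 WC pairs: score 5*15 + 5*7*4 = 215; energy -3/GC, -2/AU."""
        rng = np.random.default_rng(0)
        mirna, probe = self.perfect_pair(rng)
        hit = duplex_score(mirna, probe, score_min=170, energy_max=-30)
        assert hit is not None
        assert hit.score == pytest.approx(215.0)
        window = probe.sequence[19:41]
        gc = sum(b in "GC" for b in window)
        assert hit.energy == pytest.approx(-3.0 * gc - 2.0 * (22 - gc))
        assert hit.energy < -30
        assert hit.strict_seed

    def test_seed_mismatch_strict_vs_permissive(self):
        rng = np.random.default_rng(1)
        mirna, probe = self.perfect_pair(rng)
        # corrupt miRNA position 4 (inside the seed) to a non-pairing base
        pos = 3
        target = probe.sequence[19:41][::-1][pos]  # base opposite position 4
        for b in "ACGU":
            if b != sponge.RNA_COMPLEMENT[target] and not sponge.is_wobble(b, target):
                mutated = mirna[:pos] + b + mirna[pos + 1:]
                break
        assert duplex_score(mutated, probe, strict=True) is None
        hit = duplex_score(mutated, probe, strict=False)
        assert hit is not None and hit.score < 215.0

    def test_random_decoys_never_hit(self):
        rng = np.random.default_rng(2)
        n_hits = 0
        for _ in range(50):
            probe = JunctionProbe("c", random_rna(rng, 60), 30)
            decoy = random_rna(rng, 22)
            if duplex_score(decoy, probe, score_min=170, energy_max=-30) is not None:
                n_hits += 1
        assert n_hits == 0

    def test_spans_junction_flag(self):
        rng = np.random.default_rng(3)
        probe_seq = random_rna(rng, 60)
        probe = JunctionProbe("c", probe_seq, junction_offset=30)
        inside = revcomp_rna(probe_seq[34:56])  # entirely in the head flank
        crossing = revcomp_rna(probe_seq[19:41])
        hit_in = duplex_score(inside, probe, score_min=0, energy_max=0, strict=False)
        hit_x = duplex_score(crossing, probe, score_min=0, energy_max=0, strict=False)
        assert hit_in is not None and not hit_in.spans_junction
        assert hit_x is not None and hit_x.spans_junction

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_ungapped_enumeration_oracle(self, seed):
        """DP score >= the exhaustive ungapped-window optimum, with equality
        whenever the optimal alignment is gap-free (short random instances)."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(6, 16))
        n = int(rng.integers(8, 16))
        mirna = random_rna(rng, m)
        probe_seq = random_rna(rng, n)
        probe = JunctionProbe("c", probe_seq, junction_offset=n // 2)
        score, pairs = sponge._local_duplex_align(mirna, probe_seq)

        rev = mirna[::-1]

        def pscore(i, j):
            a, b = rev[i], probe_seq[j]
            w = 4.0 if 2 <= m - i <= 8 else 1.0
            if sponge.is_wc(a, b):
                return 5.0 * w
            if sponge.is_wobble(a, b):
                return 1.0 * w
            return -3.0 * w

        best = 0.0
        for off in range(-(m - 1), n):  # all diagonals, max subarray each
            run = 0.0
            for i in range(m):
                j = i + off
                if not 0 <= j < n:
                    run = 0.0
                    continue
                run = max(0.0, run) + pscore(i, j)
                best = max(best, run)
        assert score >= best - 1e-9
        gap_free = all(
            (p2 - p1, j2 - j1) == (-1, 1)
            for (p1, j1), (p2, j2) in zip(pairs, pairs[1:])
        )
        if gap_free:
            assert score == pytest.approx(best)

    def test_planted_cohort_pairs_recovered(self, cohort):
        genes = {g.gene_id: g for g in cohort.gene_models}
        circs = {c.junction_id: c for c in cohort.circs}
        probes = []
        for jid, _ in cohort.truth.planted_sites:
            c = circs[jid]
            seq = spliced_circ_sequence(
                jid, c.chrom, c.start, c.end, c.strand, genes[c.gene_id],
                cohort.genome,
            )
            probes.append(build_probe(jid, seq))
        hits = predict_circ_mirna(probes, cohort.mirnas)
        found = {(h.circ_id, h.mirna_id) for h in hits}
        assert set(cohort.truth.planted_sites) <= found  # sensitivity 1.0
        planted = [h for h in hits
                   if (h.circ_id, h.mirna_id) in set(cohort.truth.planted_sites)]
        assert all(h.spans_junction for h in planted)

    def test_threshold_monotonicity(self, cohort):
        genes = {g.gene_id: g for g in cohort.gene_models}
        c = next(x for x in cohort.circs
                 if x.junction_id == cohort.truth.planted_sites[0][0])
        seq = spliced_circ_sequence(
            c.junction_id, c.chrom, c.start, c.end, c.strand,
            genes[c.gene_id], cohort.genome,
        )
        probes = [build_probe(c.junction_id, seq)]
        loose = predict_circ_mirna(probes, cohort.mirnas, strict=False)
        strict = predict_circ_mirna(probes, cohort.mirnas, strict=True)
        assert len(strict) <= len(loose)
        assert predict_circ_mirna(probes, cohort.mirnas, score_min=1e9) == []
        tighter = predict_circ_mirna(probes, cohort.mirnas, score_min=200)
        assert {(h.circ_id, h.mirna_id) for h in tighter} <= {
            (h.circ_id, h.mirna_id) for h in loose
        }

    def test_empty_mirna_set_rejected(self):
        with pytest.raises(ValueError):
            predict_circ_mirna([], {})


class TestSeedMatching:
    MIRNA = "UAGCUUAUCAGACUGAUGUUGA"  # 22 nt

    def test_7mer_and_8mer_classes(self):
        site7 = seed_site(self.MIRNA)
        assert site7 == revcomp_rna(self.MIRNA[1:8])
        utr7 = "CCCC" + site7 + "GCCC"
        utr8 = "CCCC" + site7 + "ACCC"
        edges = predict_mirna_mrna({"m": self.MIRNA},
                                   {"g7": utr7, "g8": utr8, "g0": "C" * 20})
        by_gene = edges.set_index("gene_id")
        assert by_gene.loc["g7", "match_class"] == "7mer-m8"
        assert by_gene.loc["g8", "match_class"] == "8mer"
        assert "g0" not in by_gene.index

    def test_shuffled_utr_rate_matches_occurrence_probability(self):
        """Random-UTR hit frequency tracks the closed-form occurrence
        probability of a fixed 7-mer, ~1-(1-4^-7)^(L-6)."""
        rng = np.random.default_rng(4)
        L, trials = 300, 50
        hits = 0
        for _ in range(trials):
            mirna = random_rna(rng, 22)
            utr = random_rna(rng, L)
            edges = predict_mirna_mrna({"m": mirna}, {"g": utr})
            hits += len(edges) > 0
        expected = 1 - (1 - 0.25**7) ** (L - 6)
        assert abs(hits / trials - expected) < 0.07


class TestCoexpression:
    def make_pair(self, seed, rho=0.9, n=15):
        rng = np.random.default_rng(seed)
        circ = (1 + rng.negative_binomial(3, 3 / 43, size=n)) * (rng.random(n) < 0.6)
        partner = coupled_counts(circ.astype(float), mean=60.0, rho=rho, rng=rng)
        circ_fpkm = pd.DataFrame([circ * 2.0], index=["c"],
                                 columns=[f"s{i}" for i in range(n)])
        mrna_fpkm = pd.DataFrame([partner * 0.5], index=["g"],
                                 columns=[f"s{i}" for i in range(n)])
        return circ_fpkm, mrna_fpkm

    def test_planted_high_correlation_pair_recovered(self):
        passed = 0
        for seed in range(50):
            circ, mrna = self.make_pair(seed)
            table = coexpression_edges(circ, mrna)
            passed += bool(table["edge"].iloc[0])
        assert passed >= 40  # >= 80% of 50 seeds

    def test_null_edge_rate_below_one_percent(self):
        rng = np.random.default_rng(6)
        cols = [f"s{i}" for i in range(15)]
        circ = pd.DataFrame(rng.lognormal(2, 1, size=(20, 15)),
                            index=[f"c{i}" for i in range(20)], columns=cols)
        mrna = pd.DataFrame(rng.lognormal(2, 1, size=(25, 15)),
                            index=[f"g{i}" for i in range(25)], columns=cols)
        table = coexpression_edges(circ, mrna)
        assert len(table) == 500
        assert table["edge"].mean() <= 0.01

    def test_r_min_boundary_is_inclusive(self):
        circ, mrna = self.make_pair(1)
        r = coexpression_edges(circ, mrna, r_min=0.0, p_max=1.0)["r"].iloc[0]
        table = coexpression_edges(circ, mrna, r_min=abs(r), p_max=1.0)
        assert bool(table["edge"].iloc[0])  # |r| >= r_min with equality holds

    def test_too_few_shared_samples_skipped(self):
        circ = pd.DataFrame([[1.0, 2.0]], index=["c"], columns=["s1", "s2"])
        mrna = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["s1", "s2"])
        with pytest.warns(UserWarning, match="shared"):
            table = coexpression_edges(circ, mrna)
        assert len(table) == 0


class TestNetworkAssembly:
    def hit(self, circ, mirna):
        return sponge.DuplexHit(mirna, circ, 200.0, -40.0, (), True, True)

    def test_three_node_path(self):
        mm = pd.DataFrame(
            [{"mirna_id": "m1", "gene_id": "g1", "match_class": "8mer",
              "n_sites": 1}]
        )
        nodes, edges = assemble_network([self.hit("c1", "m1")], mm)
        assert set(nodes["node_id"]) == {"c1", "m1", "g1"}
        assert len(edges) == 2
        g = sponge.to_networkx(nodes, edges)
        assert list(g.neighbors("m1")) == ["c1", "g1"]

    def test_no_shared_mirna_disconnected(self):
        mm = pd.DataFrame(
            [{"mirna_id": "m2", "gene_id": "g1", "match_class": "7mer-m8",
              "n_sites": 1}]
        )
        nodes, edges = assemble_network([self.hit("c1", "m1")], mm)
        g = sponge.to_networkx(nodes, edges)
        import networkx as nx

        assert nx.number_connected_components(g) == 2

    def test_edge_conservation(self):
        mm = pd.DataFrame(
            [{"mirna_id": "m1", "gene_id": "g1", "match_class": "8mer",
              "n_sites": 1}]
        )
        hits = [self.hit("c1", "m1"), self.hit("c2", "m1")]
        nodes, edges = assemble_network(hits, mm)
        assert len(edges) == len(hits) + len(mm)
        assert set(edges["edge_type"]) == {"circ-mirna", "mirna-mrna"}

    def test_id_collision_across_classes_rejected(self):
        mm = pd.DataFrame(
            [{"mirna_id": "c1", "gene_id": "g1", "match_class": "8mer",
              "n_sites": 1}]
        )
        with pytest.raises(ValueError, match="both"):
            assemble_network([self.hit("c1", "m1")], mm)


class TestEnrichment:
    def test_closed_form_tail(self):
        universe = [f"g{i}" for i in range(10)]
        table = hypergeom_enrichment(
            universe[:3], {"s": set(universe[:3])}, universe
        )
        assert table["p_value"].iloc[0] == pytest.approx(1 / 120)

    def test_degenerate_and_disjoint(self):
        universe = ["a", "b", "c"]
        full = hypergeom_enrichment(universe, {"s": set(universe)}, universe)
        assert full["p_value"].iloc[0] == pytest.approx(1.0)
        disjoint = hypergeom_enrichment(["a"], {"s": {"b", "c"}}, universe)
        assert disjoint["p_value"].iloc[0] == pytest.approx(1.0)

    def test_list_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(["x"], {"s": {"a"}}, ["a", "b"])
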