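"""Network inference: correlation, motif scanning, assembly, statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from follireg3d.core_io import GenomicInterval, Pwm
from follireg3d.grn import (
    EnhGenePair,
    RegNetwork,
    TfEnhPair,
    assemble_grn,
    correlate_in_tad,
    enhancer_id,
    extract_core_tfs,
    motif_enrichment,
    permutation_test,
    scan_pwm,
    stability_score,
    variant_to_gene,
)

STAGES7 = list("ABCDEFG")


def consensus_pwm(consensus, name="TFX", p=0.9):
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for k, b in enumerate(consensus):
        mat[k, "ACGT".index(b)] = p
    return Pwm(name, mat)


def simple_tad_setup(n_enh, n_genes, rng, tad_span=10_000_000):
    """One shared TAD holding all enhancers and genes."""
    tads = [GenomicInterval("chr1", 0, tad_span, "tad_0")]
    enhancers = [
        GenomicInterval("chr1", 1000 + 2000 * k, 1600 + 2000 * k, f"e{k}")
        for k in range(n_enh)
    ]
    tss = [
        GenomicInterval("chr1", 5_000_000 + 3000 * k, 5_000_001 + 3000 * k, f"g{k}")
        for k in range(n_genes)
    ]
    return tads, enhancers, tss


class TestCorrelateInTad:
    def test_identical_profiles_link(self, rng):
        tads, enhancers, tss = simple_tad_setup(1, 1, rng)
        profile = rng.uniform(1, 100, 7)
        sig = pd.DataFrame([profile], index=["e0"], columns=STAGES7)
        expr = pd.DataFrame([profile], index=["g0"], columns=STAGES7)
        pairs, _ = correlate_in_tad(sig, enhancers, expr, tss, tads)
        assert len(pairs) == 1 and pairs[0].pearson_r == pytest.approx(1.0)

    def test_cross_tad_pairs_never_tested(self, rng):
        tads = [GenomicInterval("chr1", 0, 500_000, "t0"),
                GenomicInterval("chr1", 500_000, 1_000_000, "t1")]
        enhancers = [GenomicInterval("chr1", 1000, 1600, "e0")]
        tss = [GenomicInterval("chr1", 700_000, 700_001, "g0")]
        profile = rng.uniform(1, 100, 7)
        sig = pd.DataFrame([profile], index=["e0"], columns=STAGES7)
        expr = pd.DataFrame([profile], index=["g0"], columns=STAGES7)
        pairs, report = correlate_in_tad(sig, enhancers, expr, tss, tads)
        assert report["n_tested"] == 0 and pairs == []

    def test_constant_vectors_skipped(self, rng):
        tads, enhancers, tss = simple_tad_setup(1, 1, rng)
        sig = pd.DataFrame([[2.0] * 7], index=["e0"], columns=STAGES7)
        expr = pd.DataFrame([rng.uniform(1, 9, 7)], index=["g0"], columns=STAGES7)
        _, report = correlate_in_tad(sig, enhancers, expr, tss, tads)
        assert report["n_skipped_constant"] == 1 and report["n_tested"] == 0

    def test_planted_links_among_decoys(self, rng):
        """50 planted correlated pairs among 500 decoy pairs (one candidate
        pair per TAD): sensitivity >= 0.8, observed false-discovery
        proportion <= 0.1."""
        n_true, n_decoy = 50, 500
        n = n_true + n_decoy
        span = 20_000
        tads = [GenomicInterval("chr1", k * span, (k + 1) * span, f"t{k}")
                for k in range(n)]
        enhancers = [GenomicInterval("chr1", k * span + 1000, k * span + 1600, f"e{k}")
                     for k in range(n)]
        tss = [GenomicInterval("chr1", k * span + 10_000, k * span + 10_001, f"g{k}")
               for k in range(n)]
        base = rng.normal(0, 1.0, size=(n, 7))
        expr = pd.DataFrame(100 + 30 * base, index=[f"g{k}" for k in range(n)],
                            columns=STAGES7)
        sig_vals = 10 + 3 * (base + rng.normal(0, 0.2, base.shape))
        sig_vals[n_true:] = 10 + 3 * rng.normal(0, 1.0, size=(n_decoy, 7))
        sig = pd.DataFrame(sig_vals, index=[f"e{k}" for k in range(n)],
                           columns=STAGES7)
        pairs, report = correlate_in_tad(sig, enhancers, expr, tss, tads)
        assert report["n_tested"] == n
        found = {(p.enhancer.name, p.gene_id) for p in pairs}
        truth = {(f"e{k}", f"g{k}") for k in range(n_true)}
        sens = len(found & truth) / n_true
        fp = len(found - truth)
        assert sens >= 0.8
        assert fp / max(1, len(found)) <= 0.1

    def test_pure_null_rarely_discovers(self, rng):
        n = 300
        tads, enhancers, tss = simple_tad_setup(n, 30, rng)
        sig = pd.DataFrame(2.0 ** rng.normal(2, 1, (n, 7)),
                           index=[f"e{k}" for k in range(n)], columns=STAGES7)
        expr = pd.DataFrame(2.0 ** rng.normal(5, 1, (30, 7)),
                            index=[f"g{k}" for k in range(30)], columns=STAGES7)
        pairs, report = correlate_in_tad(sig, enhancers, expr, tss, tads)
        assert len(pairs) / report["n_tested"] <= 0.1


class TestScanPwm:
    def test_consensus_hit_at_origin(self):
        cons = "AAAAACGTACGT"  # non-palindromic
        pwm = consensus_pwm(cons)
        hits = scan_pwm({"s": cons}, pwm)
        assert len(hits) == 1
        h = hits[0]
        lods = np.log2(pwm.matrix / pwm.background[None, :])
        assert (h.position, h.strand) == (0, "+")
        assert h.score == pytest.approx(lods.max(axis=1).sum())

    def test_reverse_complement_strand_symmetry(self):
        pwm = consensus_pwm("AACCGGTTACGT")
        comp = str.maketrans("ACGT", "TGCA")
        seq = "TTT" + "AACCGGTTACGT" + "GGG"
        rc = seq.translate(comp)[::-1]
        fwd = scan_pwm({"s": seq}, pwm)
        rev = scan_pwm({"s": rc}, pwm)
        assert len(fwd) == len(rev) == 1
        assert fwd[0].score == pytest.approx(rev[0].score)
        assert {fwd[0].strand, rev[0].strand} == {"+", "-"}

    def test_short_sequence_no_hits(self):
        assert scan_pwm({"s": "ACGT"}, consensus_pwm("ACGTACGTACGT")) == []

    def test_n_windows_skipped(self):
        pwm = consensus_pwm("ACGTACGTACGT")
        assert scan_pwm({"s": "ACGTACGTACGN"}, pwm) == []

    def test_matches_position_rescan_oracle(self, rng):
        """Brute-force per-position rescan on 1 kb background sequence."""
        pwm = consensus_pwm("ATGCGTAACGTT", p=0.7)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        hits = scan_pwm({"s": seq}, pwm, score_fraction=0.55)
        lods = np.log2(pwm.matrix / pwm.background[None, :])
        thr = 0.55 * lods.max(axis=1).sum()
        comp = str.maketrans("ACGT", "TGCA")
        expected = set()
        L = len(pwm)
        for strand, s in (("+", seq), ("-", seq.translate(comp)[::-1])):
            for pos in range(len(s) - L + 1):
                score = sum(lods[k, "ACGT".index(s[pos + k])] for k in range(L))
                if score >= thr:
                    orig = pos if strand == "+" else len(seq) - L - pos
                    expected.add((orig, strand, round(score, 6)))
        got = {(h.position, h.strand, round(h.score, 6)) for h in hits}
        assert got == expected


class TestMotifEnrichment:
    def make_seqs(self, rng, n, planted_frac, consensus):
        seqs = {}
        for k in range(n):
            s = list("ACGT"[i] for i in rng.integers(0, 4, 200))
            if k < planted_frac * n:
                s[50:50 + len(consensus)] = list(consensus)
            seqs[f"s{k}"] = "".join(s)
        return seqs

    def test_planted_enrichment_matches_hypergeometric_tail(self, rng):
        cons = "ACGTTGCAACGT"
        pwm = consensus_pwm(cons)
        target = self.make_seqs(rng, 100, 0.8, cons)
        background = {f"b{k}": v for k, v in self.make_seqs(rng, 100, 0.05, cons).items()}
        pairs, table = motif_enrichment(target, background, [pwm])
        k = int(table.loc["TFX", "target_hits"])
        K = k + int(table.loc["TFX", "background_hits"])
        expected = stats.hypergeom.sf(k - 1, 200, K, 100)
        assert table.loc["TFX", "p"] == pytest.approx(expected)
        assert table.loc["TFX", "p"] < 1e-5
        assert {p.enhancer_id for p in pairs} == {
            s for s in target if cons in target[s]
        }

    def test_equal_rates_not_enriched(self, rng):
        cons = "ACGTTGCAACGT"
        pwm = consensus_pwm(cons)
        target = self.make_seqs(rng, 50, 0.4, cons)
        background = {f"b{k}": v for k, v in self.make_seqs(rng, 50, 0.4, cons).items()}
        _, table = motif_enrichment(target, background, [pwm])
        assert table.loc["TFX", "p"] >= 0.5

    def test_empty_target_errors(self):
        with pytest.raises(ValueError):
            motif_enrichment({}, {"b": "ACGT"}, [consensus_pwm("ACGTACGTACGT")])


def star_network():
    """Every TF->gene path crosses the single enhancer->gene edge."""
    net = RegNetwork()
    for k in range(9):
        net.tf_edges.add((f"T{k}", "E"))
    net.gene_edges.add(("E", "G"))
    return net


class TestAssembly:
    def test_single_path(self):
        net = assemble_grn(
            [TfEnhPair("T", "E", 1, 1e-9)],
            [EnhGenePair(GenomicInterval("chr1", 0, 100, "E"), "G", "t0", 0.9, 1e-4)],
        )
        assert net.paths() == {("T", "G")}
        assert net.summary()["n_paths"] == 1

    def test_disjoint_enhancers_no_paths(self):
        net = assemble_grn(
            [TfEnhPair("T", "E1", 1, 1e-9)],
            [EnhGenePair(GenomicInterval("chr1", 0, 100, "E2"), "G", "t0", 0.9, 1e-4)],
        )
        assert net.paths() == set()

    def test_path_count_matches_triple_enumeration(self, rng):
        net = RegNetwork()
        tfs = [f"T{k}" for k in range(10)]
        enhs = [f"E{k}" for k in range(30)]
        genes = [f"G{k}" for k in range(20)]
        for _ in range(60):
            net.tf_edges.add((str(rng.choice(tfs)), str(rng.choice(enhs))))
            net.gene_edges.add((str(rng.choice(enhs)), str(rng.choice(genes))))
        expected = {
            (t, g)
            for t, e in net.tf_edges
            for e2, g in net.gene_edges
            if e == e2
        }
        assert net.paths() == expected


class TestStability:
    def test_zero_edges_removed_gives_one(self):
        net = star_network()
        rep = stability_score(net, removal_fraction=0.05, trials=20, seed=0)
        assert rep.stability_score == 1.0  # floor(0.05 * 10) = 0 edges

    def test_star_network_matches_exact_expectation(self):
        """Exact expectation by enumerating every single-edge removal:
        dropping a TF edge loses 1 of 9 paths (score 8/9, 9 cases);
        dropping the shared enhancer->gene edge loses all (score 0,
        1 case) -> E[score] = 9/10 * 8/9 = 0.8."""
        net = star_network()
        rep = stability_score(net, removal_fraction=0.1, trials=4000, seed=1)
        assert rep.stability_score == pytest.approx(0.8, abs=0.02)

    def test_monotone_in_removal_fraction(self, rng):
        net = RegNetwork()
        for k in range(20):
            net.tf_edges.add((f"T{k % 5}", f"E{k}"))
            net.gene_edges.add((f"E{k}", f"G{k % 7}"))
        scores = [
            stability_score(net, f, trials=200, seed=3).stability_score
            for f in (0.05, 0.1, 0.2)
        ]
        assert scores[0] >= scores[1] >= scores[2]

    def test_invalid_fraction_errors(self):
        with pytest.raises(ValueError):
            stability_score(star_network(), removal_fraction=1.5)

    def test_deterministic_per_seed(self):
        net = star_network()
        a = stability_score(net, 0.2, trials=50, seed=7).stability_score
        b = stability_score(net, 0.2, trials=50, seed=7).stability_score
        assert a == b


def random_bipartite(rng, n_tf=8, n_enh=16, n_gene=12, m=40):
    net = RegNetwork()
    while len(net.tf_edges) < m:
        net.tf_edges.add((f"T{rng.integers(n_tf)}", f"E{rng.integers(n_enh)}"))
    while len(net.gene_edges) < m:
        net.gene_edges.add((f"E{rng.integers(n_enh)}", f"G{rng.integers(n_gene)}"))
    return net


class TestPermutation:
    def test_deterministic_per_seed(self, rng):
        net = random_bipartite(rng)
        p1, null1 = permutation_test(net, n_perm=50, seed=5)
        p2, null2 = permutation_test(net, n_perm=50, seed=5)
        assert p1 == p2 and np.array_equal(null1, null2)

    def test_degrees_preserved_in_every_replicate(self, rng):
        net = random_bipartite(rng)
        # check_degrees asserts per replicate inside the permutation loop
        permutation_test(net, n_perm=20, seed=2, check_degrees=True)

    def test_calibration_on_random_networks(self):
        """A network that IS random should give roughly uniform p."""
        ps = []
        for k in range(50):
            net = random_bipartite(np.random.default_rng(1000 + k))
            p, _ = permutation_test(net, n_perm=99, seed=k)
            ps.append(p)
        assert 0.3 <= np.mean(ps) <= 0.7

    def test_planted_circuit_distinct_from_random(self):
        """A redundant circuit (each TF reaching its target through four
        parallel enhancers) is wired unlike any degree-preserving null,
        which spreads those edges over distinct genes."""
        net = RegNetwork()
        for t in range(6):
            for e in range(4):
                eid = f"E{t}_{e}"
                net.tf_edges.add((f"T{t}", eid))
                net.gene_edges.add((eid, f"G{t}"))
        p, null = permutation_test(net, n_perm=400, seed=0)
        assert len(net.paths()) == 6
        assert np.mean(null) > 6  # rewiring diversifies targets
        assert p <= 0.01

    def test_tiny_layers_warn_nan(self):
        net = RegNetwork()
        net.tf_edges.add(("T", "E"))
        net.gene_edges.add(("E", "G"))
        with pytest.warns(UserWarning):
            p, _ = permutation_test(net, n_perm=10, seed=0)
        assert np.isnan(p)


class TestCoreTfs:
    def make_net(self):
        net = RegNetwork()
        for tf in ("T1", "T2"):
            net.tf_edges.add((tf, "E"))
        net.gene_edges.add(("E", "G1"))
        net.gene_edges.add(("E", "G2"))
        return net

    def enr(self, rows):
        return pd.DataFrame(rows).set_index("tf_name")

    def test_both_criteria_met(self):
        net = self.make_net()
        enr = self.enr([{"tf_name": "T1", "p": 1e-9}, {"tf_name": "T2", "p": 1e-9}])
        clusters = {"T1": 0, "G1": 0, "G2": 1, "T2": 3}
        core, table = extract_core_tfs(net, enr, {"T1", "T2"}, clusters, co_min=0.3)
        assert "T1" in core          # 50% of targets share its cluster
        assert "T2" not in core      # co-cluster fraction 0

    def test_enriched_but_not_deg_fails(self):
        net = self.make_net()
        enr = self.enr([{"tf_name": "T1", "p": 1e-9}, {"tf_name": "T2", "p": 0.5}])
        clusters = {"T1": 0, "G1": 0, "G2": 0, "T2": 0}
        core, _ = extract_core_tfs(net, enr, set(), clusters)
        assert core == set()

    def test_missing_from_clusters_fails(self):
        net = self.make_net()
        enr = self.enr([{"tf_name": "T1", "p": 1e-9}, {"tf_name": "T2", "p": 1e-9}])
        core, _ = extract_core_tfs(net, enr, {"T1", "T2"}, {"G1": 0, "G2": 0})
        assert core == set()


class TestVariantToGene:
    def test_locus_in_linked_enhancer(self):
        enh = GenomicInterval("chr1", 1000, 1600, "e0")
        links = [EnhGenePair(enh, "G1", "t0", 0.9, 1e-4),
                 EnhGenePair(enh, "G2", "t0", 0.8, 1e-3)]
        loci = [GenomicInterval("chr1", 1200, 1201, "rs1")]
        table = variant_to_gene(loci, [enh], links)
        assert sorted(table["gene_id"]) == ["G1", "G2"]

    def test_locus_outside_enhancers_no_rows(self):
        enh = GenomicInterval("chr1", 1000, 1600, "e0")
        links = [EnhGenePair(enh, "G1", "t0", 0.9, 1e-4)]
        loci = [GenomicInterval("chr1", 50_000, 50_001, "rs1")]
        assert len(variant_to_gene(loci, [enh], links)) == 0

    def test_matches_two_step_join_oracle(self, rng):
        enhancers = []
        for k in range(30):
            s = int(rng.integers(0, 100_000))
            enhancers.append(GenomicInterval("chr1", s, s + 600, f"e{k}"))
        links = [
            EnhGenePair(e, f"G{rng.integers(10)}", "t0", 0.5, 1e-3)
            for e in enhancers[::2]
        ]
        loci = [
            GenomicInterval("chr1", int(p), int(p) + 1, f"rs{k}")
            for k, p in enumerate(rng.integers(0, 100_000, size=50))
        ]
        table = variant_to_gene(loci, enhancers, links)
        expected = set()
        for lo in loci:
            for e in enhancers:
                if lo.overlaps(e):
                    for lk in links:
                        if lk.enhancer is e:
                            expected.add((lo.name, e.name, lk.gene_id))
        got = set(zip(table["locus"], table["enhancer"], table["gene_id"]))
        assert got == expected
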