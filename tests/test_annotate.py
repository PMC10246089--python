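import numpy as np
import pytest

from coexmux.annotate import (
    GeneLocus,
    classify_community,
    community_gene_set,
    community_summary,
    gene_distance,
    localization_tests,
    mean_pair_distance,
    same_chromosome_fraction,
    shared_eqtl_pairs,
    specialist_fraction,
)

LAYERS = ("pancreas", "salivary_gland", "mammary_gland", "skin")


def _community(unique_per_layer, shared_pairs=()):
    """Build a node set: unique_per_layer maps layer -> number of genes only
    there; shared_pairs is a list of (layer_a, layer_b, count)."""
    nodes = set()
    counter = 0
    for layer, count in unique_per_layer.items():
        for _ in range(count):
            nodes.add((f"u{counter}", layer))
            counter += 1
    for layer_a, layer_b, count in shared_pairs:
        for _ in range(count):
            nodes.add((f"s{counter}", layer_a))
            nodes.add((f"s{counter}", layer_b))
            counter += 1
    return nodes


class TestSpecialistFraction:
    def test_pure_single_layer_community(self):
        frac, tissue = specialist_fraction(_community({"pancreas": 5}))
        assert frac == 1.0 and tissue == "pancreas"

    def test_mixed_community_uses_dominant_layer(self):
        comm = _community(
            {"salivary_gland": 82, "pancreas": 1},
            shared_pairs=[("mammary_gland", "skin", 3)],
        )
        frac, tissue = specialist_fraction(comm)
        assert round(frac, 3) == 0.921 and tissue == "salivary_gland"

    def test_no_unique_genes_gives_zero(self):
        comm = _community({}, shared_pairs=[("pancreas", "skin", 4)])
        frac, tissue = specialist_fraction(comm)
        assert frac == 0.0 and tissue is None

    def test_tie_reports_lexicographically_first(self):
        comm = _community({"skin": 2, "pancreas": 2})
        frac, tissue = specialist_fraction(comm)
        assert tissue == "pancreas"
        summary = community_summary(1, comm)
        assert summary.specialist_tissues == ["pancreas", "skin"]

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError):
            specialist_fraction(set())


class TestClassify:
    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.792, "specialist"), (0.16, "generalist"), (0.5, "generalist"),
         (0.501, "specialist")],
    )
    def test_threshold_is_strict(self, fraction, expected):
        assert classify_community(fraction) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_community(1.2)


class TestCommunityGeneSet:
    def test_generalist_filters_by_layer_count(self):
        nodes = {("gA", layer) for layer in LAYERS[:3]}
        nodes |= {("gB", LAYERS[0])}
        assert community_gene_set(nodes, "generalist", min_layers=3) == ["gA"]

    def test_specialist_keeps_all_distinct_genes(self):
        nodes = {("gA", "pancreas"), ("gB", "pancreas"), ("gB", "skin")}
        assert community_gene_set(nodes, "specialist") == ["gA", "gB"]


class TestGeneDistance:
    def test_gap_adjacent_and_separated(self):
        a = GeneLocus("a", "1", 50, 100)
        assert gene_distance(a, GeneLocus("b", "1", 101, 120)) == 1
        assert gene_distance(a, GeneLocus("c", "1", 500, 600)) == 400
        assert gene_distance(GeneLocus("d", "1", 100, 200),
                             GeneLocus("e", "1", 500, 600)) == 300

    def test_cross_chromosome_undefined(self):
        a = GeneLocus("a", "1", 1, 10)
        assert gene_distance(a, GeneLocus("b", "2", 1, 10)) is None

    def test_overlap_clamps_to_zero_and_symmetry(self):
        a = GeneLocus("a", "1", 100, 300)
        b = GeneLocus("b", "1", 200, 250)
        assert gene_distance(a, b) == 0
        c = GeneLocus("c", "1", 900, 950)
        assert gene_distance(a, c) == gene_distance(c, a) == 600


class TestGroupStatistics:
    def _loci(self):
        return {
            "g1": GeneLocus("g1", "1", 100, 200),
            "g2": GeneLocus("g2", "1", 500, 600),
            "g3": GeneLocus("g3", "2", 100, 200),
            "g4": GeneLocus("g4", "2", 1000, 1100),
        }

    def test_same_chromosome_fraction_cases(self):
        loci = self._loci()
        assert same_chromosome_fraction(["g1", "g2"], loci) == 1.0
        assert same_chromosome_fraction(["g1", "g3"], loci) == 0.0
        # 2 same-chromosome pairs out of 6
        assert same_chromosome_fraction(["g1", "g2", "g3", "g4"], loci) == \
            pytest.approx(1 / 3)

    def test_mean_pair_distance_brute_force(self):
        loci = self._loci()
        # pairs: (g1,g2) gap 300; (g3,g4) gap 800
        assert mean_pair_distance(["g1", "g2", "g3", "g4"], loci) == \
            pytest.approx(550.0)
        assert mean_pair_distance(["g1", "g3"], loci) is None

    def test_fraction_needs_two_genes(self):
        with pytest.raises(ValueError):
            same_chromosome_fraction(["g1"], self._loci())

    def test_brute_force_on_random_groups(self):
        rng = np.random.default_rng(0)
        background = [
            GeneLocus(f"g{i}", str(rng.integers(1, 4)),
                      int(p := rng.integers(1, 10**6)), int(p + 500))
            for i in range(30)
        ]
        loci = {g.gene_id: g for g in background}
        for _ in range(5):
            genes = [f"g{i}" for i in rng.choice(30, size=7, replace=False)]
            # brute force via explicit double loop
            n_same, total, n_pairs = 0, 0.0, 0
            for i in range(7):
                for j in range(i):
                    a, b = loci[genes[i]], loci[genes[j]]
                    if a.chromosome == b.chromosome:
                        n_same += 1
                        total += gene_distance(a, b)
                    n_pairs += 1
            assert same_chromosome_fraction(genes, loci) == \
                pytest.approx(n_same / 21)
            expected = total / n_same if n_same else None
            got = mean_pair_distance(genes, loci)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected)


def _uniform_background(rng, n=80, n_chrom=4, length=10**7):
    out = []
    for i in range(n):
        start = int(rng.integers(1, length))
        out.append(
            GeneLocus(f"g{i:03d}", str(1 + i % n_chrom), start, start + 1000)
        )
    return out


class TestLocalizationTests:
    def test_random_group_is_unremarkable(self):
        rng = np.random.default_rng(1)
        background = _uniform_background(rng)
        genes = [f"g{i:03d}" for i in rng.choice(80, size=10, replace=False)]
        res = localization_tests(genes, background, n_rand=100, seed=3)
        assert res.z_x is None or abs(res.z_x) < 3.5
        assert res.z_d is None or abs(res.z_d) < 3.5

    def test_planted_tight_cluster_flags_chromosome(self):
        rng = np.random.default_rng(2)
        background = _uniform_background(rng)
        # place 5 genes contiguously on chromosome 1
        cluster = []
        pos = 5_000_000
        for k in range(5):
            cluster.append(GeneLocus(f"c{k}", "1", pos, pos + 1000))
            pos += 2000
        full = background + cluster
        res = localization_tests(
            [g.gene_id for g in cluster], full, n_rand=100, seed=4
        )
        assert res.z_d is not None and res.z_d <= -2
        flagged = [c for c in res.per_chromosome if c.bonferroni_significant]
        assert any(c.chromosome == "1" for c in flagged)

    def test_whole_background_randomization_degenerates(self):
        rng = np.random.default_rng(3)
        background = _uniform_background(rng, n=12, n_chrom=2)
        res = localization_tests(
            [g.gene_id for g in background], background, n_rand=20, seed=5
        )
        # every replicate reproduces the group exactly: sd 0, z undefined
        assert res.z_x is None and res.z_d is None

    def test_empirical_p_on_permutation_grid(self):
        rng = np.random.default_rng(4)
        background = _uniform_background(rng)
        genes = [f"g{i:03d}" for i in range(12)]
        res = localization_tests(genes, background, n_rand=50, seed=6)
        for chrom in res.per_chromosome:
            if chrom.p_empirical is not None:
                assert chrom.p_empirical == pytest.approx(
                    round(chrom.p_empirical * 50) / 50, abs=1e-12
                )
                assert 0.0 <= chrom.p_empirical <= 1.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        background = _uniform_background(rng)
        genes = [f"g{i:03d}" for i in range(8)]
        a = localization_tests(genes, background, n_rand=40, seed=9)
        b = localization_tests(genes, background, n_rand=40, seed=9)
        assert (a.x_c, a.z_x, a.d_c, a.z_d) == (b.x_c, b.z_x, b.d_c, b.z_d)

    def test_group_must_be_subset_of_background(self):
        rng = np.random.default_rng(6)
        background = _uniform_background(rng, n=10)
        with pytest.raises(KeyError):
            localization_tests(["missing", "g000"], background, seed=0)


class TestSharedEqtlPairs:
    def _rho(self):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = 0.6
        rho[0, 2] = rho[2, 0] = 0.4
        rho[1, 2] = rho[2, 1] = 0.7
        return rho

    def test_reports_only_correlated_pairs_with_shared_variants(self):
        eqtl = {
            "gene_id": ["gA", "gB", "gB", "gC"],
            "variant_id": ["v1", "v1", "v2", "v3"],
        }
        pairs = shared_eqtl_pairs(self._rho(), ["gA", "gB", "gC"], eqtl)
        assert pairs == [("gA", "gB", 0.6, ["v1"])]

    def test_threshold_is_strict_and_configurable(self):
        eqtl = {"gene_id": ["gA", "gC"], "variant_id": ["v9", "v9"]}
        assert shared_eqtl_pairs(self._rho(), ["gA", "gB", "gC"], eqtl) == []
        pairs = shared_eqtl_pairs(
            self._rho(), ["gA", "gB", "gC"], eqtl, r_min=0.3
        )
        assert pairs == [("gA", "gC", 0.4, ["v9"])]

    def test_unknown_gene_rejected(self):
        eqtl = {"gene_id": ["nope"], "variant_id": ["v1"]}
        with pytest.raises(KeyError):
            shared_eqtl_pairs(self._rho(), ["gA", "gB", "gC"], eqtl)
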