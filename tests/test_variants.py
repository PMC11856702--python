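import itertools

import numpy as np
import pytest

import ferment_rank as fr
from ferment_rank.variants import (
    ContrastResult,
    GenotypeMatrix,
    GenotypeState,
    VariantSite,
    _classify_gt,
    aggregate_genes,
    discriminating_sites,
    filter_nonsynonymous,
    quality_filter,
    read_genotype_tsv,
    strict_rule_false_positive_rate,
    write_genotype_tsv,
)

REF, HOM, HET, NO = (
    GenotypeState.REF_CONSISTENT,
    GenotypeState.HOM_ALT,
    GenotypeState.HET,
    GenotypeState.LOW_QUALITY,
)


def make_matrix(rows, samples=None, sites=None, depths=None):
    rows = np.asarray(rows, dtype=np.int8)
    n_sites, n_samples = rows.shape
    if samples is None:
        samples = tuple(f"S{i + 1}" for i in range(n_samples))
    if sites is None:
        sites = tuple(
            VariantSite("chrI", 100 * (i + 1), "A", "T", qual=60.0, mapping_quality=50.0,
                        consequence="nonsynonymous", gene=f"G{i + 1}")
            for i in range(n_sites)
        )
    return GenotypeMatrix(sites=sites, samples=samples, states=rows, depths=depths)


def oracle_rule(a_states, b_states):
    """Independent brute-force statement of the contrast rule: one group's
    members all share one identical mutation state that the other group does
    not contain; sites touching a low-quality call are skipped."""
    if NO in a_states or NO in b_states:
        return set()
    hits = set()
    for direction, share, other in (("A->B", a_states, b_states), ("B->A", b_states, a_states)):
        for s in (HOM, HET):
            if all(x == s for x in share) and all(x != s for x in other):
                hits.add((direction, s))
    return hits


class TestGTClassification:
    @pytest.mark.parametrize(
        "gt,alt_index,expected",
        [
            ((0, 0), 1, REF),
            ((1, 1), 1, HOM),
            ((0, 1), 1, HET),
            ((1, 0), 1, HET),
            ((None, None), 1, NO),
            (None, 1, NO),
            ((2, 2), 1, GenotypeState.OTHER_ALT),
            ((2, 2), 2, HOM),
            ((0, 2), 2, HET),
            # 1/2 at a two-alt record is hom-alt for neither decomposed row
            ((1, 2), 1, GenotypeState.OTHER_ALT),
            ((1, 2), 2, GenotypeState.OTHER_ALT),
        ],
    )
    def test_decomposition_rule(self, gt, alt_index, expected):
        assert _classify_gt(gt, alt_index) == expected


class TestQualityFilter:
    def test_qual_below_threshold_removed(self):
        sites = (
            VariantSite("chrI", 1, "A", "T", qual=19.9, mapping_quality=50.0),
            VariantSite("chrI", 2, "A", "T", qual=20.0, mapping_quality=50.0),
        )
        m = make_matrix([[HOM], [HOM]], samples=("S1",), sites=sites)
        out = quality_filter(m)
        assert out.n_sites == 1 and out.sites[0].pos == 2

    def test_boundary_values_inclusive(self):
        sites = (VariantSite("chrI", 1, "A", "T", qual=20.0, mapping_quality=30.0),)
        m = make_matrix([[HOM, REF]], samples=("S1", "S2"), sites=sites,
                        depths=np.array([[10, 10]]))
        out = quality_filter(m, min_depth=10, min_qual=20.0, min_mq=30.0)
        assert out.n_sites == 1
        np.testing.assert_array_equal(out.states, [[HOM, REF]])

    def test_low_mapping_quality_removed(self):
        sites = (VariantSite("chrI", 1, "A", "T", qual=60.0, mapping_quality=29.9),)
        m = make_matrix([[HOM]], samples=("S1",), sites=sites)
        assert quality_filter(m).n_sites == 0

    def test_low_depth_demotes_cell_not_site(self):
        sites = (VariantSite("chrI", 1, "A", "T", qual=60.0, mapping_quality=50.0),)
        m = make_matrix([[HOM, HET]], samples=("S1", "S2"), sites=sites,
                        depths=np.array([[9, 30]]))
        out = quality_filter(m)
        np.testing.assert_array_equal(out.states, [[NO, HET]])

    def test_planted_failure_counts(self):
        # 100 sites, 40 planted below the QUAL threshold -> 60 survive
        rng = np.random.default_rng(0)
        fail = rng.choice(100, size=40, replace=False)
        sites = tuple(
            VariantSite("chrI", i + 1, "A", "T",
                        qual=10.0 if i in fail else 60.0, mapping_quality=50.0)
            for i in range(100)
        )
        m = make_matrix(np.full((100, 2), REF), samples=("S1", "S2"), sites=sites)
        assert quality_filter(m).n_sites == 60

    def test_negative_threshold_rejected(self):
        m = make_matrix([[REF]], samples=("S1",))
        with pytest.raises(ValueError):
            quality_filter(m, min_depth=-1)

    def test_missing_quality_fields_pass(self):
        sites = (VariantSite("chrI", 1, "A", "T", qual=None, mapping_quality=None),)
        m = make_matrix([[HOM]], samples=("S1",), sites=sites)
        assert quality_filter(m).n_sites == 1


class TestDiscriminatingSites:
    GROUP_A = ("S1", "S2", "S3")
    GROUP_B = ("S4", "S5", "S6")

    def test_spec_positive_example(self):
        m = make_matrix([[HOM, HOM, HOM, REF, REF, HET]])
        res = discriminating_sites(m, self.GROUP_A, self.GROUP_B)
        assert res.n_sites_discriminating == 1
        assert res.hits[0].shared_state == HOM
        assert res.hits[0].direction == "A->B"

    def test_non_identical_group_does_not_discriminate(self):
        m = make_matrix([[HOM, HET, HOM, REF, REF, REF]])
        res = discriminating_sites(m, self.GROUP_A, self.GROUP_B)
        assert res.n_sites_discriminating == 0

    def test_het_is_a_distinct_mutation_state(self):
        # A all-HET vs B without HET discriminates even if B carries HOM;
        # B is not internally identical, so no mirror-direction hit
        m = make_matrix([[HET, HET, HET, HOM, REF, REF]])
        res = discriminating_sites(m, self.GROUP_A, self.GROUP_B)
        assert {(h.direction, h.shared_state) for h in res.hits} == {("A->B", HET)}

    def test_exhaustive_oracle_equivalence(self):
        # all 4^3 x 4^3 = 4096 state combinations at a single site
        combos = list(itertools.product((REF, HOM, HET, NO), repeat=3))
        rows = []
        expected = []
        for a in combos:
            for b in combos:
                rows.append(list(a) + list(b))
                expected.append(oracle_rule(a, b))
        m = make_matrix(rows)
        res = discriminating_sites(m, self.GROUP_A, self.GROUP_B)
        got: dict[int, set] = {}
        for h in res.hits:
            got.setdefault(h.site_index, set()).add((h.direction, h.shared_state))
        for i, exp in enumerate(expected):
            assert got.get(i, set()) == exp, f"mismatch at combination {i}"

    def test_group_swap_mirrors_directions(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.choice([REF, HOM, HET, NO], size=(200, 6), p=[0.5, 0.2, 0.2, 0.1]))
        r1 = discriminating_sites(m, self.GROUP_A, self.GROUP_B)
        r2 = discriminating_sites(m, self.GROUP_B, self.GROUP_A)
        assert {h.site_index for h in r1.hits} == {h.site_index for h in r2.hits}
        flip = {"A->B": "B->A", "B->A": "A->B"}
        assert {(h.site_index, h.direction) for h in r1.hits} == {
            (h.site_index, flip[h.direction]) for h in r2.hits
        }

    def test_invariant_to_site_and_sample_order(self):
        rng = np.random.default_rng(2)
        states = rng.choice([REF, HOM, HET], size=(50, 6), p=[0.5, 0.3, 0.2])
        m = make_matrix(states)
        r1 = discriminating_sites(m, self.GROUP_A, self.GROUP_B)
        site_perm = rng.permutation(50)
        m2 = GenotypeMatrix(
            sites=tuple(m.sites[i] for i in site_perm),
            samples=m.samples,
            states=states[site_perm],
        )
        r2 = discriminating_sites(m2, ("S3", "S1", "S2"), ("S6", "S5", "S4"))
        assert {h.site.key for h in r1.hits} == {h.site.key for h in r2.hits}

    def test_monotone_in_group_b_growth(self):
        rng = np.random.default_rng(3)
        states = rng.choice([REF, HOM, HET], size=(300, 7), p=[0.45, 0.3, 0.25])
        samples = tuple(f"S{i + 1}" for i in range(7))
        m = make_matrix(states, samples=samples)
        small = discriminating_sites(m, self.GROUP_A, ("S4", "S5"))
        large = discriminating_sites(m, self.GROUP_A, ("S4", "S5", "S6"))
        ab_small = {h.site_index for h in small.hits if h.direction == "A->B"}
        ab_large = {h.site_index for h in large.hits if h.direction == "A->B"}
        assert ab_large <= ab_small

    def test_low_quality_site_excluded_when_full_groups_required(self):
        m = make_matrix([[HOM, HOM, HOM, REF, REF, NO]])
        res = discriminating_sites(m, self.GROUP_A, self.GROUP_B, require_full_groups=True)
        assert res.n_sites_discriminating == 0
        assert res.n_excluded_low_quality == 1
        relaxed = discriminating_sites(m, self.GROUP_A, self.GROUP_B, require_full_groups=False)
        assert relaxed.n_sites_discriminating == 1

    def test_majority_threshold_variant(self):
        m = make_matrix([[HOM, HOM, HET, REF, REF, REF]])
        strict = discriminating_sites(m, self.GROUP_A, self.GROUP_B)
        assert strict.n_sites_discriminating == 0
        relaxed = discriminating_sites(m, self.GROUP_A, self.GROUP_B, min_shared_fraction=0.6)
        assert relaxed.n_sites_discriminating == 1

    def test_overlapping_groups_rejected(self):
        m = make_matrix([[REF] * 6])
        with pytest.raises(ValueError, match="overlap"):
            discriminating_sites(m, ("S1", "S2"), ("S2", "S3"))

    def test_analytic_false_positive_rate(self):
        # the strict rule's false-positive probability on i.i.d. states has a
        # closed form; a large simulated background must agree
        probs = {REF: 0.55, HOM: 0.25, HET: 0.15, NO: 0.05}
        p = strict_rule_false_positive_rate(probs, 3, 3)
        cfg = fr.GenotypeSimConfig(
            n_sites=10000, n_planted=0, n_planted_genes=0,
            background_hom=0.25, background_het=0.15, missing_rate=0.05,
            exclude_background_contrast=False, seed=7,
        )
        m, _ = fr.simulate_genotypes(cfg)
        res = discriminating_sites(m, ("S1", "S25", "S33"), ("S18", "S20", "S35"))
        n_fp = len({h.site_index for h in res.hits})
        expected = 10000 * p
        sd = np.sqrt(10000 * p * (1 - p))
        assert abs(n_fp - expected) < 4 * sd


class TestConsequenceAndGenes:
    def _contrast_with(self, consequences):
        sites = tuple(
            VariantSite("chrI", i + 1, "A", "T", consequence=c, gene=f"G{i + 1}")
            for i, c in enumerate(consequences)
        )
        m = make_matrix([[HOM, HOM, HOM, REF, REF, REF]] * len(sites), sites=sites)
        return discriminating_sites(m, ("S1", "S2", "S3"), ("S4", "S5", "S6"))

    def test_nonsynonymous_filter_counts(self):
        res = self._contrast_with(["nonsynonymous"] * 5 + ["synonymous"] * 3)
        out = filter_nonsynonymous(res)
        assert out.n_sites_discriminating == 5

    def test_empty_and_identity_cases(self):
        empty = ContrastResult(hits=(), group_a=("a",), group_b=("b",), n_sites_tested=0)
        assert filter_nonsynonymous(empty).hits == ()
        allns = self._contrast_with(["nonsynonymous"] * 4)
        assert filter_nonsynonymous(allns).n_sites_discriminating == 4

    def test_unannotated_sites_dropped_and_counted(self):
        res = self._contrast_with(["nonsynonymous", None, None])
        out = filter_nonsynonymous(res)
        assert out.n_sites_discriminating == 1
        assert out.n_excluded_unannotated == 2

    def test_gene_aggregation_counts(self):
        sites = tuple(
            VariantSite("chrI", i + 1, "A", "T", consequence="nonsynonymous", gene=g)
            for i, g in enumerate(["SEO1"] * 4 + ["COX10"])
        )
        m = make_matrix([[HOM, HOM, HOM, REF, REF, REF]] * 5, sites=sites)
        res = discriminating_sites(m, ("S1", "S2", "S3"), ("S4", "S5", "S6"))
        counts = aggregate_genes(res)
        assert counts == {"SEO1": 4, "COX10": 1}

    def test_every_site_distinct_gene(self):
        res = self._contrast_with(["nonsynonymous"] * 6)
        counts = aggregate_genes(res)
        assert len(counts) == 6 and all(v == 1 for v in counts.values())

    def test_no_sites_empty_aggregation(self):
        empty = ContrastResult(hits=(), group_a=("a",), group_b=("b",), n_sites_tested=0)
        assert aggregate_genes(empty) == {}


class TestTSVRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        states = rng.choice([REF, HOM, HET, NO], size=(20, 4))
        sites = tuple(
            VariantSite("chrII", 10 * (i + 1), "G", "C", consequence="synonymous", gene=f"g{i}")
            for i in range(20)
        )
        m = make_matrix(states, samples=("S1", "S2", "S3", "S4"), sites=sites)
        path = tmp_path / "m.tsv"
        write_genotype_tsv(m, path)
        back = read_genotype_tsv(path)
        np.testing.assert_array_equal(back.states, m.states)
        assert back.samples == m.samples
        assert all(a.key == b.key for a, b in zip(back.sites, m.sites))
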