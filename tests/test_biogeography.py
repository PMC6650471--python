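"""Isolation-by-distance machinery: p-distance, haversine, Mantel test and
correlogram, Sturge's rule."""
import itertools

import numpy as np
import pytest
from skbio.stats.distance import DistanceMatrix as SkbioDM, mantel as skb_mantel

from cryodiv import (
    Alignment,
    GeoSites,
    MEAN_EARTH_RADIUS_KM,
    genetic_distance_matrix,
    geographic_distance_matrix,
    haversine_km,
    ibd_analysis,
    mantel,
    mantel_correlogram,
    simulate_ibd_sequences,
    sturges_classes,
    transect_sites,
)
from cryodiv.biogeography import _pearson
from cryodiv.exceptions import (
    ComparabilityError,
    DegenerateError,
    MappingError,
)
from cryodiv.io import DistanceMatrix
from cryodiv.synthetic import SyntheticConfig


class TestGeneticDistance:
    def test_identical_sequences(self):
        aln = Alignment(("a", "b"), ("ACGT", "ACGT"))
        assert genetic_distance_matrix(aln).values[0, 1] == 0.0

    def test_one_mismatch_in_four(self):
        aln = Alignment(("a", "b"), ("ACGT", "ACGA"))
        assert genetic_distance_matrix(aln).values[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_of_gaps_and_ambiguities(self):
        # position 3 (gap in a, N in b) is dropped pairwise; of the 4
        # comparable sites only T/A mismatches
        aln = Alignment(("a", "b"), ("AC-GT", "ACNGA"))
        assert genetic_distance_matrix(aln).values[0, 1] == pytest.approx(0.25)

    def test_u_equivalent_to_t(self):
        aln = Alignment(("a", "b"), ("ACGU", "ACGT"))
        assert genetic_distance_matrix(aln).values[0, 1] == 0.0

    def test_complete_deletion_mode(self):
        aln = Alignment(("a", "b", "c"), ("ACGT", "AC-T", "GCGT"))
        dm = genetic_distance_matrix(aln, deletion="complete")
        # column 3 (gap in b) removed for every pair
        assert dm[("a", "c")] == pytest.approx(1 / 3)

    def test_no_comparable_sites(self):
        aln = Alignment(("a", "b"), ("AC--", "--GT"))
        with pytest.raises(ComparabilityError):
            genetic_distance_matrix(aln)

    def test_clade_scale_pair_count(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        seqs = tuple("".join(bases[rng.integers(0, 4, 60)]) for _ in range(96))
        aln = Alignment(tuple(f"s{i}" for i in range(96)), seqs)
        assert genetic_distance_matrix(aln).n_pairs == 4560


class TestGeographicDistance:
    def test_pole_to_pole_is_half_circumference(self):
        assert haversine_km(90, 0, -90, 0) == pytest.approx(
            np.pi * MEAN_EARTH_RADIUS_KM
        )

    def test_one_degree_longitude_on_equator(self):
        assert haversine_km(0, 0, 0, 1) == pytest.approx(
            np.pi * MEAN_EARTH_RADIUS_KM / 180, abs=1e-6
        )

    def test_same_site_pairs_zero(self):
        sites = GeoSites({"x": (0.0, 0.0), "y": (10.0, 10.0)})
        dm = geographic_distance_matrix(
            sites, {"s1": "x", "s2": "x", "s3": "y"}
        )
        assert dm[("s1", "s2")] == 0.0
        assert dm[("s1", "s3")] > 0

    def test_unmapped_sequence(self):
        sites = GeoSites({"x": (0.0, 0.0)})
        with pytest.raises(MappingError):
            geographic_distance_matrix(sites, {"s1": "nowhere"})

    def test_transect_spacing_exact(self):
        sites = transect_sites(5, spacing_km=300.0)
        ids = sites.site_ids
        for a, b in zip(ids, ids[1:]):
            assert haversine_km(*sites[a], *sites[b]) == pytest.approx(
                300.0, abs=1e-6
            )


class TestMantel:
    def test_identical_matrices(self, random_distance_matrix):
        dm = random_distance_matrix(8, seed=0)
        res = mantel(dm, dm, n_permutations=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)  # minimum attainable

    def test_affine_transform_gives_r_one(self, random_distance_matrix):
        dm = random_distance_matrix(6, seed=3)
        dy = DistanceMatrix(dm.labels, 2.5 * dm.values)
        assert mantel(dm, dy, 9, seed=0).r == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, random_distance_matrix):
        dx = random_distance_matrix(7, seed=4)
        dy = random_distance_matrix(7, seed=5)
        assert mantel(dx, dy, 9, seed=0).r == pytest.approx(
            mantel(dy, dx, 9, seed=0).r
        )

    def test_zero_variance_rejected(self, make_distance_matrix):
        dm = make_distance_matrix(list("abcd"), [1.0] * 6)
        other = make_distance_matrix(list("abcd"), [1, 2, 3, 4, 5, 6])
        with pytest.raises(DegenerateError):
            mantel(dm, other, 9, seed=0)

    def test_label_alignment(self, random_distance_matrix):
        dx = random_distance_matrix(5, seed=6)
        perm = [3, 1, 4, 0, 2]
        dy = DistanceMatrix(
            [dx.labels[i] for i in perm],
            dx.values[np.ix_(perm, perm)],
        )
        assert mantel(dx, dy, 9, seed=0).r == pytest.approx(1.0)

    def test_exhaustive_permutation_oracle_n4(self, random_distance_matrix):
        dx = random_distance_matrix(4, seed=7)
        dy = random_distance_matrix(4, seed=8)
        iu = np.triu_indices(4, k=1)
        x = dx.values[iu]
        r_obs = _pearson(x, dy.values[iu])
        r_all = [
            _pearson(x, dy.values[np.ix_(p, p)][iu])
            for p in itertools.permutations(range(4))
        ]
        p_exact = np.mean([r >= r_obs - 1e-12 for r in r_all])
        res = mantel(dx, dy, 9999, seed=0)
        assert res.p == pytest.approx(p_exact, abs=0.02)

    def test_r_matches_skbio(self, random_distance_matrix):
        dx = random_distance_matrix(9, seed=9)
        dy = random_distance_matrix(9, seed=10)
        ours = mantel(dx, dy, 99, seed=0)
        r_skb, p_skb, _ = skb_mantel(
            SkbioDM(dx.values, ids=list(dx.labels)),
            SkbioDM(dy.values, ids=list(dy.labels)),
            permutations=999, alternative="greater",
        )
        assert ours.r == pytest.approx(r_skb, abs=1e-10)


class TestSturges:
    @pytest.mark.parametrize("n_pairs,expected", [
        (1, 1),
        (2, 2),
        (120, 8),
        (1326, 12),   # the documented ceil convention
        (4560, 14),   # 96-sequence clade
    ])
    def test_rule(self, n_pairs, expected):
        assert sturges_classes(n_pairs) == expected


class TestCorrelogram:
    @pytest.fixture
    def ibd_instance(self):
        cfg = SyntheticConfig(
            seed=14, n_sites=8, seqs_per_site=2, seq_length=400,
            ibd_slope_beta=5e-6, site_noise=0.002,
        )
        aln, membership = simulate_ibd_sequences(cfg)
        sites = transect_sites(8)
        return (
            genetic_distance_matrix(aln),
            geographic_distance_matrix(sites, membership),
        )

    def test_classes_partition_all_pairs(self, ibd_instance):
        d_gen, d_geo = ibd_instance
        classes = mantel_correlogram(d_gen, d_geo, 49, seed=0)
        assert len(classes) == sturges_classes(d_gen.n_pairs)
        assert sum(c.n_pairs for c in classes) == d_gen.n_pairs

    def test_bonferroni_is_global_correction(self, ibd_instance):
        d_gen, d_geo = ibd_instance
        classes = mantel_correlogram(d_gen, d_geo, 199, seed=1)
        k = len(classes)
        for c in classes:
            if c.n_pairs:
                assert c.p_bonferroni == pytest.approx(min(1.0, k * c.p_raw))
                assert c.significant == (c.p_bonferroni <= 0.05)
                assert c.midpoint_km == pytest.approx(
                    (c.lower_km + c.upper_km) / 2
                )

    def test_strong_structure_detected_in_first_class(self, ibd_instance):
        d_gen, d_geo = ibd_instance
        classes = mantel_correlogram(d_gen, d_geo, 199, seed=2)
        assert classes[0].r > 0
        assert classes[0].significant

    def test_empty_class_flagged(self, make_distance_matrix):
        # geographic distances leave a gap so one class has no pairs
        rng = np.random.default_rng(15)
        n = 40
        geo = np.zeros((n, n))
        half = n // 2
        geo[:half, half:] = 1000.0  # only 0 and 1000 km occur
        geo[half:, :half] = 1000.0
        pts = rng.normal(size=(n, 2))
        gen = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = [f"s{i}" for i in range(n)]
        classes = mantel_correlogram(
            DistanceMatrix(labels, gen), DistanceMatrix(labels, geo), 19, seed=0
        )
        empties = [c for c in classes if c.n_pairs == 0]
        assert empties
        for c in empties:
            assert np.isnan(c.r) and not c.significant


class TestIbdAnalysis:
    def test_full_chain_metadata(self):
        cfg = SyntheticConfig(
            seed=16, n_sites=6, seqs_per_site=2, seq_length=300,
            ibd_slope_beta=5e-6, site_noise=0.002,
        )
        aln, membership = simulate_ibd_sequences(cfg)
        res = ibd_analysis(
            aln, transect_sites(6), membership, n_permutations=99, seed=3
        )
        assert res.metadata["n_sequences"] == 12
        assert res.metadata["n_sites"] == 6
        assert res.metadata["n_pairs"] == 66
        assert res.metadata["n_classes"] == sturges_classes(66)
        assert len(res.correlogram) == res.metadata["n_classes"]
        assert res.mantel.r > 0

    def test_single_site_degenerate(self):
        cfg = SyntheticConfig(
            seed=17, n_sites=4, seqs_per_site=2, seq_length=200,
            ibd_slope_beta=0.0, site_noise=0.01,
        )
        aln, _ = simulate_ibd_sequences(cfg)
        one_site = GeoSites({"only": (0.0, 0.0)})
        membership = {s: "only" for s in aln.seq_ids}
        with pytest.raises(DegenerateError):
            ibd_analysis(aln, one_site, membership, n_permutations=9, seed=0)
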