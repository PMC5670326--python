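"""Distances, PCoA, AMOVA/PhiPT and Mantel against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from epiterroir import popgen
from epiterroir.popgen import DistanceMatrix

from conftest import binary_frame


# ---------------------------------------------------------------------------
# binary distances

class TestBinaryDistance:
    def test_identical_rows_are_at_zero(self):
        prof = binary_frame([[1, 0, 1], [1, 0, 1]])
        d = popgen.binary_distance_matrix(prof)
        assert d.values[0, 1] == 0

    def test_mismatch_count(self):
        prof = binary_frame([[1, 0, 1], [0, 1, 1]])
        d = popgen.binary_distance_matrix(prof)
        assert d.values[0, 1] == 2

    def test_missing_rescales_to_all_locus_scale(self):
        # 10N vs 11N over 3 loci: 1 mismatch over 2 shared -> 1 * 3/2
        prof = binary_frame([[1, 0, None], [1, 1, None]])
        d = popgen.binary_distance_matrix(prof)
        assert d.values[0, 1] == pytest.approx(1.5)

    def test_no_shared_loci_is_an_error(self):
        prof = binary_frame([[1, None], [None, 1]], samples=["a", "b"])
        with pytest.raises(ValueError, match="'a' and 'b'"):
            popgen.binary_distance_matrix(prof)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(3)
        prof = binary_frame(rng.integers(0, 2, (8, 30)).tolist())
        d = popgen.binary_distance_matrix(prof)
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)


# ---------------------------------------------------------------------------
# PCoA

class TestPcoa:
    def test_collinear_points_load_on_one_axis(self):
        d = DistanceMatrix(np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float),
                           ["a", "b", "c"])
        ordn = popgen.pcoa(d)
        assert ordn.proportion_explained[0] == pytest.approx(1.0)

    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 2))
        diff = pts[:, None, :] - pts[None, :, :]
        d = DistanceMatrix(np.sqrt((diff ** 2).sum(-1)), [str(i) for i in range(10)])
        ordn = popgen.pcoa(d)
        rec = ordn.coordinates.values[:, :2]
        from scipy.spatial import procrustes
        _, _, disparity = procrustes(pts, rec)
        assert disparity < 1e-15

    def test_duplicated_sample_is_coincident(self):
        prof = binary_frame([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        ordn = popgen.pcoa(popgen.binary_distance_matrix(prof))
        assert np.allclose(ordn.coordinates.iloc[0], ordn.coordinates.iloc[1])

    def test_euclidean_input_has_no_negative_eigenvalues(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 4))
        diff = pts[:, None, :] - pts[None, :, :]
        d = DistanceMatrix(np.sqrt((diff ** 2).sum(-1)), [str(i) for i in range(12)])
        ordn = popgen.pcoa(d)
        scale = max(1.0, float(ordn.eigenvalues.max()))
        assert (ordn.eigenvalues > -1e-9 * scale).all()

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        prof = binary_frame(rng.integers(0, 2, (9, 40)).tolist())
        d = popgen.binary_distance_matrix(prof)
        ours = popgen.pcoa(d)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.values, d.labels))
        n = min(3, len(ours.proportion_explained))
        assert np.allclose(
            ours.proportion_explained[:n],
            ref.proportion_explained.values[:n], atol=1e-8,
        )


# ---------------------------------------------------------------------------
# AMOVA

def amova_oracle_two_level(d2, groups):
    """Brute-force variance components from the mean-square equations."""
    n = len(groups)
    labels = sorted(set(groups))
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    sizes = []
    for g in labels:
        idx = [i for i, x in enumerate(groups) if x == g]
        sizes.append(len(idx))
        ss_within += sum(
            d2[i, j] for i, j in itertools.combinations(idx, 2)
        ) / len(idx)
    ss_among = ss_total - ss_within
    df_a, df_w = len(labels) - 1, n - len(labels)
    ms_a, ms_w = ss_among / df_a, ss_within / df_w
    n0 = (n - sum(s * s for s in sizes) / n) / df_a
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n0
    return {"ss_among": ss_among, "ss_within": ss_within,
            "sigma_a": sigma_a, "sigma_w": sigma_w,
            "phipt": max(sigma_a, 0) / (max(sigma_a, 0) + max(sigma_w, 0))}


class TestAmova:
    def test_toy_instance_matches_brute_force(self):
        rng = np.random.default_rng(21)
        prof = binary_frame(rng.integers(0, 2, (6, 15)).tolist())
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=prof.index)
        res = popgen.amova(prof, groups, n_perm=0)
        d2 = popgen.binary_distance_matrix(prof).values
        oracle = amova_oracle_two_level(d2, list(groups))
        assert res.components["among"]["SS"] == pytest.approx(oracle["ss_among"], abs=1e-9)
        assert res.components["within"]["SS"] == pytest.approx(oracle["ss_within"], abs=1e-9)
        assert res.phi_pt == pytest.approx(oracle["phipt"], abs=1e-9)

    def test_complementary_fixed_profiles_give_phipt_one(self):
        prof = binary_frame([[1] * 10] * 3 + [[0] * 10] * 3)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=prof.index)
        res = popgen.amova(prof, groups, n_perm=99, seed=0)
        assert res.phi_pt == pytest.approx(1.0)

    def test_identical_groups_show_no_structure(self):
        rng = np.random.default_rng(4)
        rows = rng.integers(0, 2, (4, 30))
        prof = binary_frame(np.vstack([rows, rows[rng.permutation(4)]]).tolist())
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=prof.index)
        res = popgen.amova(prof, groups, n_perm=499, seed=0)
        assert res.phi_pt == pytest.approx(0.0, abs=0.05)
        assert res.p_value > 0.05

    def test_percentages_sum_to_100(self, msap_small):
        ds, _ = msap_small
        res = popgen.amova(ds.msp, ds.groups("vineyard"),
                           regions=ds.groups("subregion"), n_perm=0)
        total = sum(v["pct"] for v in res.components.values())
        assert total == pytest.approx(100.0, abs=0.1)

    def test_invariant_under_locus_and_sample_reordering(self, msap_small):
        ds, _ = msap_small
        prof = ds.msp
        groups = ds.groups("vineyard")
        base = popgen.amova(prof, groups, n_perm=0)
        rng = np.random.default_rng(0)
        shuffled = prof.iloc[rng.permutation(len(prof)),
                             rng.permutation(prof.shape[1])]
        res = popgen.amova(shuffled, groups, n_perm=0)
        assert res.phi_pt == pytest.approx(base.phi_pt, abs=1e-12)

    def test_single_sample_group_is_an_error(self):
        prof = binary_frame([[1, 0], [0, 1], [1, 1]])
        groups = pd.Series(["A", "A", "B"], index=prof.index)
        with pytest.raises(ValueError, match="single sample"):
            popgen.amova(prof, groups, n_perm=0)


class TestPairwisePhipt:
    def test_identical_populations_are_undifferentiated(self):
        rng = np.random.default_rng(9)
        rows = rng.integers(0, 2, (4, 40))
        prof = binary_frame(np.vstack([rows, rows, rows]).tolist())
        groups = pd.Series(["A"] * 4 + ["B"] * 4 + ["C"] * 4, index=prof.index)
        pw = popgen.pairwise_phipt(prof, groups, n_perm=0)
        off = pw.phipt.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.0, atol=1e-12)

    def test_matrix_symmetry_and_zero_diagonal(self, msap_small):
        ds, _ = msap_small
        pw = popgen.pairwise_phipt(ds.msp, ds.groups("subregion"), n_perm=19, seed=0)
        assert np.allclose(pw.phipt.values, pw.phipt.values.T)
        assert np.all(np.diag(pw.phipt.values) == 0)
        off = ~np.eye(len(pw.p_values), dtype=bool)
        assert ((pw.p_values.values[off] > 0) & (pw.p_values.values[off] <= 1)).all()

    def test_planted_separation_orders_phipt(self):
        # stronger planted gradients should give larger pairwise PhiPT
        from epiterroir import simulate as sim
        hits = 0
        for seed in range(10):
            ds, _ = sim.simulate_msap_dataset(
                n_regions=3, vineyards_per_region=2, plants_per_vineyard=4,
                n_msl=120, n_nml=10, seed=seed, delta_p=0.35,
            )
            pw = popgen.pairwise_phipt(ds.msp, ds.groups("subregion"), n_perm=0)
            near = pw.phipt.loc["R1", "R2"]
            far = pw.phipt.loc["R1", "R3"]
            hits += far > near
        assert hits >= 7


# ---------------------------------------------------------------------------
# Mantel

class TestMantel:
    def _pair(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.random((n, 2))
        diff = pts[:, None] - pts[None, :]
        d = np.sqrt((diff ** 2).sum(-1))
        return DistanceMatrix(d, [str(i) for i in range(n)])

    def test_self_correlation_is_one_with_minimal_p(self):
        a = self._pair()
        res = popgen.mantel_test(a, a, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000, abs=5e-3)

    def test_anti_ordered_matrix_gives_minus_one(self):
        a = self._pair()
        b = DistanceMatrix(np.where(np.eye(a.n, dtype=bool), 0.0,
                                    a.values.max() - a.values), a.labels)
        res = popgen.mantel_test(a, b, n_perm=99, seed=0, alternative="less")
        assert res.r == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_r_equals_pearson_of_triangles(self):
        from scipy.stats import pearsonr
        a, b = self._pair(seed=1), self._pair(seed=2)
        res = popgen.mantel_test(a, b, n_perm=9, seed=0)
        iu = np.triu_indices(a.n, k=1)
        assert res.r == pytest.approx(pearsonr(a.values[iu], b.values[iu])[0], abs=1e-12)

    def test_monte_carlo_agrees_with_exhaustive_enumeration(self):
        a, b = self._pair(n=5, seed=3), self._pair(n=5, seed=4)
        res = popgen.mantel_test(a, b, n_perm=9999, seed=0)
        iu = np.triu_indices(5, k=1)
        va = a.values[iu]

        def corr(x, y):
            xc, yc = x - x.mean(), y - y.mean()
            return (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))

        r_obs = corr(va, b.values[iu])
        rs = [
            corr(va, b.values[np.ix_(p, p)][iu])
            for p in itertools.permutations(range(5))
        ]
        p_exact = np.mean([r >= r_obs - 1e-12 for r in rs])
        assert abs(res.p_value - p_exact) <= 0.02

    def test_constant_matrix_is_rejected(self):
        a = self._pair()
        b = DistanceMatrix(np.where(np.eye(a.n, dtype=bool), 0.0, 1.0), a.labels)
        with pytest.raises(ValueError, match="degenerate"):
            popgen.mantel_test(a, b, n_perm=9)

    def test_label_mismatch_is_rejected(self):
        a, b = self._pair(seed=1), self._pair(seed=2)
        b.labels = list(reversed(b.labels))
        with pytest.raises(ValueError, match="identical labels"):
            popgen.mantel_test(a, b, n_perm=9)

    def test_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as sk_mantel
        a, b = self._pair(n=8, seed=5), self._pair(n=8, seed=6)
        res = popgen.mantel_test(a, b, n_perm=999, seed=1)
        r_ref, p_ref, _ = sk_mantel(
            skbio.DistanceMatrix(a.values, a.labels),
            skbio.DistanceMatrix(b.values, b.labels),
            method="pearson", permutations=999, alternative="greater",
        )
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert abs(res.p_value - p_ref) < 0.05
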