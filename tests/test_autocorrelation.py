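import numpy as np
import pytest

from geoprev import (
    DegenerateInputError,
    InvalidArgumentError,
    bivariate_local_moran,
    classify_clusters,
    global_bivariate_moran,
    global_moran,
    knn_weights,
    local_moran,
    queen_contiguity,
    row_standardize,
)
from geoprev.spatial_weights import SpatialWeights

from .conftest import make_grid_layer


# ---------------------------------------------------------------------------
# independent double-loop oracles
# ---------------------------------------------------------------------------


def dense_w(w: SpatialWeights) -> np.ndarray:
    m = np.zeros((w.n, w.n))
    for i in range(w.n):
        for j, wij in zip(w.neighbors[i], w.weights[i]):
            m[i, j] = wij
    return m


def brute_global_moran(x, w):
    m = dense_w(w)
    n = len(x)
    z = np.asarray(x, float) - np.mean(x)
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += m[i, j] * z[i] * z[j]
    return (n / m.sum()) * num / np.sum(z * z)

def brute_local_moran(x, w):
    m = dense_w(w)
    n = len(x)
    z = np.asarray(x, float) - np.mean(x)
    m2 = np.sum(z * z) / n
    out = np.zeros(n)
    for i in range(n):
        lag = 0.0
        for j in range(n):
            lag += m[i, j] * z[j]
        out[i] = z[i] / m2 * lag
    return out


def brute_bivariate_local(x, y, w):
    m = dense_w(w)
    n = len(x)
    zx = (np.asarray(x, float) - np.mean(x)) / np.std(x)
    zy = (np.asarray(y, float) - np.mean(y)) / np.std(y)
    out = np.zeros(n)
    for i in range(n):
        lag = 0.0
        for j in range(n):
            lag += m[i, j] * zy[j]
        out[i] = zx[i] * lag
    return out


def ring_weights(n: int) -> SpatialWeights:
    neighbors = [[(i - 1) % n, (i + 1) % n] for i in range(n)]
    weights = [[0.5, 0.5] for _ in range(n)]
    return SpatialWeights([f"U{i}" for i in range(n)], neighbors, weights, True)


@pytest.fixture
def grid_w(grid5x5):
    return row_standardize(queen_contiguity(grid5x5))


class TestGlobalMoran:
    def test_four_cycle_alternating_is_minus_one(self):
        # closed form: on a row-standardized 4-cycle each lag equals -z_i
        res = global_moran([1.0, -1.0, 1.0, -1.0], ring_weights(4), n_perm=19, seed=0)
        assert res.I == pytest.approx(-1.0, abs=1e-12)

    def test_constant_x_errors(self, grid_w):
        with pytest.raises(DegenerateInputError):
            global_moran(np.ones(25), grid_w, n_perm=19, seed=0)

    def test_matches_brute_force(self, grid_w):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(size=25)
            res = global_moran(x, grid_w, n_perm=19, seed=0)
            assert res.I == pytest.approx(brute_global_moran(x, grid_w), abs=1e-12)

    def test_null_calibration(self, grid_w):
        # exchangeable null: one-sided rejection rate ~ alpha
        rng = np.random.default_rng(77)
        rej = sum(
            global_moran(rng.normal(size=25), grid_w, n_perm=199, seed=rep).pseudo_p <= 0.05
            for rep in range(500)
        )
        assert 0.03 <= rej / 500 <= 0.07

    def test_seed_reproducible(self, grid_w):
        x = np.random.default_rng(1).normal(size=25)
        a = global_moran(x, grid_w, n_perm=99, seed=5)
        b = global_moran(x, grid_w, n_perm=99, seed=5)
        assert np.array_equal(a.permutation_Is, b.permutation_Is)
        assert a.pseudo_p == b.pseudo_p
        assert a.pseudo_p > 0

    def test_nan_units_excluded(self, grid_w):
        x = np.random.default_rng(2).normal(size=25)
        x[3] = np.nan
        res = global_moran(x, grid_w, n_perm=19, seed=0)
        assert res.n_used == 24
        assert res.excluded_ids == [grid_w.ids[3]]


class TestLocalMoran:
    def test_sum_identity(self, grid_w):
        # sum_i I_i = n * I_global on a row-standardized matrix
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.normal(size=25)
            g = global_moran(x, grid_w, n_perm=19, seed=0)
            loc = local_moran(x, grid_w, n_perm=19, seed=0)
            assert loc.table["I_i"].sum() == pytest.approx(25 * g.I, abs=1e-10)

    def test_high_value_surrounded_by_low_is_HL_negative(self, grid_w):
        x = np.zeros(25)
        x[12] = 10.0  # center of the 5x5 grid
        loc = local_moran(x, grid_w, n_perm=99, seed=1)
        row = loc.table[loc.table.unit_id == grid_w.ids[12]].iloc[0]
        assert row.quadrant == "HL"
        assert row.I_i < 0

    def test_matches_brute_force(self, grid_w):
        rng = np.random.default_rng(6)
        x = rng.normal(size=25)
        loc = local_moran(x, grid_w, n_perm=19, seed=0)
        assert np.allclose(loc.table["I_i"], brute_local_moran(x, grid_w), atol=1e-12)

    def test_null_flagging_rate(self, grid_w):
        # uncorrected LISA over-flagging: mean flagged fraction near alpha
        rng = np.random.default_rng(11)
        fractions = []
        for rep in range(100):
            x = rng.normal(size=25)
            loc = classify_clusters(local_moran(x, grid_w, n_perm=199, seed=rep), 0.05)
            fractions.append(loc.table["significant"].mean())
        assert 0.02 <= np.mean(fractions) <= 0.10

    def test_planted_block_recovered_as_HH(self):
        # power: a contiguous block of elevated values must be flagged HH
        # recovery = majority of the planted block classified HH-significant
        layer = make_grid_layer(7, 7)
        w = row_standardize(queen_contiguity(layer))
        block = [16, 17, 18, 23, 24, 25, 30, 31, 32]  # 3x3 interior block
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            rng = np.random.default_rng(300 + rep)
            x = rng.normal(0, 1, 49)
            x[block] += 4.0
            loc = classify_clusters(local_moran(x, w, n_perm=199, seed=rep), 0.05)
            t = loc.table.set_index("unit_id")
            n_hh = sum(t.loc[layer.unit_ids[b], "cluster"] == "HH" for b in block)
            hits += n_hh > len(block) / 2
        assert hits / n_rep >= 0.90


class TestBivariate:
    def test_reduces_to_univariate_when_y_equals_x(self, grid_w):
        x = np.random.default_rng(8).normal(size=25)
        uni = local_moran(x, grid_w, n_perm=19, seed=0)
        bi = bivariate_local_moran(x, x, grid_w, n_perm=19, seed=0)
        # m2 scaling equals unit-variance scaling once z is standardized
        assert np.allclose(bi.table["I_i"], uni.table["I_i"], atol=1e-10)

    def test_path_graph_hand_values(self):
        # 3-node path, z_x = (1, 0, -1), z_y = (-1, 0, 1): all lags of z_y
        # are 0 at the ends' single neighbor and (1 - 1)/2 = 0 at the center,
        # so every I_i = 0
        w = SpatialWeights(
            ["P0", "P1", "P2"],
            [[1], [0, 2], [1]],
            [[1.0], [0.5, 0.5], [1.0]],
            True,
        )
        zx = np.array([1.0, 0.0, -1.0])
        zy = np.array([-1.0, 0.0, 1.0])
        bi = bivariate_local_moran(zx, zy, w, n_perm=19, seed=0)
        assert np.allclose(bi.table["I_i"], 0.0, atol=1e-12)

    def test_matches_brute_force(self, grid_w):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=25), rng.normal(size=25)
        bi = bivariate_local_moran(x, y, grid_w, n_perm=19, seed=0)
        assert np.allclose(bi.table["I_i"], brute_bivariate_local(x, y, grid_w), atol=1e-12)

    def test_global_positive_when_y_is_smoothed_x(self, grid_w):
        # construction oracle: y = spatial smooth of x => positive cross-scale I
        rng = np.random.default_rng(10)
        x = rng.normal(size=25)
        wd = np.zeros((25, 25))
        for i in range(25):
            for j, wij in zip(grid_w.neighbors[i], grid_w.weights[i]):
                wd[i, j] = wij
        y = 0.5 * x + 0.5 * (wd @ x)
        res = global_bivariate_moran(x, y, grid_w, n_perm=199, seed=0)
        assert res.I > 0
        assert res.pseudo_p <= 0.05


class TestClassification:
    def test_hh_when_significant(self, grid_w):
        rng = np.random.default_rng(12)
        loc = local_moran(rng.normal(size=25), grid_w, n_perm=99, seed=0)
        t = loc.table.copy()
        cls = classify_clusters(loc, alpha=0.05)
        for _, row in cls.table.iterrows():
            if row.pseudo_p <= 0.05:
                assert row.cluster == row.quadrant
            else:
                assert row.cluster == "NS"

    def test_alpha_validation(self, grid_w):
        loc = local_moran(np.random.default_rng(1).normal(size=25), grid_w, 19, 0)
        with pytest.raises(InvalidArgumentError):
            classify_clusters(loc, alpha=1.5)

    def test_cluster_map_export(self, grid_w, grid5x5, tmp_path):
        import json

        from geoprev import write_cluster_map

        loc = local_moran(np.random.default_rng(1).normal(size=25), grid_w, 99, 0)
        cls = classify_clusters(loc, 0.05)
        p = tmp_path / "clusters.geojson"
        write_cluster_map(grid5x5, cls, p)
        doc = json.loads(p.read_text())
        assert len(doc["features"]) == 25
        labels = {f["properties"]["cluster"] for f in doc["features"]}
        assert labels <= {"HH", "LL", "HL", "LH", "NS"}
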