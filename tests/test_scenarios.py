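import numpy as np
import pandas as pd
import pytest

from mwchamber.em_forward import SMatrix
from mwchamber.phantom import RigidTransform, build_phantom
from mwchamber.scenarios import (
    Dataset,
    DehydrationScenarioConfig,
    NoiseScenarioConfig,
    PositionScenarioConfig,
    add_noise,
    build_dehydration_scenario,
    build_noise_scenario,
    build_position_scenario,
    default_positions,
    differential_smatrix,
    noise_sigma,
    shuffle_split,
    vectorize,
)


def _rand_smatrix(n=4, seed=0, kind="differential"):
    rng = np.random.default_rng(seed)
    return SMatrix(rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n)), 1e9, kind)


class TestDifferential:
    def test_full_minus_empty_zero(self):
        s = _rand_smatrix(kind="full")
        d = differential_smatrix(s, s)
        assert np.array_equal(d.entries, np.zeros_like(s.entries))
        assert d.kind == "differential"

    def test_linearity(self):
        a, b = _rand_smatrix(seed=1, kind="full"), _rand_smatrix(seed=2, kind="empty")
        ab = SMatrix(a.entries + b.entries, 1e9, "full")
        assert np.allclose(differential_smatrix(ab, b).entries, a.entries)

    def test_injured_healthy_differ(self, cache16):
        dH = cache16.differential(build_phantom(injured=False))
        dI = cache16.differential(build_phantom(injured=True))
        assert np.linalg.norm(dH.entries - dI.entries) > 1e-4


class TestAddNoise:
    def test_infinite_snr_is_identity(self):
        s = _rand_smatrix()
        out = add_noise(s, np.inf, seed=3)
        assert np.array_equal(out.entries, s.entries)

    def test_deterministic(self):
        s = _rand_smatrix()
        a = add_noise(s, 10.0, seed=42)
        b = add_noise(s, 10.0, seed=42)
        assert np.array_equal(a.entries, b.entries)

    def test_seeds_differ(self):
        s = _rand_smatrix()
        assert not np.array_equal(
            add_noise(s, 10.0, 1).entries, add_noise(s, 10.0, 2).entries
        )

    def test_negative_seed_rejected(self):
        with pytest.raises(ValueError):
            add_noise(_rand_smatrix(), 10.0, -1)

    @pytest.mark.parametrize("snr_db", [20.0, 6.0, 0.0])
    def test_empirical_snr(self, snr_db):
        """Monte-Carlo check of the sigma <-> dB mapping."""
        s = _rand_smatrix(n=8, seed=7)
        x = np.concatenate([s.entries.real.ravel(), s.entries.imag.ravel()])
        num = den = 0.0
        n_draws = 10_000 // 8
        for seed in range(n_draws):
            noisy = add_noise(s, snr_db, seed)
            y = np.concatenate([noisy.entries.real.ravel(), noisy.entries.imag.ravel()])
            num += np.sum(x**2)
            den += np.sum((y - x) ** 2)
        measured = 20 * np.log10(np.sqrt(num / den))
        assert measured == pytest.approx(snr_db, abs=0.2)

    def test_sigma_mapping(self):
        assert noise_sigma(20.0) == pytest.approx(0.1)
        assert noise_sigma(-1.6) == pytest.approx(1.2, abs=0.02)


class TestVectorize:
    def test_lengths(self):
        assert len(vectorize(_rand_smatrix(32))) == 2048
        assert len(vectorize(_rand_smatrix(16))) == 512

    def test_block_order(self):
        s = _rand_smatrix(3)
        v = vectorize(s)
        assert np.array_equal(v[:9], s.entries.real.ravel())
        assert np.array_equal(v[9:], s.entries.imag.ravel())

    def test_injective(self):
        a, b = _rand_smatrix(4, seed=1), _rand_smatrix(4, seed=2)
        assert not np.array_equal(vectorize(a), vectorize(b))


class TestNoiseScenario:
    def test_counts_default(self, cache16):
        ds = build_noise_scenario(cache16, master_seed=0)
        c = ds.counts()
        assert c.loc["train", 1] == 180 and c.loc["train", -1] == 180
        assert c.loc["test", 1] == 216 and c.loc["test", -1] == 216

    def test_minimal_config(self, cache16):
        cfg = NoiseScenarioConfig(
            train_levels_healthy=(10.0,), train_levels_injured=(10.0,),
            test_levels_healthy=(8.0,), test_levels_injured=(8.0,), n_seeds=1,
        )
        ds = build_noise_scenario(cache16, cfg)
        assert ds.counts().to_numpy().sum() == 4

    def test_duplicate_levels_rejected(self, cache16):
        cfg = NoiseScenarioConfig(train_levels_healthy=(10.0, 10.0))
        with pytest.raises(ValueError, match="duplicate"):
            build_noise_scenario(cache16, cfg)

    def test_solve_count_independent_of_seeds(self, model16):
        from mwchamber.scenarios import ForwardCache

        cache = ForwardCache(model16)
        build_noise_scenario(cache, NoiseScenarioConfig(n_seeds=2))
        n1 = cache.n_solves
        build_noise_scenario(cache, NoiseScenarioConfig(n_seeds=5))
        assert cache.n_solves == n1  # all phantoms cached, seeds are free
        assert n1 == 3  # healthy, injured, empty

    def test_reproducible(self, cache16):
        a = build_noise_scenario(cache16, master_seed=5)
        b = build_noise_scenario(cache16, master_seed=5)
        assert np.array_equal(a.features, b.features)

    def test_feature_length(self, cache16):
        ds = build_noise_scenario(
            cache16, NoiseScenarioConfig(n_seeds=1)
        )
        assert ds.n_features == 2 * 16**2


@pytest.fixture(scope="module")
def deh(cache16):
    return build_dehydration_scenario(cache16, master_seed=0)


class TestDehydrationScenario:
    def test_category_sizes(self, deh):
        for g in ("healthy", "sf0", "sf1", "sf2"):
            sub = deh.subset((deh.meta["group_name"] == g).values)
            assert len(sub) == 1008
            assert np.sum(sub.split == "train") == 900
            assert np.sum(sub.split == "test") == 108

    def test_healthy_has_all_muscle_variants_in_both_splits(self, deh):
        h = deh.subset((deh.meta["group_name"] == "healthy").values)
        for split in ("train", "test"):
            hm = set(h.meta.loc[h.split == split, "hderr_muscle"])
            assert hm == {-0.09, 0.0, 0.09}

    def test_partition_mismatch_rejected(self, cache16):
        cfg = DehydrationScenarioConfig(n_train=901)
        with pytest.raises(ValueError, match="partition"):
            build_dehydration_scenario(cache16, cfg)

    def test_solve_budget(self, model16):
        from mwchamber.scenarios import ForwardCache

        cache = ForwardCache(model16)
        build_dehydration_scenario(cache)
        # 3 healthy + 9 injured + 1 empty
        assert cache.n_solves == 13


class TestPositionScenario:
    def test_per_position_counts(self, cache16):
        trs = [RigidTransform(), RigidTransform(dx=0.5)]
        ds = build_position_scenario(cache16, trs, test_position=1)
        for ti, split in ((0, "train"), (1, "test")):
            sub = ds.subset((ds.meta["transform_id"] == ti).values)
            assert len(sub) == 288
            assert np.sum(sub.labels == 1) == 144
            assert np.sum(sub.labels == -1) == 144
            assert (sub.split == split).all()

    def test_unbalanced_config_rejected(self, cache16):
        cfg = PositionScenarioConfig(n_seeds_healthy=11)
        with pytest.raises(ValueError, match="unbalanced"):
            build_position_scenario(cache16, [RigidTransform()], cfg)

    def test_default_positions_fixture(self):
        trs = default_positions()
        assert len(trs) == 31
        assert trs[0].is_identity
        # every fixture position must produce a valid phantom
        for t in trs:
            build_phantom(injured=True, transform=t)
        # M-cases carry the printed values
        assert trs[7].theta == 25.7
        assert (trs[9].dx, trs[9].dz, trs[9].theta) == (1.0, 3.0, 22.5)


class TestShuffleSplit:
    def _toy(self, n=100, d=4):
        rng = np.random.default_rng(0)
        return Dataset(
            rng.normal(size=(n, d)),
            np.where(np.arange(n) % 2 == 0, 1, -1),
            np.full(n, "train", dtype=object),
            pd.DataFrame({"i": np.arange(n)}),
        )

    def test_sizes_and_disjoint(self):
        ds = shuffle_split(self._toy(), 70, 30, seed=1)
        assert np.sum(ds.split == "train") == 70
        assert np.sum(ds.split == "test") == 30

    def test_reproducible(self):
        a = shuffle_split(self._toy(), 60, 20, seed=9)
        b = shuffle_split(self._toy(), 60, 20, seed=9)
        assert np.array_equal(a.split, b.split)
        assert np.array_equal(a.meta["i"], b.meta["i"])

    def test_overflow_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            shuffle_split(self._toy(), 90, 20, seed=0)

    def test_printed_trial_sizes(self):
        ds = shuffle_split(self._toy(n=8928, d=2), 3350, 1114, seed=0)
        assert np.sum(ds.split == "train") == 3350
        assert np.sum(ds.split == "test") == 1114


def test_noise_free_full_contrast_separable(cache16):
    """Zero noise, full contrast: training accuracy 1.0 at any C >= 1."""
    from mwchamber.classify import SVMConfig, _fit, _predict

    cfg = NoiseScenarioConfig(
        train_levels_healthy=(np.inf,), train_levels_injured=(np.inf,),
        test_levels_healthy=(np.inf,), test_levels_injured=(np.inf,), n_seeds=4,
    )
    ds = build_noise_scenario(cache16, cfg)
    dev = ds.part("train")
    for C in (1.0, 100.0):
        m = _fit(dev.features, dev.labels, SVMConfig(), C=C)
        assert np.all(_predict(m, dev.features) == dev.labels)
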