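"""Labeled differential S-parameter datasets for the four experiment designs.

Each sample is one noisy realization of a differential scattering matrix
(loaded chamber minus empty chamber), flattened into a real feature vector of
length ``2 N^2`` (row-major real block, then row-major imaginary block).
Healthy phantoms are labeled ``+1``, injured ``-1``.

Forward solves are cached per distinct phantom, so the number of FEM solves
scales with the number of distinct (geometry, dehydration, position) tuples
and never with the seed count.  Per-sample noise seeds derive from a
splittable counter ``(master seed, scenario, class, group, level, seed
index)``, making every dataset reproducible sample by sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .em_forward import ChamberModel, SMatrix
from .phantom import (
    DEFAULT_GEOMETRY,
    GeometryConfig,
    Phantom,
    RigidTransform,
    build_phantom,
    tissue_permittivity,
)

__all__ = [
    "Dataset",
    "ForwardCache",
    "NoiseScenarioConfig",
    "DehydrationScenarioConfig",
    "PositionScenarioConfig",
    "differential_smatrix",
    "add_noise",
    "noise_sigma",
    "vectorize",
    "build_noise_scenario",
    "build_dehydration_scenario",
    "build_position_scenario",
    "shuffle_split",
    "surrounding_positions",
    "default_positions",
]

_SCENARIO_CODES = {"noise": 1, "dehydration": 2, "position": 3, "shuffled": 4}


# ---------------------------------------------------------------------------
# S-matrix level operations


def differential_smatrix(full: SMatrix, empty: SMatrix) -> SMatrix:
    """Entrywise ``full - empty`` (the phantom's scattering signature)."""
    return full - empty


def noise_sigma(snr_db: float) -> float:
    """Per-component multiplicative noise std for a given SNR in dB."""
    return 10.0 ** (-snr_db / 20.0)


def add_noise(s: SMatrix, snr_db: float, seed: int) -> SMatrix:
    """Multiplicative white Gaussian noise on each real/imag component.

    Every component ``x`` becomes ``x * (1 + eta)`` with ``eta ~ N(0,
    sigma^2)``, ``sigma = 10^(-snr_db/20)``, drawn row-major over the real
    block first and the imaginary block second.  Identical inputs give
    bitwise identical outputs.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    sigma = noise_sigma(snr_db)
    if sigma == 0.0:
        return SMatrix(s.entries.copy(), s.frequency, s.kind)
    rng = np.random.default_rng(seed)
    n = s.n_ports
    eta_re = rng.normal(0.0, sigma, size=(n, n))
    eta_im = rng.normal(0.0, sigma, size=(n, n))
    noisy = s.entries.real * (1.0 + eta_re) + 1j * s.entries.imag * (1.0 + eta_im)
    return SMatrix(noisy, s.frequency, s.kind)


def vectorize(s: SMatrix) -> np.ndarray:
    """Length ``2 N^2`` real feature vector: real block then imaginary block."""
    return np.concatenate([s.entries.real.ravel(), s.entries.imag.ravel()])


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class Dataset:
    """Feature matrix with labels, split assignment and provenance metadata."""

    features: np.ndarray          # (n, 2 N^2)
    labels: np.ndarray            # (n,) in {+1, -1}
    split: np.ndarray             # (n,) of {"train", "validation", "test"}
    meta: pd.DataFrame            # one row per sample

    def __post_init__(self):
        n = len(self.features)
        if not (len(self.labels) == len(self.split) == len(self.meta) == n):
            raise ValueError("inconsistent dataset lengths")
        if not np.isin(self.labels, [1, -1]).all():
            raise ValueError("labels must be +1 or -1")
        if not np.isin(self.split, ["train", "validation", "test"]).all():
            raise ValueError("unknown split labels")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, mask: np.ndarray) -> "Dataset":
        return Dataset(
            self.features[mask],
            self.labels[mask],
            self.split[mask],
            self.meta.loc[mask].reset_index(drop=True),
        )

    def part(self, *splits: str) -> "Dataset":
        return self.subset(np.isin(self.split, splits))

    def counts(self) -> pd.DataFrame:
        """Sample counts by split and class."""
        df = pd.DataFrame({"split": self.split, "label": self.labels})
        return df.value_counts(["split", "label"]).unstack(fill_value=0)

    @staticmethod
    def concatenate(parts: list["Dataset"]) -> "Dataset":
        return Dataset(
            np.concatenate([p.features for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.split for p in parts]),
            pd.concat([p.meta for p in parts], ignore_index=True),
        )


# ---------------------------------------------------------------------------
# forward-solve caching


class ForwardCache:
    """Caches S-matrices of a fixed chamber model per distinct phantom."""

    def __init__(self, model: ChamberModel):
        self.model = model
        self._cache: dict = {}
        self._empty: SMatrix | None = None
        self.n_solves = 0

    @property
    def n_ports(self) -> int:
        return self.model.n_ports

    def empty(self) -> SMatrix:
        if self._empty is None:
            self._empty = self.model.smatrix(None)
            self.n_solves += 1
        return self._empty

    def smatrix(self, phantom: Phantom) -> SMatrix:
        key = phantom.key()
        if key not in self._cache:
            self._cache[key] = self.model.smatrix(phantom)
            self.n_solves += 1
        return self._cache[key]

    def differential(self, phantom: Phantom) -> SMatrix:
        return differential_smatrix(self.smatrix(phantom), self.empty())


def _sample_seed(
    master_seed: int, scenario: str, label: int, group: int, level_idx: int, seed_idx: int
) -> int:
    ss = np.random.SeedSequence(
        [master_seed, _SCENARIO_CODES[scenario], label % 3, group, level_idx, seed_idx]
    )
    return int(ss.generate_state(1, dtype=np.uint64)[0] >> 1)


# ---------------------------------------------------------------------------
# scenario configs

# Per-class SNR levels (dB) of the noise study; training and test sets use
# deliberately different levels.
TRAIN_LEVELS_HEALTHY = (16.6, 13.0, 7.0, 4.4, 2.3)
TRAIN_LEVELS_INJURED = (23.0, 15.3, 5.6, 3.9, 1.38)
TEST_LEVELS_HEALTHY = (19.0, 7.7, 4.9, 2.7, 0.9, -0.65)
TEST_LEVELS_INJURED = (31.0, 15.2, 6.4, 4.0, 1.9, 0.24)


@dataclass(frozen=True)
class NoiseScenarioConfig:
    train_levels_healthy: tuple = TRAIN_LEVELS_HEALTHY
    train_levels_injured: tuple = TRAIN_LEVELS_INJURED
    test_levels_healthy: tuple = TEST_LEVELS_HEALTHY
    test_levels_injured: tuple = TEST_LEVELS_INJURED
    n_seeds: int = 36
    geometry: GeometryConfig = DEFAULT_GEOMETRY
    zero_contrast: bool = False


@dataclass(frozen=True)
class DehydrationScenarioConfig:
    hderr_muscle_values: tuple = (-0.09, 0.0, 0.09)
    hderr_sf_values: tuple = (-0.09, 0.0, 0.09)
    noise_levels: tuple = tuple(np.linspace(23.0, 10.0, 7))
    n_seeds: int = 48
    n_train: int = 900
    n_test: int = 108
    sf_baseline: str = "rounded"   # the dehydration sweep perturbs 68.0-29.0i
    geometry: GeometryConfig = DEFAULT_GEOMETRY


@dataclass(frozen=True)
class PositionScenarioConfig:
    hderr_muscle_values: tuple = (-0.09, 0.0, 0.09)
    hderr_sf_values: tuple = (-0.09, 0.0, 0.09)
    noise_levels: tuple = tuple(np.linspace(23.0, 10.0, 4))
    n_seeds_healthy: int = 12
    n_seeds_injured: int = 4
    sf_baseline: str = "rounded"
    geometry: GeometryConfig = DEFAULT_GEOMETRY


# ---------------------------------------------------------------------------
# builders


def _make_samples(
    dS: SMatrix,
    levels,
    n_seeds: int,
    *,
    scenario: str,
    label: int,
    split: str,
    master_seed: int,
    group: int = 0,
    level_offset: int = 0,
    meta_extra: dict | None = None,
) -> Dataset:
    if len(set(levels)) != len(levels):
        raise ValueError(f"duplicate noise levels in {levels}")
    feats, metas = [], []
    for li, level in enumerate(levels):
        for si in range(n_seeds):
            seed = _sample_seed(master_seed, scenario, label, group, li + level_offset, si)
            feats.append(vectorize(add_noise(dS, level, seed)))
            row = {
                "noise_db": level,
                "seed": seed,
                "seed_idx": si,
                "scenario": scenario,
                "group": group,
            }
            if meta_extra:
                row.update(meta_extra)
            metas.append(row)
    n = len(feats)
    return Dataset(
        np.asarray(feats),
        np.full(n, label, dtype=int),
        np.full(n, split, dtype=object),
        pd.DataFrame(metas),
    )


def build_noise_scenario(
    cache: ForwardCache,
    config: NoiseScenarioConfig = NoiseScenarioConfig(),
    master_seed: int = 0,
) -> Dataset:
    """Noise study: one healthy and one injured phantom, many noise levels.

    Per class the defaults give ``36 x 5 = 180`` training and ``36 x 6 =
    216`` test samples.  Only two loaded forward solves (plus the shared
    empty reference) underlie the whole dataset.
    """
    healthy = build_phantom(config.geometry, injured=False)
    if config.zero_contrast:
        # negative control: the "injured" phantom is filled with muscle
        injured = build_phantom(
            config.geometry, injured=True,
            injury_override=tissue_permittivity("muscle", 0.0),
        )
    else:
        injured = build_phantom(config.geometry, injured=True)
    dH = cache.differential(healthy)
    dI = cache.differential(injured)
    kw = dict(scenario="noise", master_seed=master_seed)
    parts = [
        _make_samples(dH, config.train_levels_healthy, config.n_seeds,
                      label=+1, split="train", **kw),
        _make_samples(dI, config.train_levels_injured, config.n_seeds,
                      label=-1, split="train", **kw),
        _make_samples(dH, config.test_levels_healthy, config.n_seeds,
                      label=+1, split="test", level_offset=100, **kw),
        _make_samples(dI, config.test_levels_injured, config.n_seeds,
                      label=-1, split="test", level_offset=100, **kw),
    ]
    return Dataset.concatenate(parts)


def build_dehydration_scenario(
    cache: ForwardCache,
    config: DehydrationScenarioConfig = DehydrationScenarioConfig(),
    master_seed: int = 0,
) -> Dataset:
    """Dehydration study: tissue permittivities drift by +/-9 percent.

    Healthy samples pool all three muscle variants (one category,
    ``48 x 7 x 3 = 1008`` samples); injured samples form one category per
    synovial-fluid variant, each again 1008 samples.  Every category is
    partitioned at random into 900 training and 108 test samples.  The
    ``group`` meta column is ``"healthy"`` or ``"sf<variant index>"``.
    """
    n_cat = len(config.hderr_muscle_values) * len(config.noise_levels) * config.n_seeds
    if config.n_train + config.n_test != n_cat:
        raise ValueError(
            f"partition {config.n_train}+{config.n_test} != category size {n_cat}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 2, 777]))

    def partition(ds: Dataset) -> Dataset:
        perm = rng.permutation(len(ds))
        split = np.full(len(ds), "test", dtype=object)
        split[perm[: config.n_train]] = "train"
        ds.split[:] = split
        return ds

    parts = []
    healthy_parts = []
    for mi, hm in enumerate(config.hderr_muscle_values):
        ph = build_phantom(config.geometry, injured=False, hderr_muscle=hm)
        healthy_parts.append(
            _make_samples(
                cache.differential(ph), config.noise_levels, config.n_seeds,
                scenario="dehydration", label=+1, split="train",
                master_seed=master_seed, group=0, level_offset=10 * mi,
                meta_extra={"hderr_muscle": hm, "hderr_sf": 0.0, "group_name": "healthy"},
            )
        )
    parts.append(partition(Dataset.concatenate(healthy_parts)))

    for gi, hsf in enumerate(config.hderr_sf_values):
        grp = []
        for mi, hm in enumerate(config.hderr_muscle_values):
            ph = build_phantom(
                config.geometry, injured=True, hderr_muscle=hm, hderr_sf=hsf,
                sf_baseline=config.sf_baseline,
            )
            grp.append(
                _make_samples(
                    cache.differential(ph), config.noise_levels, config.n_seeds,
                    scenario="dehydration", label=-1, split="train",
                    master_seed=master_seed, group=gi + 1, level_offset=10 * mi,
                    meta_extra={
                        "hderr_muscle": hm, "hderr_sf": hsf,
                        "group_name": f"sf{gi}",
                    },
                )
            )
        parts.append(partition(Dataset.concatenate(grp)))
    return Dataset.concatenate(parts)


def build_position_scenario(
    cache: ForwardCache,
    transforms: list[RigidTransform],
    config: PositionScenarioConfig = PositionScenarioConfig(),
    master_seed: int = 0,
    test_position: int | None = None,
) -> Dataset:
    """Position study: the phantom is shifted/rotated between samples.

    Per position and class the defaults give 144 samples (healthy: 3 muscle
    variants x 12 seeds x 4 noise levels; injured: 3 muscle x 3 SF x 4 seeds
    x 4 levels).  With ``test_position`` set, that position's samples form
    the test split (leave-position-out); otherwise everything is "train" and
    can be re-split with :func:`shuffle_split`.
    """
    n_h = (len(config.hderr_muscle_values) * config.n_seeds_healthy
           * len(config.noise_levels))
    n_i = (len(config.hderr_muscle_values) * len(config.hderr_sf_values)
           * config.n_seeds_injured * len(config.noise_levels))
    if n_h != n_i:
        raise ValueError(
            f"unbalanced per-position counts: {n_h} healthy vs {n_i} injured"
        )
    parts = []
    for ti, tr in enumerate(transforms):
        split = "test" if ti == test_position else "train"
        extra = {"transform_id": ti}
        for mi, hm in enumerate(config.hderr_muscle_values):
            ph = build_phantom(
                config.geometry, injured=False, hderr_muscle=hm, transform=tr,
            )
            parts.append(
                _make_samples(
                    cache.differential(ph), config.noise_levels,
                    config.n_seeds_healthy,
                    scenario="position", label=+1, split=split,
                    master_seed=master_seed, group=ti,
                    level_offset=10 * mi,
                    meta_extra={**extra, "hderr_muscle": hm, "hderr_sf": 0.0},
                )
            )
            for si, hsf in enumerate(config.hderr_sf_values):
                phi = build_phantom(
                    config.geometry, injured=True, hderr_muscle=hm,
                    hderr_sf=hsf, transform=tr, sf_baseline=config.sf_baseline,
                )
                parts.append(
                    _make_samples(
                        cache.differential(phi), config.noise_levels,
                        config.n_seeds_injured,
                        scenario="position", label=-1, split=split,
                        master_seed=master_seed, group=ti,
                        level_offset=100 * mi + 10 * si,
                        meta_extra={**extra, "hderr_muscle": hm, "hderr_sf": hsf},
                    )
                )
    ds = Dataset.concatenate(parts)
    # verify the per-position class balance
    df = pd.DataFrame(
        {"pos": ds.meta["transform_id"], "label": ds.labels, "one": 1}
    )
    counts = df.groupby(["pos", "label"])["one"].sum()
    if counts.nunique() != 1:
        raise ValueError("unbalanced per-position sample counts")
    return ds


def shuffle_split(dataset: Dataset, n_train: int, n_test: int, seed: int) -> Dataset:
    """Uniformly random reassignment into ``n_train`` train / ``n_test`` test."""
    total = len(dataset)
    if n_train + n_test > total:
        raise ValueError(f"{n_train}+{n_test} exceeds dataset size {total}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(total)
    chosen = perm[: n_train + n_test]
    out = dataset.subset(np.sort(chosen))
    # positions within the sorted subset
    order = rng.permutation(n_train + n_test)
    split = np.full(n_train + n_test, "test", dtype=object)
    split[order[:n_train]] = "train"
    out.split[:] = split
    return out


def surrounding_positions(
    held_dx: float, held_dz: float, radius: float = 0.5
) -> list[RigidTransform]:
    """Reference placement plus eight neighbors ``radius`` cm around a
    held-out point: the tightest training grid the translation study
    supports (placements farther than 0.5 cm degrade accuracy)."""
    trs = [RigidTransform()]
    for k in range(8):
        a = math.pi * k / 4
        dx = round(held_dx + radius * math.cos(a), 3)
        dz = round(held_dz + radius * math.sin(a), 3)
        if (dx, dz) == (0.0, 0.0):
            continue
        trs.append(RigidTransform(dx=dx, dz=dz, theta=(-3.6 if k % 2 else 0.0)))
    return trs


JOINT_PIVOT = (3.5, 0.0)   # rotations pivot about the joint (bone centre)


def default_positions() -> list[RigidTransform]:
    """31-position fixture: the reference, the nine printed cases M1-M9, and
    21 additional training placements clustered around the reference and the
    three M groups (nearby-neighborhood layout, spacing mostly 0.5 cm).

    Rotations pivot about the joint: the shoulder rotates about the joint
    complex, not the body centroid, and joint-centred pivots keep the injury
    signature coherent across placements.
    """
    J = JOINT_PIVOT

    def T(dx=0.0, dz=0.0, theta=0.0):
        return RigidTransform(dx=dx, dz=dz, theta=theta, pivot=J)

    positions = [
        T(),                                   # 0: reference
        T(theta=-3.6),                         # 1: M1
        T(dx=-1.0, theta=-3.6),                # 2: M2
        T(theta=-7.2),                         # 3: M3
        T(theta=-18.0),                        # 4: M4
        T(dx=-3.0, theta=-12.0),               # 5: M5
        T(dx=-4.5, theta=-16.3),               # 6: M6
        T(theta=25.7),                         # 7: M7
        T(dx=1.0, dz=1.0, theta=25.7),         # 8: M8
        T(dx=1.0, dz=3.0, theta=22.5),         # 9: M9
        # reference-cluster placements
        T(dx=0.5), T(dx=-0.5), T(dz=0.5), T(dz=-0.5), T(dx=0.5, dz=0.5),
        T(dx=-0.5, dz=-0.5, theta=-2.0),
        # small-rotation group (around M1-M3)
        T(dx=-0.5, theta=-3.6), T(dx=-1.0, theta=-7.2), T(dz=0.5, theta=-3.6),
        T(dx=-0.5, dz=-0.5, theta=-7.2), T(dz=-0.5, theta=-5.4),
        # intermediate-rotation group (around M4-M6)
        T(dx=-3.5, theta=-12.0), T(dx=-2.5, theta=-12.0), T(dx=-4.0, theta=-16.3),
        T(dx=-3.0, dz=-0.5, theta=-18.0), T(dx=-4.0, dz=-1.0, theta=-16.3),
        # large-rotation group (around M7-M9)
        T(dx=0.5, theta=25.7), T(dx=0.5, dz=0.5, theta=25.7),
        T(dx=1.0, dz=0.5, theta=25.7), T(dx=1.0, dz=2.0, theta=22.5),
        T(dx=0.5, dz=1.0, theta=24.0),
    ]
    assert len(positions) == 31
    return positions
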