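"""Synthetic phantoms and simulated cohorts.

Two families of test beds stand in for patient data:

* **Fractal phantoms** — binary lattices of known dimension (filled cube,
  plane, line, Menger sponge) plus tumor-like blobs whose spatial
  *fragmentation* is controllable.  STAS-positive tumors grow
  discontinuously, with detached satellite cell clusters around the main
  mass; the ``fragmented_tumor`` phantom emulates that geometry by moving a
  chosen fraction of the tumor volume out of the main blob into small
  detached clusters in a surrounding halo, at constant total volume, so the
  expected effect (fragmentation lowers the 3D box-counting FD) can be
  checked directly.

* **Simulated cohorts** — per-patient feature tables with the structure of
  the study's baseline table: a binary STAS label drawn at a configurable
  prevalence and group-conditional feature distributions (binary CT signs
  by group probability; consolidation-to-tumor ratio as a scaled Beta on
  the 0-100 percent scale; FD 3D as a logistic location family).  Defaults
  reproduce the published group summaries (e.g. FD 3D medians 3.25 vs 3.52,
  CTR medians 50.30 vs 16.96).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .fractal import VoxelMask

__all__ = [
    "PhantomSpec",
    "CohortSimSpec",
    "make_fractal_phantom",
    "make_tumor_phantom",
    "simulate_cohort",
    "default_cohort_spec",
    "BINARY_FEATURES",
    "CONTINUOUS_FEATURES",
    "COHORT_COLUMNS",
]

PHANTOM_KINDS = ("cube", "plane", "line", "menger", "random_blob", "fragmented_tumor")

#: binary cohort features: (probability given STAS+, probability given STAS-)
#: from the published group counts, e.g. morphological irregularity present
#: in 13/48 positive vs 4/62 negative patients.
BINARY_FEATURES: dict[str, tuple[float, float]] = {
    "sex": (15 / 48, 19 / 62),                     # male = 1
    "smoking": (11 / 48, 10 / 62),                 # former/current = 1
    "location": (27 / 48, 41 / 62),                # upper/middle lobe = 1
    "interface": (4 / 48, 9 / 62),                 # blurry tumor-lung interface = 1
    "morph_irregularity": (13 / 48, 4 / 62),
    "spiculation": (19 / 48, 19 / 62),
    "lobulation": (39 / 48, 39 / 62),
    "pleural_indentation": (32 / 48, 24 / 62),
    "vascular_convergence": (33 / 48, 28 / 62),
    "vacuole": (13 / 48, 14 / 62),
    "air_bronchogram": (23 / 48, 22 / 62),
}

#: continuous features: family, params given STAS+, params given STAS-.
#: Normal families match the published mean +/- sd; the Beta shapes for CTR
#: (percent scale) and logistic scales for FD 3D were chosen by quantile
#: matching to the published median (IQR) per group.
CONTINUOUS_FEATURES: dict[str, tuple[str, tuple, tuple]] = {
    "age": ("normal", (60.60, 9.18), (60.60, 7.52)),
    "ctr": ("beta_percent", (0.677, 0.674), (0.487, 1.456)),
    "fd2d": ("normal", (1.36, 0.08), (1.36, 0.10)),
    "fd3d": ("logistic", (3.25, 0.0956), (3.52, 0.1229)),
}

COHORT_COLUMNS = (
    ["patient_id", "stas"]
    + list(BINARY_FEATURES)
    + list(CONTINUOUS_FEATURES)
)


@dataclass
class PhantomSpec:
    """Specification of a deterministic binary phantom."""

    kind: str
    level_or_size: int = 32
    fragmentation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unsupported phantom kind {self.kind!r}; choose from {PHANTOM_KINDS}")
        if self.level_or_size < 1:
            raise ValueError("level_or_size must be a positive integer")
        if self.kind == "menger" and self.level_or_size < 1:
            raise ValueError("menger level must be >= 1")
        if not (0.0 <= self.fragmentation <= 1.0):
            raise ValueError("fragmentation must lie in [0, 1]")


@dataclass
class CohortSimSpec:
    """Specification of a simulated cohort.

    ``feature_params`` holds the group-conditional distributions: binary
    features map to ``(p_given_positive, p_given_negative)``, continuous
    features to ``(family, params_positive, params_negative)``.
    """

    n: int = 110
    prevalence: float = 48 / 110
    binary_features: dict = field(default_factory=lambda: dict(BINARY_FEATURES))
    continuous_features: dict = field(default_factory=lambda: dict(CONTINUOUS_FEATURES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 20:
            raise ValueError("cohort size must be >= 20")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        for name, (pp, pn) in self.binary_features.items():
            if not (0.0 <= pp <= 1.0 and 0.0 <= pn <= 1.0):
                raise ValueError(f"probabilities for {name!r} must lie in [0, 1]")
        for name, (family, ppos, pneg) in self.continuous_features.items():
            for params in (ppos, pneg):
                if family in ("normal", "logistic") and params[1] <= 0:
                    raise ValueError(f"degenerate (zero-variance) distribution for {name!r}")
                if family == "beta_percent" and (params[0] <= 0 or params[1] <= 0):
                    raise ValueError(f"invalid Beta shapes for {name!r}")


def default_cohort_spec(n: int = 110, seed: int = 0, prevalence: float = 48 / 110) -> CohortSimSpec:
    """Cohort spec with the published group-conditional defaults."""
    return CohortSimSpec(n=n, prevalence=prevalence, seed=seed)


def _menger(level: int) -> np.ndarray:
    n = 3**level
    z, y, x = np.indices((n, n, n))
    keep = np.ones((n, n, n), dtype=bool)
    for d in range(level):
        p = 3**d
        mid = ((z // p) % 3 == 1).astype(int) + ((y // p) % 3 == 1).astype(int) + ((x // p) % 3 == 1).astype(int)
        keep &= mid < 2
    return keep


def make_fractal_phantom(spec: PhantomSpec) -> VoxelMask:
    """Deterministic phantom of known fractal dimension.

    ``cube``/``plane``/``line`` of edge n occupy n^3, n^2 and n voxels; a
    level-k Menger sponge occupies 20^k voxels on a 3^k lattice and has
    dimension log 20 / log 3.
    """
    k = spec.kind
    n = int(spec.level_or_size)
    sid = f"phantom:{k}:{n}:seed={spec.seed}"
    if k == "cube":
        occ = np.ones((n, n, n), dtype=bool)
    elif k == "plane":
        occ = np.ones((n, n, 1), dtype=bool)
    elif k == "line":
        occ = np.ones((1, 1, n), dtype=bool)
    elif k == "menger":
        occ = _menger(n)
    elif k in ("random_blob", "fragmented_tumor"):
        frag = spec.fragmentation if k == "fragmented_tumor" else 0.0
        return make_tumor_phantom(n, frag, spec.seed)
    else:  # pragma: no cover - guarded by PhantomSpec
        raise ValueError(f"unsupported phantom kind {k!r}")
    return VoxelMask(occ, source_id=sid)


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _ellipsoid_field(size: int, rng: np.random.Generator, noise_amp: float = 0.15):
    """Smooth scalar field whose sublevel sets are perturbed ellipsoids."""
    c = (size - 1) / 2.0
    radii = np.array([0.22, 0.20, 0.18]) * size
    z, y, x = np.indices((size, size, size))
    d = np.sqrt(((z - c) / radii[0]) ** 2 + ((y - c) / radii[1]) ** 2 + ((x - c) / radii[2]) ** 2)
    noise = ndimage.gaussian_filter(rng.standard_normal((size, size, size)), sigma=size / 8.0)
    noise /= max(noise.std(), 1e-12)
    field = d - noise_amp * noise
    target_volume = int(round(4.0 / 3.0 * np.pi * radii.prod()))
    return field, d, target_volume


def _threshold_to_count(field: np.ndarray, count: int) -> np.ndarray:
    """Boolean mask of exactly the ``count`` smallest field values."""
    flat = field.ravel()
    order = np.argpartition(flat, count - 1)[:count]
    out = np.zeros(flat.shape, dtype=bool)
    out[order] = True
    return out.reshape(field.shape)


def make_tumor_phantom(size: int, fragmentation: float, seed: int) -> VoxelMask:
    """Tumor-like blob with a controllable fraction of detached satellites.

    The main mass is a randomly surface-perturbed ellipsoid holding
    ``(1 - fragmentation)`` of the target volume; the remaining fraction is
    redistributed into small detached clusters (6-connectivity detachment,
    at least three clusters whenever ``fragmentation > 0``) placed in a
    bounded halo around the main mass.  Cluster target sizes are drawn
    log-uniformly between 1% and 5% of the main-blob volume.  Total occupied
    volume is conserved exactly across fragmentation levels, so FD
    comparisons isolate spatial continuity from size.
    """
    if not (0.0 <= fragmentation <= 1.0):
        raise ValueError("fragmentation must lie in [0, 1]")
    size = int(size)
    if size < 16:
        raise ValueError("lattice size must be >= 16 per axis to host satellites")
    rng = np.random.default_rng(seed)
    field, d_norm, target_volume = _ellipsoid_field(size, rng)
    main_volume = int(round((1.0 - fragmentation) * target_volume))
    main_volume = max(main_volume, 1)
    occ = _threshold_to_count(field, main_volume)

    remaining = target_volume - main_volume
    if fragmentation > 0 and remaining > 0:
        # plan >= 3 satellite cluster sizes summing exactly to `remaining`
        sizes: list[int] = []
        left = remaining
        while left > 0:
            lo, hi = 0.01 * main_volume, 0.05 * main_volume
            s = int(round(np.exp(rng.uniform(np.log(max(lo, 1.0)), np.log(max(hi, 2.0))))))
            s = int(np.clip(s, 1, left))
            sizes.append(s)
            left -= s
        while len(sizes) < 3:
            big = int(np.argmax(sizes))
            if sizes[big] < 2:
                break
            half = sizes[big] // 2
            sizes[big] -= half
            sizes.append(half)

        forbidden = ndimage.binary_dilation(occ, structure=_STRUCT6)
        c = (size - 1) / 2.0
        zz, yy, xx = np.indices((size, size, size))
        placed = 0
        for s in sizes:
            r = max((3.0 * s / (4.0 * np.pi)) ** (1.0 / 3.0), 1.0)
            ok = False
            for _ in range(300):
                # random point in the halo 1.2..1.7 normalized ellipsoid units out
                u = rng.uniform(1.2, 1.7)
                v = rng.standard_normal(3)
                v /= np.linalg.norm(v)
                radii = np.array([0.22, 0.20, 0.18]) * size
                pos = c + u * v * radii
                lo = np.floor(pos - r - 1).astype(int)
                hi = np.ceil(pos + r + 2).astype(int)
                if (lo < 0).any() or (hi > size).any():
                    continue
                sl = tuple(slice(a, b) for a, b in zip(lo, hi))
                dist = ((zz[sl] - pos[0]) ** 2 + (yy[sl] - pos[1]) ** 2 + (xx[sl] - pos[2]) ** 2)
                free = ~forbidden[sl]
                if int(free.sum()) < s:
                    continue
                dd = np.where(free, dist, np.inf).ravel()
                pick = np.argpartition(dd, s - 1)[:s]
                if not np.isfinite(dd[pick]).all():
                    continue
                cluster = np.zeros(dist.shape, dtype=bool).ravel()
                cluster[pick] = True
                cluster = cluster.reshape(dist.shape)
                # accept only compact, fully detached picks
                lab, ncomp = ndimage.label(cluster, structure=_STRUCT6)
                if ncomp != 1:
                    continue
                occ[sl] |= cluster
                forbidden[sl] |= ndimage.binary_dilation(cluster, structure=_STRUCT6)
                placed += 1
                ok = True
                break
            if not ok:
                raise RuntimeError(
                    f"could not place satellite cluster of {s} voxels on a {size}^3 lattice"
                )
    return VoxelMask(occ, source_id=f"phantom:fragmented_tumor:{size}:f={fragmentation}:seed={seed}")


def _draw_continuous(rng: np.random.Generator, family: str, params, n: int) -> np.ndarray:
    if family == "normal":
        return rng.normal(params[0], params[1], n)
    if family == "logistic":
        return rng.logistic(params[0], params[1], n)
    if family == "beta_percent":
        return 100.0 * rng.beta(params[0], params[1], n)
    raise ValueError(f"unknown distribution family {family!r}")


def simulate_cohort(spec: CohortSimSpec | None = None) -> pd.DataFrame:
    """Simulate a per-patient cohort table.

    The STAS label is Bernoulli at the configured prevalence; every feature
    is drawn from its group-conditional distribution.  Because features are
    conditionally independent given the label, each binary feature's true
    coefficient in the joint logistic model of label on features equals its
    cross-product log odds ratio, which makes the simulator usable for
    parameter-recovery checks of the downstream regression machinery.
    """
    spec = spec or default_cohort_spec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    stas = (rng.random(n) < spec.prevalence).astype(int)
    data: dict[str, np.ndarray] = {
        "patient_id": np.array([f"P{i + 1:04d}" for i in range(n)]),
        "stas": stas,
    }
    pos = stas == 1
    for name, (pp, pn) in spec.binary_features.items():
        p = np.where(pos, pp, pn)
        data[name] = (rng.random(n) < p).astype(int)
    for name, (family, ppos, pneg) in spec.continuous_features.items():
        xpos = _draw_continuous(rng, family, ppos, n)
        xneg = _draw_continuous(rng, family, pneg, n)
        data[name] = np.where(pos, xpos, xneg)
    df = pd.DataFrame(data)
    if "ctr" in df:
        df["ctr"] = df["ctr"].clip(0.0, 100.0)
    return df
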