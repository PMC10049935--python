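"""Synthetic paired two-biometer cohorts.

The generator emulates same-day paired biometry exports of a cataract
population measured on two swept-source OCT devices, labelled Z
(reference) and H (comparison).  The generative model is

    measurement = latent truth + device offset + device noise

per variable.  Latent distances (AL, ACD, LT, with a moderate
correlation structure; CCT independent) are drawn from a truncated
multivariate normal; corneal surfaces are drawn as a latent mean radius
plus a latent astigmatism power vector, and each device observes the
surface through additive noise in power-vector space before the record
is re-expressed as flat/steep radii with a flat-meridian axis, which is
what real device exports contain.

Default parameters reproduce a cataractous cohort of 854 eyes: AL
23.85 +/- 1.49 mm, CCT 0.554 +/- 0.037 mm, ACD 3.15 +/- 0.40 mm,
LT 4.65 +/- 0.43 mm, front mean radius 7.73 mm, back mean radius
6.91 mm, with systematic device-H effects of +0.120 mm on ACD,
-0.0078 mm on CCT (with a thickness-dependent trend: thicker corneas
read relatively thinner on H), -0.397 mm on the back-surface mean
radius, and an essentially unbiased front surface.  Noise SDs are set
so the paired H-Z difference spreads match those systematics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PopulationParams",
    "default_population_params",
    "generate_cohort",
    "cohort_to_exports",
    "inject_defects",
    "BIOMETRY_COLUMNS",
    "KEY_COLUMNS",
]

KEY_COLUMNS = ("patient_id", "eye", "exam_date")
BIOMETRY_COLUMNS = ("al", "cct", "acd", "lt", "r1a", "r2a", "aa", "r1p", "r2p", "ap")


@dataclass(frozen=True)
class PopulationParams:
    """Population marginals, inter-device systematics and noise levels.

    Distances in mm, powers in dpt, axes in degrees.  ``*_offset``
    fields are systematic device-H minus device-Z effects; ``*_noise``
    fields are per-device measurement-error SDs (so a paired difference
    has spread sqrt(2) times the per-device value, plus any trend
    term).  ``cct_slope`` adds ``cct_slope * (CCT - cct_mean)`` to the
    H reading, producing the thickness-dependent disagreement.
    """

    n: int = 854
    seed: int = 0

    # latent distance marginals (truth level)
    al_mean: float = 23.8503
    al_sd: float = 1.4927
    cct_mean: float = 0.5544
    cct_sd: float = 0.0369
    acd_mean: float = 3.1523
    acd_sd: float = 0.3957
    lt_mean: float = 4.6477
    lt_sd: float = 0.4282

    # latent corneal surfaces: mean radius (mm) and astigmatism power
    # vector components (dpt, full steep-minus-flat cylinder)
    r12a_mean: float = 7.7336
    r12a_sd: float = 0.2616
    v0a_mean: float = 0.286
    v0a_sd: float = 1.188
    v45a_mean: float = -0.034
    v45a_sd: float = 0.660
    r12p_mean: float = 6.9085
    r12p_sd: float = 0.2717
    v0p_mean: float = -0.2545
    v0p_sd: float = 0.1556
    v45p_mean: float = -0.0452
    v45p_sd: float = 0.1021

    # systematic H - Z effects
    al_offset: float = -0.0146
    cct_offset: float = -0.0078
    cct_slope: float = -0.05
    acd_offset: float = 0.1200
    lt_offset: float = 0.0383
    front_radius_offset: float = -0.0004
    r12p_offset: float = -0.3970

    # per-device noise SDs
    al_noise: float = 0.0202
    cct_noise: float = 0.00448
    acd_noise: float = 0.0376
    lt_noise: float = 0.0421
    veqa_noise: float = 0.1855
    v0a_noise: float = 0.2308
    v45a_noise: float = 0.1867
    veqp_noise: float = 0.0458
    v0p_noise: float = 0.0485
    v45p_noise: float = 0.0508

    # latent correlation structure (assumed, not measured)
    corr_al_acd: float = 0.45
    corr_al_lt: float = -0.30
    corr_acd_lt: float = -0.45

    # truncation of latent marginals, in SD units around the mean
    truncation_sd: float = 3.5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be at least 1")
        for name in (
            "al_sd", "cct_sd", "acd_sd", "lt_sd", "r12a_sd", "r12p_sd",
            "v0a_sd", "v45a_sd", "v0p_sd", "v45p_sd",
            "al_noise", "cct_noise", "acd_noise", "lt_noise",
            "veqa_noise", "v0a_noise", "v45a_noise",
            "veqp_noise", "v0p_noise", "v45p_noise",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("corr_al_acd", "corr_al_lt", "corr_acd_lt"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1)")


def default_population_params(**overrides) -> PopulationParams:
    """The default cataract-population parameter set (854 paired eyes)."""
    return PopulationParams(**overrides)


def _truncated_normal(rng, mean, sd, k, size):
    """Rejection-sampled N(mean, sd) truncated to mean +/- k*sd."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    lo, hi = mean - k * sd, mean + k * sd
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _correlated_distances(rng, p: PopulationParams) -> tuple[np.ndarray, ...]:
    mean = np.array([p.al_mean, p.acd_mean, p.lt_mean])
    sd = np.array([p.al_sd, p.acd_sd, p.lt_sd])
    corr = np.array(
        [
            [1.0, p.corr_al_acd, p.corr_al_lt],
            [p.corr_al_acd, 1.0, p.corr_acd_lt],
            [p.corr_al_lt, p.corr_acd_lt, 1.0],
        ]
    )
    cov = corr * np.outer(sd, sd)
    draws = rng.multivariate_normal(mean, cov, size=p.n, method="cholesky")
    k = p.truncation_sd
    bad = np.any(np.abs(draws - mean) > k * sd, axis=1)
    while bad.any():
        draws[bad] = rng.multivariate_normal(mean, cov, size=int(bad.sum()), method="cholesky")
        bad = np.any(np.abs(draws - mean) > k * sd, axis=1)
    return draws[:, 0], draws[:, 1], draws[:, 2]


def _keratometry_from_power(veq, v0, v45, dn):
    """Re-express a surface power vector as (r1 flat, r2 steep, axis).

    The signed cylinder s = P_steep - P_flat has the sign of dn; the
    flat/steep meridional powers are veq -/+ s/2 and the flat-meridian
    axis is half the double angle of (v0, v45) in the signed-cylinder
    frame."""
    c = np.hypot(v0, v45)
    s = np.sign(dn) * c
    with np.errstate(invalid="ignore"):
        two_axis = np.where(
            c > 0, np.arctan2(np.sign(dn) * v45, np.sign(dn) * v0), 0.0
        )
    axis = np.mod(np.degrees(two_axis) / 2.0, 180.0)
    p1 = veq - 0.5 * s
    p2 = veq + 0.5 * s
    r1 = dn * 1000.0 / p1
    r2 = dn * 1000.0 / p2
    return r1, r2, axis


def generate_cohort(p: PopulationParams) -> pd.DataFrame:
    """Draw a paired cohort; one row per eye, device columns suffixed
    ``_z`` / ``_h``.  Deterministic given ``p.seed``."""
    rng = np.random.default_rng(p.seed)
    n, k = p.n, p.truncation_sd
    nc, na = 1.376, 1.336
    dn_front, dn_back = nc - 1.0, na - nc

    al, acd, lt = _correlated_distances(rng, p)
    cct = _truncated_normal(rng, p.cct_mean, p.cct_sd, k, n)
    # keep ACD physiologic relative to CCT
    acd = np.maximum(acd, cct + 1.0)

    r12a = _truncated_normal(rng, p.r12a_mean, p.r12a_sd, k, n)
    v0a = rng.normal(p.v0a_mean, p.v0a_sd, n)
    v45a = rng.normal(p.v45a_mean, p.v45a_sd, n)
    r12p = _truncated_normal(rng, p.r12p_mean, p.r12p_sd, k, n)
    v0p = rng.normal(p.v0p_mean, p.v0p_sd, n)
    v45p = rng.normal(p.v45p_mean, p.v45p_sd, n)

    frames = {}
    for dev in ("z", "h"):
        is_h = dev == "h"
        cols = {}
        cols["al"] = al + (p.al_offset if is_h else 0.0) + rng.normal(0, p.al_noise, n)
        cols["cct"] = (
            cct
            + (p.cct_offset + p.cct_slope * (cct - p.cct_mean) if is_h else 0.0)
            + rng.normal(0, p.cct_noise, n)
        )
        cols["acd"] = acd + (p.acd_offset if is_h else 0.0) + rng.normal(0, p.acd_noise, n)
        cols["lt"] = lt + (p.lt_offset if is_h else 0.0) + rng.normal(0, p.lt_noise, n)

        r12a_dev = r12a + (p.front_radius_offset if is_h else 0.0)
        veqa = dn_front * 1000.0 / r12a_dev + rng.normal(0, p.veqa_noise, n)
        cols["r1a"], cols["r2a"], cols["aa"] = _keratometry_from_power(
            veqa,
            v0a + rng.normal(0, p.v0a_noise, n),
            v45a + rng.normal(0, p.v45a_noise, n),
            dn_front,
        )
        r12p_dev = r12p + (p.r12p_offset if is_h else 0.0)
        veqp = dn_back * 1000.0 / r12p_dev + rng.normal(0, p.veqp_noise, n)
        cols["r1p"], cols["r2p"], cols["ap"] = _keratometry_from_power(
            veqp,
            v0p + rng.normal(0, p.v0p_noise, n),
            v45p + rng.normal(0, p.v45p_noise, n),
            dn_back,
        )
        frames[dev] = cols

    eye = np.where(rng.random(n) < 0.5, "R", "L")
    dates = pd.to_datetime("2021-01-04") + pd.to_timedelta(
        rng.integers(0, 365, n), unit="D"
    )
    out = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(1, n + 1)],
            "eye": eye,
            "exam_date": dates.strftime("%Y-%m-%d"),
        }
    )
    for dev in ("z", "h"):
        for col in BIOMETRY_COLUMNS:
            out[f"{col}_{dev}"] = frames[dev][col]
    return out


def cohort_to_exports(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a paired cohort into the two per-device export tables."""
    exports = []
    for dev in ("z", "h"):
        cols = {k: cohort[k] for k in KEY_COLUMNS}
        cols.update({c: cohort[f"{c}_{dev}"] for c in BIOMETRY_COLUMNS})
        exports.append(pd.DataFrame(cols))
    return exports[0], exports[1]


def inject_defects(
    cohort: pd.DataFrame,
    missing_rate: float = 0.0,
    duplicate_rate: float = 0.0,
    second_eye_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Corrupt a cohort so the ingestion filters have something to do.

    Blanks one random measured field per selected row (``missing_rate``),
    appends exact duplicate rows (``duplicate_rate``) and appends
    fellow-eye rows for randomly selected patients
    (``second_eye_rate``).  Deterministic given ``seed``."""
    for name, rate in (
        ("missing_rate", missing_rate),
        ("duplicate_rate", duplicate_rate),
        ("second_eye_rate", second_eye_rate),
    ):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    value_cols = [c for c in out.columns if c not in KEY_COLUMNS]

    miss = rng.random(len(out)) < missing_rate
    for i in np.flatnonzero(miss):
        col = value_cols[rng.integers(len(value_cols))]
        out.iloc[i, out.columns.get_loc(col)] = np.nan

    dup = out[rng.random(len(out)) < duplicate_rate]
    fellow = cohort[rng.random(len(cohort)) < second_eye_rate].copy()
    if len(fellow):
        fellow["eye"] = fellow["eye"].map({"R": "L", "L": "R"})
    return pd.concat([out, dup, fellow], ignore_index=True)
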