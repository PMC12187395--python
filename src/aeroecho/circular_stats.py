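"""Circular statistics for animal displacement and wind directions.

All angles follow the geographic convention: degrees clockwise from
geographic north in [0, 360), so 0° = north, 90° = east.  Under this
convention the unit vector of an angle a is (north, east) = (cos a, sin a)
and the north–south component of a direction sample is the mean cosine.

The Rayleigh test uses the standard small-sample-corrected exponential
approximation for the p-value; Watson's two-sample U² uses a permutation
null so it is valid at any sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DirectionalSummary",
    "WatsonU2Result",
    "circular_summary",
    "rayleigh_test",
    "watson_u2",
    "downwind_direction",
    "period_directionality",
    "circular_mean",
    "angular_deviation_deg",
    "circular_std_deg",
]

_R_UNDEFINED_TOL = 1e-12


@dataclass(frozen=True)
class DirectionalSummary:
    """Circular summary of a direction sample.

    Attributes
    ----------
    n : int
        Sample size.
    mean_direction : float
        Circular mean in degrees [0, 360); ``nan`` when undefined (r ≈ 0).
    r : float
        Mean resultant length in [0, 1].
    rayleigh_z : float
        Rayleigh statistic z = n·r².
    rayleigh_p : float
        p-value of the Rayleigh uniformity test, in (0, 1].
    ns_component : float
        Mean cosine of the sample: +1 due north, −1 due south.
    angular_deviation : float
        Circular dispersion sqrt(2·(1−r)) expressed in degrees.
    circular_std : float
        Circular standard deviation sqrt(−2·ln r) in degrees (inf at r=0).
    mean_defined : bool
        False when r is numerically zero and the mean direction is undefined.
    significant : bool
        True when rayleigh_p < 0.05.
    insufficient : bool
        Set by :func:`period_directionality` when n is below its minimum.
    """

    n: int
    mean_direction: float
    r: float
    rayleigh_z: float
    rayleigh_p: float
    ns_component: float
    angular_deviation: float
    circular_std: float
    mean_defined: bool = True
    significant: bool = False
    insufficient: bool = False


@dataclass(frozen=True)
class WatsonU2Result:
    """Two-sample Watson U² with permutation p-value."""

    u2: float
    p: float
    n1: int
    n2: int
    n_permutations: int
    ties_jittered: bool = False


def _to_radians(angles_deg: Sequence[float] | np.ndarray) -> np.ndarray:
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle sample")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    return np.deg2rad(a)


def circular_mean(angles_deg: Sequence[float] | np.ndarray) -> float:
    """Circular mean direction in degrees [0, 360); nan if resultant is zero."""
    rad = _to_radians(angles_deg)
    c, s = np.cos(rad).sum(), np.sin(rad).sum()
    if np.hypot(c, s) / rad.size < _R_UNDEFINED_TOL:
        return float("nan")
    return float(np.rad2deg(np.arctan2(s, c)) % 360.0)


def angular_deviation_deg(r: float) -> float:
    """Angular deviation sqrt(2(1-r)), mapped from radians to degrees."""
    return float(np.rad2deg(np.sqrt(max(0.0, 2.0 * (1.0 - r)))))


def circular_std_deg(r: float) -> float:
    """Circular standard deviation sqrt(-2 ln r) in degrees; inf at r = 0."""
    if r <= 0.0:
        return float("inf")
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(min(r, 1.0)))))


def _rayleigh_p(n: int, r: float) -> tuple[float, float]:
    z = n * r * r
    # Small-sample-corrected exponential approximation (Zar / Fisher).
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return float(z), float(min(max(p, np.finfo(float).tiny), 1.0))


def circular_summary(angles_deg: Sequence[float] | np.ndarray) -> DirectionalSummary:
    """Summarise a sample of geographic directions.

    C = Σ cos, S = Σ sin over the angles in radians; r = |resultant| / n;
    the mean direction is atan2(S, C) mapped back to [0, 360).  Because 0°
    is north, the north–south component is the mean cosine C/n.
    """
    rad = _to_radians(angles_deg)
    n = rad.size
    c, s = np.cos(rad).sum(), np.sin(rad).sum()
    r = float(np.hypot(c, s) / n)
    r = min(r, 1.0)
    defined = r > _R_UNDEFINED_TOL
    mean_dir = float(np.rad2deg(np.arctan2(s, c)) % 360.0) if defined else float("nan")
    z, p = _rayleigh_p(n, r)
    return DirectionalSummary(
        n=int(n),
        mean_direction=mean_dir,
        r=r,
        rayleigh_z=z,
        rayleigh_p=p,
        ns_component=float(c / n),
        angular_deviation=angular_deviation_deg(r),
        circular_std=circular_std_deg(r),
        mean_defined=defined,
        significant=p < 0.05,
    )


def rayleigh_test(angles_deg: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Rayleigh test of circular uniformity.

    Returns (z, p) with z = n·r².  Requires n ≥ 3 for the analytic
    approximation; for smaller samples use a permutation approach.
    """
    rad = _to_radians(angles_deg)
    n = rad.size
    if n < 3:
        raise ValueError(
            "Rayleigh analytic approximation needs n >= 3; "
            "use a permutation test for smaller samples"
        )
    r = float(np.hypot(np.cos(rad).sum(), np.sin(rad).sum()) / n)
    return _rayleigh_p(n, min(r, 1.0))


def _watson_u2_stat(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample Watson U² from the combined circular ordering.

    Standard rank formulation: with the pooled sorted sample, track the
    cumulative empirical-CDF difference d_k between the two samples and
    form U² = (n·m/N²)·(Σ d_k² − (Σ d_k)²/N).
    """
    n, m = x.size, y.size
    big_n = n + m
    pooled = np.concatenate([x, y])
    labels = np.concatenate([np.zeros(n), np.ones(m)])
    order = np.argsort(pooled, kind="mergesort")
    lab = labels[order]
    cdf_x = np.cumsum(lab == 0) / n
    cdf_y = np.cumsum(lab == 1) / m
    d = cdf_x - cdf_y
    return float(n * m / big_n**2 * (np.sum(d * d) - np.sum(d) ** 2 / big_n))


def watson_u2(
    sample_a: Sequence[float] | np.ndarray,
    sample_b: Sequence[float] | np.ndarray,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> WatsonU2Result:
    """Two-sample Watson U² test of equality of circular distributions.

    Significance by permutation of pooled sample labels:
    p = (1 + #{permuted U² ≥ observed}) / (n_permutations + 1).
    The statistic is invariant to a joint rotation of both samples.  Heavy
    ties (> 50% duplicated pooled values) are broken by a tiny stable
    jitter drawn from the recorded seed.
    """
    a = np.asarray(sample_a, dtype=float) % 360.0
    b = np.asarray(sample_b, dtype=float) % 360.0
    if a.size < 8 or b.size < 8:
        raise ValueError("watson_u2 requires at least 8 observations per sample")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    ties_jittered = False
    n_dup = pooled.size - np.unique(pooled).size
    if n_dup > 0.5 * pooled.size:
        ties_jittered = True
        jitter = rng.uniform(-1e-9, 1e-9, size=pooled.size)
        pooled = (pooled + jitter) % 360.0
        a, b = pooled[: a.size], pooled[a.size :]

    observed = _watson_u2_stat(a, b)
    pooled = np.concatenate([a, b])
    n = a.size
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if _watson_u2_stat(perm[:n], perm[n:]) >= observed:
            count += 1
    p = (1.0 + count) / (n_permutations + 1.0)
    return WatsonU2Result(
        u2=observed,
        p=p,
        n1=int(a.size),
        n2=int(b.size),
        n_permutations=int(n_permutations),
        ties_jittered=ties_jittered,
    )


def downwind_direction(u: float | np.ndarray, v: float | np.ndarray) -> float | np.ndarray:
    """Direction toward which the air moves, degrees clockwise from north.

    u is the eastward and v the northward wind component (m/s); a pure
    westerly (u > 0, v = 0) blows toward 90°.  Calm air (0, 0) has no
    downwind direction and yields nan.
    """
    u_arr = np.asarray(u, dtype=float)
    v_arr = np.asarray(v, dtype=float)
    out = np.rad2deg(np.arctan2(u_arr, v_arr)) % 360.0
    calm = (u_arr == 0.0) & (v_arr == 0.0)
    if np.isscalar(u) and np.isscalar(v):
        return float("nan") if calm else float(out)
    return np.where(calm, np.nan, out)


def period_directionality(
    directions_deg: Sequence[float] | np.ndarray,
    n_min: int = 10,
) -> DirectionalSummary:
    """Directional summary of one diel period's echoes.

    Missing directions (NaN) are dropped first — only the rotating-antenna
    fraction of echoes carries displacement directions.  Periods with fewer
    than ``n_min`` directional echoes are flagged insufficient (their
    summary is still computed when n ≥ 1).
    """
    a = np.asarray(directions_deg, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        return DirectionalSummary(
            n=0,
            mean_direction=float("nan"),
            r=0.0,
            rayleigh_z=0.0,
            rayleigh_p=1.0,
            ns_component=float("nan"),
            angular_deviation=angular_deviation_deg(0.0),
            circular_std=float("inf"),
            mean_defined=False,
            significant=False,
            insufficient=True,
        )
    summ = circular_summary(a)
    if a.size < n_min:
        summ = DirectionalSummary(**{**summ.__dict__, "insufficient": True})
    return summ
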