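"""Synthetic weekly attendance-count generation.

The generator emulates the statistical regime of the national ED series the
analysis was built for: a roughly flat, slightly declining pre-period around
200,000 attendances/week over 2019, a 4-week transition window in spring
2020, an abrupt level drop of about half the baseline, and a linear
recovery through mid-2020.  Week means follow the segmented-model truth

    mu(w) = i + t*w                                   (pre-window weeks)
    mu(w) = i + t*w + p + s*(w - w_ref)               (post-window weeks)

with interruption-window weeks filled by linear interpolation between the
two segment endpoints — those weeks are excluded from every fit, so the
fill only matters for plotting.  Counts are drawn around mu(w) from one of
three noise families: gaussian(sigma), poisson, or negative_binomial(theta)
with variance mu + mu**2/theta.

Subgrouped datasets split the baseline across levels by share and give each
level its own planted step and slope-change (via multipliers), which is what
the subgroup machinery's recovery tests exercise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CoefficientSet, InterruptionSpec, WeeklySeries
from .exceptions import ConfigError

#: Default gaussian noise scale (counts/week), matching the visible
#: pre-period scatter of the reference series (~181,500-209,100 around a
#: near-flat trend).
DEFAULT_SIGMA = 3000.0


@dataclass(frozen=True)
class SubgroupLevel:
    """One planted subgroup level: its baseline share and effect multipliers."""
    grouping: str
    level: str
    share: float
    p_multiplier: float = 1.0
    s_multiplier: float = 1.0


@dataclass
class SyntheticConfig:
    """Configuration of a synthetic weekly-count dataset.

    Parameters
    ----------
    truth : CoefficientSet
        True (i, t, p, s) on the count scale; defaults to the reference fit.
    spec : InterruptionSpec
        Interruption window; defaults to weeks 63-66.
    n_weeks : int
        Total span (default 78 = 52 weeks of 2019 + 26 of 2020).
    noise : tuple
        ("gaussian", sigma), ("poisson",) or ("negative_binomial", theta).
    subgroup_plan : list of SubgroupLevel, optional
        Within each grouping, shares must sum to 1 and be positive.
    seed : int
        Master seed; per-level streams are derived deterministically.
    """

    truth: CoefficientSet | None = None
    spec: InterruptionSpec = field(default_factory=InterruptionSpec)
    n_weeks: int = 78
    noise: tuple = ("gaussian", DEFAULT_SIGMA)
    subgroup_plan: list[SubgroupLevel] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.truth is None:
            from .datasets import reference_fit
            self.truth = reference_fit()
        if self.n_weeks < self.spec.reference_week + 1:
            raise ConfigError(
                "n_weeks must extend at least one week past the reference week"
            )
        fam = self.noise[0]
        if fam not in ("gaussian", "poisson", "negative_binomial"):
            raise ConfigError(f"unknown noise family {fam!r}")
        if fam == "gaussian":
            if len(self.noise) != 2 or not self.noise[1] >= 0:
                raise ConfigError("gaussian noise needs a non-negative sigma")
        elif fam == "negative_binomial":
            if len(self.noise) != 2 or not self.noise[1] > 0:
                raise ConfigError("negative_binomial noise needs a positive theta")
        if self.subgroup_plan is not None:
            by_grouping: dict[str, float] = {}
            for lvl in self.subgroup_plan:
                if not 0 < lvl.share <= 1:
                    raise ConfigError(
                        f"share for {lvl.grouping}:{lvl.level} must be in (0, 1]"
                    )
                by_grouping[lvl.grouping] = by_grouping.get(lvl.grouping, 0.0) + lvl.share
            for g, total in by_grouping.items():
                if not np.isclose(total, 1.0):
                    raise ConfigError(
                        f"shares for grouping {g!r} sum to {total:.4f}, expected 1"
                    )


def level_seed(master_seed: int, grouping: str, level: str) -> int:
    """Deterministic per-level seed: master + CRC32 of 'grouping:level',
    reduced below 2**31."""
    h = zlib.crc32(f"{grouping}:{level}".encode())
    return (int(master_seed) + h) % (2**31)


def _mean_profile(truth: CoefficientSet, spec: InterruptionSpec,
                  n_weeks: int) -> tuple[np.ndarray, np.ndarray]:
    """Weekly means over 1..n_weeks, window weeks linearly interpolated."""
    w = np.arange(1, n_weeks + 1, dtype=float)
    pre_mu = truth.i + truth.t * w
    post_mu = truth.i + truth.t * w + truth.p + truth.s * (w - spec.reference_week)
    mu = np.where(w >= spec.reference_week, post_mu, pre_mu)
    inside = spec.in_window(w)
    if inside.any():
        # join the last pre-window mean to the reference-week mean
        w0, w1 = spec.gap_start_week - 1, spec.reference_week
        mu0 = truth.i + truth.t * w0
        mu1 = truth.i + truth.t * w1 + truth.p
        frac = (w[inside] - w0) / (w1 - w0)
        mu[inside] = mu0 + frac * (mu1 - mu0)
    return w.astype(int), mu


def _draw(mu: np.ndarray, noise: tuple, rng: np.random.Generator) -> np.ndarray:
    fam = noise[0]
    if fam == "gaussian":
        sigma = noise[1]
        counts = mu + sigma * rng.standard_normal(mu.size)
        return np.maximum(counts, 0.0)
    if fam == "poisson":
        return rng.poisson(mu).astype(float)
    theta = noise[1]
    # NB2 as gamma-poisson mixture: lambda ~ Gamma(theta, mu/theta)
    lam = rng.gamma(shape=theta, scale=mu / theta)
    return rng.poisson(lam).astype(float)


def generate_series(config: SyntheticConfig, *, truth: CoefficientSet | None = None,
                    seed: int | None = None, label: str | None = None) -> WeeklySeries:
    """Generate one weekly series from the configured truth and noise.

    Raises :class:`ConfigError` before sampling if any implied mean is
    negative.  Deterministic given the seed.
    """
    truth = truth if truth is not None else config.truth
    weeks, mu = _mean_profile(truth, config.spec, config.n_weeks)
    if np.any(mu < 0):
        bad = weeks[mu < 0][0]
        raise ConfigError(f"implied mean count negative at week {bad}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    counts = _draw(mu, config.noise, rng)
    return WeeklySeries(weeks, counts, label=label)


def _level_truth(base: CoefficientSet, lvl: SubgroupLevel) -> CoefficientSet:
    """Planted truth for one level: share of the baseline, own step/slope."""
    return CoefficientSet(
        i=base.i * lvl.share, t=base.t * lvl.share,
        p=base.p * lvl.share * lvl.p_multiplier,
        s=base.s * lvl.share * lvl.s_multiplier,
        se_i=0.0, se_t=0.0, se_p=0.0, se_s=0.0,
        pvalues=np.full(4, np.nan), covariance=np.zeros((4, 4)),
        model_family="linear",
    )


def generate_subgrouped_dataset(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a long-format weekly table with subgroup columns.

    One row per (grouping, level, week) with columns ``grouping``,
    ``subgroup``, ``week`` and ``count``.  Each level's series is drawn
    independently with a seed derived from the master seed and the level
    label, so the full dataset is reproducible from ``config.seed`` alone.
    """
    if not config.subgroup_plan:
        raise ConfigError("subgroup_plan required for subgrouped generation")
    frames = []
    for lvl in config.subgroup_plan:
        truth = _level_truth(config.truth, lvl)
        s = generate_series(
            config, truth=truth,
            seed=level_seed(config.seed, lvl.grouping, lvl.level),
            label=lvl.level,
        )
        frames.append(pd.DataFrame({
            "grouping": lvl.grouping, "subgroup": lvl.level,
            "week": s.week, "count": s.count,
        }))
    return pd.concat(frames, ignore_index=True)
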