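"""Seeded synthetic cytometry events and CASA tracks with known truth.

The generator emulates a boar-stud storage study: ``boars`` males, several
ejaculates each, every dose analysed fresh (D0) and after cooled storage
(D11).  Per-cell fluorescence is drawn from log-normal mixture components on
the channel scale (the cytometry convention for positively skewed
fluorescence), with a broad low-intensity debris component; boar and
ejaculate identities act as Gaussian random effects on logit-(fractions) or
log-(intensities) transformed truth parameters, and storage day is a fixed
shift whose default direction and size follow the changes the assays are
designed to detect (large disulfide loss and mBBr redistribution, small %DFI
and 8-oxo-dG increases, near-null CMA3 boar variance).

Every simulated table carries a ``truth`` record holding the *model-implied*
value of each downstream statistic for that sample (gate fractions
integrated against the realized mixture, mixture medians solved numerically,
DFI tail probabilities), so truth-recovery tests compare each estimator with
its actual estimand, not with a nominal component weight.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Any, Callable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .config import Thresholds
from .motility import kinematics_frame
from .tables import KINEMATIC_COLUMNS, EventTable, KinematicTable

__all__ = [
    "StudyDesign",
    "LogNormal",
    "mixture_median",
    "mixture_median_se",
    "ScsaTruth",
    "MbbrTruth",
    "Cma3Truth",
    "OxoDgTruth",
    "Phys1Truth",
    "Phys2Truth",
    "KinematicComponent",
    "CasaTruth",
    "default_truths",
    "simulate_scsa_events",
    "simulate_stain_pair_mbbr",
    "simulate_cma3_events",
    "simulate_oxodg_events",
    "simulate_phys1_events",
    "simulate_phys2_events",
    "simulate_casa_sample",
    "generate_study",
    "iter_study",
    "StudyBundle",
    "SampleData",
]


def as_rng(seed: int | SeedSequence | Generator | None) -> Generator:
    if isinstance(seed, Generator):
        return seed
    return default_rng(seed)


# ---------------------------------------------------------------------------
# distribution helpers

@dataclass(frozen=True)
class LogNormal:
    """Log-normal on the channel scale, parameterised by median and the
    standard deviation of the natural log (sigma = 0 gives a point mass)."""

    median: float
    sigma: float

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError("median must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def sample(self, rng: Generator, n: int) -> np.ndarray:
        if self.sigma == 0:
            return np.full(n, self.median)
        return self.median * np.exp(self.sigma * rng.standard_normal(n))

    def cdf(self, x: float) -> float:
        if x <= 0:
            return 0.0
        if self.sigma == 0:
            return float(x >= self.median)
        return float(norm.cdf((math.log(x) - math.log(self.median)) / self.sigma))

    def sf(self, x: float) -> float:
        return 1.0 - self.cdf(x)

    def pdf(self, x: float) -> float:
        if x <= 0 or self.sigma == 0:
            return 0.0
        z = (math.log(x) - math.log(self.median)) / self.sigma
        return float(norm.pdf(z) / (x * self.sigma))

    def scaled(self, factor: float) -> "LogNormal":
        return LogNormal(self.median * factor, self.sigma)


def mixture_median(
    weights: Sequence[float], comps: Sequence[LogNormal]
) -> float:
    """Median of a log-normal mixture (numerical root of the CDF)."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    def f(x: float) -> float:
        return sum(wi * c.cdf(x) for wi, c in zip(w, comps)) - 0.5

    lo = min(c.median for c in comps) * 1e-3
    hi = max(c.median for c in comps) * 1e3
    return float(brentq(f, lo, hi, xtol=1e-9, rtol=1e-12))


def mixture_median_se(
    weights: Sequence[float], comps: Sequence[LogNormal], n: int
) -> float:
    """Large-sample standard error of the sample median of a mixture,
    SE = 1 / (2 f(m) sqrt(n)) with f the mixture density at the median."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    m = mixture_median(w, comps)
    dens = sum(wi * c.pdf(m) for wi, c in zip(w, comps))
    return 1.0 / (2.0 * dens * math.sqrt(n))


def _ratio_tail_prob(
    num: LogNormal, den: LogNormal, ratio_cut: float
) -> float:
    """P(num/den > ratio_cut) for independent log-normals."""
    mu = math.log(num.median) - math.log(den.median)
    s = math.hypot(num.sigma, den.sigma)
    if s == 0:
        return float(mu > math.log(ratio_cut))
    return float(norm.sf((math.log(ratio_cut) - mu) / s))


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# study design

@dataclass(frozen=True)
class StudyDesign:
    """Study layout: boars x ejaculates x analysis days."""

    boars: int = 36
    ejaculates_per_boar: int = 3
    days: tuple[str, ...] = ("D0", "D11")
    events_per_sample: int = 5000
    casa_cells_per_sample: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boars < 1 or self.ejaculates_per_boar < 1:
            raise ValueError("boars and ejaculates_per_boar must be >= 1")
        if self.events_per_sample < 1 or self.casa_cells_per_sample < 1:
            raise ValueError("per-sample cell counts must be >= 1")
        if len(self.days) < 1:
            raise ValueError("at least one analysis day required")

    @property
    def n_samples(self) -> int:
        return self.boars * self.ejaculates_per_boar * len(self.days)

    def sample_frame(self) -> pd.DataFrame:
        rows = []
        for b in range(1, self.boars + 1):
            for e in range(1, self.ejaculates_per_boar + 1):
                for day in self.days:
                    rows.append(
                        {
                            "sample_id": f"B{b:02d}_E{e}_{day}",
                            "boar": f"B{b:02d}",
                            "ejaculate": f"E{e}",
                            "day": day,
                        }
                    )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random-effect machinery

@dataclass(frozen=True)
class Effect:
    """How a truth parameter responds to boar/ejaculate/day.

    ``scale`` is ``"logit"`` for proportions or ``"log"`` for positive
    quantities; ``day_shift`` is added on that scale for the storage day.
    """

    scale: str
    boar_sd: float = 0.0
    ejaculate_sd: float = 0.0
    day_shift: float = 0.0

    def apply(self, value: float, zb: float, ze: float, day_on: bool) -> float:
        shift = self.boar_sd * zb + self.ejaculate_sd * ze
        if day_on:
            shift += self.day_shift
        if self.scale == "logit":
            return float(expit(logit(value) + shift))
        if self.scale == "log":
            return float(value * math.exp(shift))
        raise ValueError(f"unknown effect scale {self.scale!r}")


class _TruthBase:
    """Mixin: apply per-parameter random effects declared in ``EFFECTS``."""

    EFFECTS: Mapping[str, Effect] = {}

    def realize(
        self,
        zb: Mapping[str, float],
        ze: Mapping[str, float],
        day_on: bool,
    ):
        updates = {}
        for name, eff in self.EFFECTS.items():
            value = getattr(self, name)
            updates[name] = eff.apply(
                value, zb.get(name, 0.0), ze.get(name, 0.0), day_on
            )
        return dataclasses.replace(self, **updates)

    @classmethod
    def effect_names(cls) -> list[str]:
        return sorted(cls.EFFECTS)


# ---------------------------------------------------------------------------
# SCSA

@dataclass(frozen=True)
class ScsaTruth(_TruthBase):
    """Acridine-orange mixture: main population (high green / low red), a
    fragmented tail whose red shift puts per-cell DFI above 250, a
    high-green (high-stainability) component, and AO double-negative
    debris."""

    frac_dfi: float = 0.011
    frac_hds: float = 0.045
    debris: float = 0.05
    main_green: float = 500.0
    main_green_sigma: float = 0.08
    main_red: float = 70.0
    main_red_sigma: float = 0.15
    frag_green: float = 300.0
    frag_green_sigma: float = 0.10
    frag_red: float = 350.0
    frag_red_sigma: float = 0.15
    hds_green: float = 850.0
    hds_green_sigma: float = 0.07
    debris_level: float = 10.0
    debris_sigma: float = 0.45

    EFFECTS = {
        "frac_dfi": Effect("logit", boar_sd=0.25, ejaculate_sd=0.10, day_shift=0.23),
        "frac_hds": Effect("logit", boar_sd=0.25, ejaculate_sd=0.10, day_shift=0.10),
        "debris": Effect("logit", boar_sd=0.15, ejaculate_sd=0.05),
    }

    def __post_init__(self) -> None:
        for name in ("frac_dfi", "frac_hds", "debris"):
            _check_fraction(name, getattr(self, name))
        if self.frac_dfi + self.frac_hds > 1.0:
            raise ValueError("sperm component fractions exceed 1")

    def components(self) -> list[tuple[float, dict[str, LogNormal], str]]:
        sperm = 1.0 - self.debris
        return [
            (
                sperm * (1.0 - self.frac_dfi - self.frac_hds),
                {
                    "green": LogNormal(self.main_green, self.main_green_sigma),
                    "red": LogNormal(self.main_red, self.main_red_sigma),
                },
                "main",
            ),
            (
                sperm * self.frac_dfi,
                {
                    "green": LogNormal(self.frag_green, self.frag_green_sigma),
                    "red": LogNormal(self.frag_red, self.frag_red_sigma),
                },
                "fragmented",
            ),
            (
                sperm * self.frac_hds,
                {
                    "green": LogNormal(self.hds_green, self.hds_green_sigma),
                    "red": LogNormal(self.main_red, self.main_red_sigma),
                },
                "hds",
            ),
            (
                self.debris,
                {
                    "green": LogNormal(self.debris_level, self.debris_sigma),
                    "red": LogNormal(self.debris_level, self.debris_sigma),
                },
                "debris",
            ),
        ]

    def implied(self, th: Thresholds) -> dict[str, float]:
        comps = self.components()
        cut = th.nuclear_cut
        # an event is kept unless both AO channels are at/below the cut
        keep = [
            1.0 - c["green"].cdf(cut) * c["red"].cdf(cut) for _, c, _ in comps
        ]
        w = np.array([wi for wi, _, _ in comps])
        p_kept = float(np.sum(w * keep))
        ratio_cut = th.dfi_cut / (1000.0 - th.dfi_cut)  # DFI>cut <=> red/green>r
        p_dfi = sum(
            wi * ki * _ratio_tail_prob(c["red"], c["green"], ratio_cut)
            for (wi, c, _), ki in zip(comps, keep)
        )
        p_hds = sum(
            wi * ki * c["green"].sf(th.hds_cut)
            for (wi, c, _), ki in zip(comps, keep)
        )
        return {
            "pct_dfi": 100.0 * p_dfi / p_kept,
            "pct_hds": 100.0 * p_hds / p_kept,
            "debris": 100.0 * (1.0 - p_kept),
        }


# ---------------------------------------------------------------------------
# generic mixture sampler

def _sample_mixture(
    rng: Generator,
    n: int,
    comps: Sequence[tuple[float, Mapping[str, LogNormal], str]],
    channel_max: float,
) -> tuple[pd.DataFrame, np.ndarray, int]:
    weights = np.array([w for w, _, _ in comps], dtype=float)
    if np.any(weights < 0):
        raise ValueError("negative mixture weight")
    if not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("mixture fractions must sum to 1")
    weights = weights / weights.sum()
    idx = rng.choice(len(comps), size=n, p=weights)
    channels = list(comps[0][1])
    data = {}
    n_clipped = 0
    for ch in channels:
        med = np.array([c[ch].median for _, c, _ in comps])
        sig = np.array([c[ch].sigma for _, c, _ in comps])
        vals = med[idx] * np.exp(sig[idx] * rng.standard_normal(n))
        n_clipped += int(np.sum(vals > channel_max))
        data[ch] = np.clip(vals, 0.0, channel_max)
    labels = np.array([comps[i][2] for i in idx])
    return pd.DataFrame(data), labels, n_clipped


def simulate_scsa_events(
    truth: ScsaTruth,
    n: int,
    seed: int | SeedSequence | Generator | None = None,
    thresholds: Thresholds | None = None,
    sample_id: str = "sample",
) -> EventTable:
    """Simulate one SCSA acquisition of ``n`` events."""
    if n < 1:
        raise ValueError("n must be >= 1")
    th = thresholds or Thresholds()
    rng = as_rng(seed)
    data, labels, n_clipped = _sample_mixture(
        rng, n, truth.components(), th.channel_max
    )
    rec: dict[str, Any] = truth.implied(th)
    rec["params"] = dataclasses.asdict(truth)
    return EventTable(
        sample_id=sample_id,
        assay="SCSA",
        data=data,
        channel_max=th.channel_max,
        n_clipped=n_clipped,
        truth=rec,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# mBBr (thiol/disulfide) pair

@dataclass(frozen=True)
class MbbrTruth(_TruthBase):
    """mBBr fluorescence as a low/moderate/high mixture; the DTT-reduced
    split shifts every sperm component up so its mixture median exceeds the
    untreated one by twice the intended disulfide index (raw channel
    units)."""

    frac_low: float = 0.069
    frac_high: float = 0.048
    debris: float = 0.05
    mfi: float = 200.0            # scales all sperm component medians
    disulfide: float = 33.0       # (median_dtt - median_untreated) / 2
    low_median: float = 60.0
    mod_median: float = 200.0
    high_median: float = 650.0
    comp_sigma: float = 0.12
    pi_sperm: float = 600.0
    pi_sperm_sigma: float = 0.15
    pi_debris: float = 15.0
    debris_mbbr: float = 20.0
    debris_sigma: float = 0.5

    EFFECTS = {
        "frac_low": Effect("logit", boar_sd=0.25, ejaculate_sd=0.10, day_shift=1.95),
        "frac_high": Effect("logit", boar_sd=0.25, ejaculate_sd=0.10, day_shift=-1.44),
        "mfi": Effect("log", boar_sd=0.05, ejaculate_sd=0.02, day_shift=math.log(1.24)),
        "disulfide": Effect("log", boar_sd=0.08, ejaculate_sd=0.03,
                            day_shift=math.log(21.31 / 33.28)),
        "debris": Effect("logit", boar_sd=0.15, ejaculate_sd=0.05),
    }

    def __post_init__(self) -> None:
        for name in ("frac_low", "frac_high", "debris"):
            _check_fraction(name, getattr(self, name))
        if self.frac_low + self.frac_high > 1.0:
            raise ValueError("sperm component fractions exceed 1")
        if self.mfi <= 0:
            raise ValueError("mfi must be positive")
        if self.disulfide < 0:
            raise ValueError("disulfide index truth must be nonnegative")

    def _sperm_weights(self) -> np.ndarray:
        return np.array(
            [self.frac_low, 1.0 - self.frac_low - self.frac_high, self.frac_high]
        )

    def _sperm_comps(self, factor: float = 1.0) -> list[LogNormal]:
        scale = self.mfi / 200.0 * factor
        return [
            LogNormal(self.low_median * scale, self.comp_sigma),
            LogNormal(self.mod_median * scale, self.comp_sigma),
            LogNormal(self.high_median * scale, self.comp_sigma),
        ]

    def untreated_median(self) -> float:
        return mixture_median(self._sperm_weights(), self._sperm_comps())

    def dtt_factor(self) -> float:
        m = self.untreated_median()
        if self.disulfide < 0:
            raise ValueError("disulfide index truth must be nonnegative")
        return (m + 2.0 * self.disulfide) / m

    def components(self, split: str) -> list[tuple[float, dict[str, LogNormal], str]]:
        factor = 1.0 if split == "untreated" else self.dtt_factor()
        sperm_w = (1.0 - self.debris) * self._sperm_weights()
        comps = []
        for w, ln, name in zip(
            sperm_w, self._sperm_comps(factor), ("low", "moderate", "high")
        ):
            comps.append(
                (
                    float(w),
                    {
                        "mbbr": ln,
                        "pi": LogNormal(self.pi_sperm, self.pi_sperm_sigma),
                    },
                    name,
                )
            )
        comps.append(
            (
                self.debris,
                {
                    "mbbr": LogNormal(self.debris_mbbr, self.debris_sigma),
                    "pi": LogNormal(self.pi_debris, self.debris_sigma),
                },
                "debris",
            )
        )
        return comps

    def implied(self, th: Thresholds) -> dict[str, float]:
        w = self._sperm_weights()
        comps = self._sperm_comps()
        low_cut, high_cut = th.mbbr_bounds
        p_low = float(sum(wi * c.cdf(low_cut) for wi, c in zip(w, comps)))
        p_high = float(sum(wi * c.sf(high_cut) for wi, c in zip(w, comps)))
        m_untr = mixture_median(w, comps)
        m_dtt = mixture_median(w, self._sperm_comps(self.dtt_factor()))
        ref = th.mbbr_reference
        return {
            "pct_low": 100.0 * p_low,
            "pct_moderate": 100.0 * (1.0 - p_low - p_high),
            "pct_high": 100.0 * p_high,
            "mfi_norm": m_untr / ref,
            "disulfide_index": (m_dtt - m_untr) / 2.0 / ref,
            "debris": 100.0 * self.debris,
        }


def simulate_stain_pair_mbbr(
    truth: MbbrTruth,
    n: int,
    seed: int | SeedSequence | Generator | None = None,
    thresholds: Thresholds | None = None,
    sample_id: str = "sample",
) -> tuple[EventTable, EventTable]:
    """Simulate the untreated / DTT-reduced mBBr split pair."""
    if n < 1:
        raise ValueError("n must be >= 1")
    th = thresholds or Thresholds()
    rng = as_rng(seed)
    rec: dict[str, Any] = truth.implied(th)
    rec["params"] = dataclasses.asdict(truth)
    tables = []
    for split, assay in (("untreated", "MBBR"), ("dtt", "MBBR_DTT")):
        data, labels, n_clipped = _sample_mixture(
            rng, n, truth.components(split), th.channel_max
        )
        tables.append(
            EventTable(
                sample_id=sample_id,
                assay=assay,
                data=data,
                channel_max=th.channel_max,
                n_clipped=n_clipped,
                truth=rec,
                labels=labels,
            )
        )
    return tables[0], tables[1]


# ---------------------------------------------------------------------------
# CMA3

@dataclass(frozen=True)
class Cma3Truth(_TruthBase):
    """Chromomycin A3 low/moderate/high mixture with a Hoechst nuclear
    gate; boar variance deliberately small (protamination is homogeneous in
    a production stud)."""

    frac_low: float = 0.061
    frac_high: float = 0.0645
    debris: float = 0.05
    mfi: float = 200.0
    low_median: float = 60.0
    mod_median: float = 200.0
    high_median: float = 650.0
    comp_sigma: float = 0.12
    h342_sperm: float = 600.0
    h342_sperm_sigma: float = 0.15
    h342_debris: float = 15.0
    debris_cma3: float = 20.0
    debris_sigma: float = 0.5

    EFFECTS = {
        "frac_low": Effect("logit", boar_sd=0.05, ejaculate_sd=0.05, day_shift=-0.075),
        "frac_high": Effect("logit", boar_sd=0.05, ejaculate_sd=0.05, day_shift=0.165),
        "mfi": Effect("log", boar_sd=0.01, ejaculate_sd=0.005,
                      day_shift=math.log(1.099 / 1.083)),
        "debris": Effect("logit", boar_sd=0.15, ejaculate_sd=0.05),
    }

    def __post_init__(self) -> None:
        for name in ("frac_low", "frac_high", "debris"):
            _check_fraction(name, getattr(self, name))
        if self.frac_low + self.frac_high > 1.0:
            raise ValueError("sperm component fractions exceed 1")

    def _sperm_weights(self) -> np.ndarray:
        return np.array(
            [self.frac_low, 1.0 - self.frac_low - self.frac_high, self.frac_high]
        )

    def _sperm_comps(self) -> list[LogNormal]:
        scale = self.mfi / 200.0
        return [
            LogNormal(self.low_median * scale, self.comp_sigma),
            LogNormal(self.mod_median * scale, self.comp_sigma),
            LogNormal(self.high_median * scale, self.comp_sigma),
        ]

    def components(self) -> list[tuple[float, dict[str, LogNormal], str]]:
        sperm_w = (1.0 - self.debris) * self._sperm_weights()
        comps = []
        for w, ln, name in zip(
            sperm_w, self._sperm_comps(), ("low", "moderate", "high")
        ):
            comps.append(
                (
                    float(w),
                    {
                        "cma3": ln,
                        "h342": LogNormal(self.h342_sperm, self.h342_sperm_sigma),
                    },
                    name,
                )
            )
        comps.append(
            (
                self.debris,
                {
                    "cma3": LogNormal(self.debris_cma3, self.debris_sigma),
                    "h342": LogNormal(self.h342_debris, self.debris_sigma),
                },
                "debris",
            )
        )
        return comps

    def implied(self, th: Thresholds) -> dict[str, float]:
        w = self._sperm_weights()
        comps = self._sperm_comps()
        low_cut, high_cut = th.cma3_bounds
        p_low = float(sum(wi * c.cdf(low_cut) for wi, c in zip(w, comps)))
        p_high = float(sum(wi * c.sf(high_cut) for wi, c in zip(w, comps)))
        return {
            "pct_low": 100.0 * p_low,
            "pct_moderate": 100.0 * (1.0 - p_low - p_high),
            "pct_high": 100.0 * p_high,
            "mfi_norm": mixture_median(w, comps) / th.cma3_reference,
            "debris": 100.0 * self.debris,
        }


def simulate_cma3_events(
    truth: Cma3Truth,
    n: int,
    seed: int | SeedSequence | Generator | None = None,
    thresholds: Thresholds | None = None,
    sample_id: str = "sample",
) -> EventTable:
    if n < 1:
        raise ValueError("n must be >= 1")
    th = thresholds or Thresholds()
    rng = as_rng(seed)
    data, labels, n_clipped = _sample_mixture(
        rng, n, truth.components(), th.channel_max
    )
    rec: dict[str, Any] = truth.implied(th)
    rec["params"] = dataclasses.asdict(truth)
    return EventTable(
        sample_id=sample_id,
        assay="CMA3",
        data=data,
        channel_max=th.channel_max,
        n_clipped=n_clipped,
        truth=rec,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# 8-oxo-dG

@dataclass(frozen=True)
class OxoDgTruth(_TruthBase):
    """Anti-8-oxo-dG FITC signal: a basal-damage main population plus a
    high-damage tail; storage shifts the whole FITC scale up."""

    frac_high: float = 0.08
    debris: float = 0.05
    level: float = 1.0            # multiplies both FITC component medians
    main_fitc: float = 120.0
    main_sigma: float = 0.15
    high_fitc: float = 400.0
    high_sigma: float = 0.15
    h342_sperm: float = 600.0
    h342_sperm_sigma: float = 0.15
    h342_debris: float = 15.0
    debris_fitc: float = 20.0
    debris_sigma: float = 0.5

    EFFECTS = {
        "frac_high": Effect("logit", boar_sd=0.20, ejaculate_sd=0.08, day_shift=0.10),
        "level": Effect("log", boar_sd=0.06, ejaculate_sd=0.02,
                        day_shift=math.log(2.80 / 2.54)),
        "debris": Effect("logit", boar_sd=0.15, ejaculate_sd=0.05),
    }

    def __post_init__(self) -> None:
        for name in ("frac_high", "debris"):
            _check_fraction(name, getattr(self, name))

    def _sperm_weights(self) -> np.ndarray:
        return np.array([1.0 - self.frac_high, self.frac_high])

    def _sperm_comps(self) -> list[LogNormal]:
        return [
            LogNormal(self.main_fitc * self.level, self.main_sigma),
            LogNormal(self.high_fitc * self.level, self.high_sigma),
        ]

    def components(self) -> list[tuple[float, dict[str, LogNormal], str]]:
        sperm_w = (1.0 - self.debris) * self._sperm_weights()
        comps = []
        for w, ln, name in zip(sperm_w, self._sperm_comps(), ("main", "high")):
            comps.append(
                (
                    float(w),
                    {
                        "fitc": ln,
                        "h342": LogNormal(self.h342_sperm, self.h342_sperm_sigma),
                    },
                    name,
                )
            )
        comps.append(
            (
                self.debris,
                {
                    "fitc": LogNormal(self.debris_fitc, self.debris_sigma),
                    "h342": LogNormal(self.h342_debris, self.debris_sigma),
                },
                "debris",
            )
        )
        return comps

    def implied(self, th: Thresholds) -> dict[str, float]:
        w = self._sperm_weights()
        comps = self._sperm_comps()
        p_high = float(sum(wi * c.sf(th.oxodg_high_cut) for wi, c in zip(w, comps)))
        return {
            "pct_high": 100.0 * p_high,
            "mfi_norm": mixture_median(w, comps) / th.oxodg_reference,
            "debris": 100.0 * self.debris,
        }


def simulate_oxodg_events(
    truth: OxoDgTruth,
    n: int,
    seed: int | SeedSequence | Generator | None = None,
    thresholds: Thresholds | None = None,
    sample_id: str = "sample",
) -> EventTable:
    if n < 1:
        raise ValueError("n must be >= 1")
    th = thresholds or Thresholds()
    rng = as_rng(seed)
    data, labels, n_clipped = _sample_mixture(
        rng, n, truth.components(), th.channel_max
    )
    rec: dict[str, Any] = truth.implied(th)
    rec["params"] = dataclasses.asdict(truth)
    return EventTable(
        sample_id=sample_id,
        assay="OXODG",
        data=data,
        channel_max=th.channel_max,
        n_clipped=n_clipped,
        truth=rec,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# physiology panels

_POS = LogNormal(500.0, 0.2)
_NEG = LogNormal(40.0, 0.3)


def _marker(rng: Generator, positive: np.ndarray, channel_max: float):
    n = len(positive)
    vals = np.where(
        positive, _POS.sample(rng, n), _NEG.sample(rng, n)
    )
    clipped = int(np.sum(vals > channel_max))
    return np.clip(vals, 0.0, channel_max), clipped


@dataclass(frozen=True)
class Phys1Truth(_TruthBase):
    """Viability / apoptosis / capacitation / acrosome panel (H342 nuclear
    gate; PI marks dead cells, YO-PRO-1 early apoptosis, M540 capacitation,
    PNA acrosomal damage)."""

    viable: float = 0.88
    apoptotic_of_viable: float = 0.10
    capacitated_of_nonapoptotic: float = 0.15
    acrosome_of_nonapoptotic: float = 0.08
    acrosome_of_apoptotic: float = 0.45
    yp_of_dead: float = 0.85
    m540_of_apoptotic: float = 0.70
    debris: float = 0.05

    EFFECTS = {
        "viable": Effect("logit", boar_sd=0.20, ejaculate_sd=0.08, day_shift=-0.15),
        "apoptotic_of_viable": Effect("logit", boar_sd=0.20, ejaculate_sd=0.08,
                                      day_shift=0.10),
        "capacitated_of_nonapoptotic": Effect("logit", boar_sd=0.20,
                                              ejaculate_sd=0.08, day_shift=0.10),
        "acrosome_of_nonapoptotic": Effect("logit", boar_sd=0.20,
                                           ejaculate_sd=0.08, day_shift=0.10),
        "debris": Effect("logit", boar_sd=0.15, ejaculate_sd=0.05),
    }

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            _check_fraction(f.name, getattr(self, f.name))

    def p_yp_positive(self) -> float:
        return (
            self.viable * self.apoptotic_of_viable
            + (1.0 - self.viable) * self.yp_of_dead
        )

    def implied(self, th: Thresholds) -> dict[str, float]:
        p_yp = self.p_yp_positive()
        acro_total = (
            (1.0 - p_yp) * self.acrosome_of_nonapoptotic
            + p_yp * self.acrosome_of_apoptotic
        )
        return {
            "pct_viable": 100.0 * self.viable,
            "pct_apoptotic_of_viable": 100.0 * self.apoptotic_of_viable,
            "pct_capacitated_of_nonapoptotic":
                100.0 * self.capacitated_of_nonapoptotic,
            "pct_acrosome_damaged_of_nonapoptotic":
                100.0 * self.acrosome_of_nonapoptotic,
            "pct_acrosome_damaged_total": 100.0 * acro_total,
            "debris": 100.0 * self.debris,
        }


def simulate_phys1_events(
    truth: Phys1Truth,
    n: int,
    seed: int | SeedSequence | Generator | None = None,
    thresholds: Thresholds | None = None,
    sample_id: str = "sample",
) -> EventTable:
    if n < 1:
        raise ValueError("n must be >= 1")
    th = thresholds or Thresholds()
    rng = as_rng(seed)
    debris = rng.random(n) < truth.debris
    viable = rng.random(n) < truth.viable
    yp = np.where(
        viable,
        rng.random(n) < truth.apoptotic_of_viable,
        rng.random(n) < truth.yp_of_dead,
    )
    m540 = np.where(
        ~yp,
        rng.random(n) < truth.capacitated_of_nonapoptotic,
        rng.random(n) < truth.m540_of_apoptotic,
    )
    pna = np.where(
        ~yp,
        rng.random(n) < truth.acrosome_of_nonapoptotic,
        rng.random(n) < truth.acrosome_of_apoptotic,
    )
    n_clipped = 0
    data = {}
    h342, c = _marker(rng, ~debris, th.channel_max)
    n_clipped += c
    data["h342"] = np.where(debris, LogNormal(15.0, 0.5).sample(rng, n), h342)
    for name, positive in (
        ("pi", ~viable), ("yp", yp), ("m540", m540), ("pna", pna)
    ):
        vals, c = _marker(rng, positive & ~debris, th.channel_max)
        n_clipped += c
        data[name] = np.where(
            debris, LogNormal(20.0, 0.5).sample(rng, n), vals
        )
    data = {k: np.clip(v, 0.0, th.channel_max) for k, v in data.items()}
    labels = np.where(
        debris, "debris",
        np.where(~viable, "dead", np.where(yp, "apoptotic", "viable")),
    )
    rec: dict[str, Any] = truth.implied(th)
    rec["params"] = dataclasses.asdict(truth)
    return EventTable(
        sample_id=sample_id,
        assay="PHYS1",
        data=pd.DataFrame(data),
        channel_max=th.channel_max,
        n_clipped=n_clipped,
        truth=rec,
        labels=labels,
    )


@dataclass(frozen=True)
class Phys2Truth(_TruthBase):
    """Viability / ROS / mitochondria panel (scatter gate; H258 marks dead
    cells, CM-H2DCFDA cytoplasmic ROS, MitoSOX mitochondrial superoxide,
    MitoTracker deep red mitochondrial activity)."""

    viable: float = 0.88
    superoxide_of_viable: float = 0.06
    mito_of_viable: float = 0.93
    mito_of_dead: float = 0.08
    mx_of_dead: float = 0.50
    ros_mfi: float = 120.0
    ros_sigma: float = 0.30
    debris: float = 0.05

    EFFECTS = {
        "viable": Effect("logit", boar_sd=0.20, ejaculate_sd=0.08, day_shift=-0.15),
        "superoxide_of_viable": Effect("logit", boar_sd=0.20, ejaculate_sd=0.08,
                                       day_shift=0.35),
        "mito_of_viable": Effect("logit", boar_sd=0.20, ejaculate_sd=0.08,
                                 day_shift=-0.10),
        "ros_mfi": Effect("log", boar_sd=0.06, ejaculate_sd=0.02,
                          day_shift=math.log(1.3)),
        "debris": Effect("logit", boar_sd=0.15, ejaculate_sd=0.05),
    }

    def __post_init__(self) -> None:
        for name in (
            "viable", "superoxide_of_viable", "mito_of_viable",
            "mito_of_dead", "mx_of_dead", "debris",
        ):
            _check_fraction(name, getattr(self, name))
        if self.ros_mfi <= 0:
            raise ValueError("ros_mfi must be positive")

    def implied(self, th: Thresholds) -> dict[str, float]:
        mito_total = (
            self.viable * self.mito_of_viable
            + (1.0 - self.viable) * self.mito_of_dead
        )
        return {
            "pct_viable": 100.0 * self.viable,
            "pct_high_superoxide_of_viable": 100.0 * self.superoxide_of_viable,
            "pct_active_mitochondria": 100.0 * mito_total,
            "cytoplasmic_ros_mfi": self.ros_mfi / th.ros_reference,
            "debris": 100.0 * self.debris,
        }


def simulate_phys2_events(
    truth: Phys2Truth,
    n: int,
    seed: int | SeedSequence | Generator | None = None,
    thresholds: Thresholds | None = None,
    sample_id: str = "sample",
) -> EventTable:
    if n < 1:
        raise ValueError("n must be >= 1")
    th = thresholds or Thresholds()
    rng = as_rng(seed)
    debris = rng.random(n) < truth.debris
    viable = rng.random(n) < truth.viable
    mx = np.where(
        viable,
        rng.random(n) < truth.superoxide_of_viable,
        rng.random(n) < truth.mx_of_dead,
    )
    mtdr = np.where(
        viable,
        rng.random(n) < truth.mito_of_viable,
        rng.random(n) < truth.mito_of_dead,
    )
    n_clipped = 0
    data = {}
    ssc_cell = LogNormal(400.0, 0.2).sample(rng, n)
    data["ssc"] = np.where(debris, LogNormal(40.0, 0.5).sample(rng, n), ssc_cell)
    # H258 is positive on *dead* cells; viable sperm are H258-negative
    h258, c = _marker(rng, ~viable & ~debris, th.channel_max)
    n_clipped += c
    data["h258"] = np.where(debris, LogNormal(20.0, 0.5).sample(rng, n), h258)
    ros_viable = LogNormal(truth.ros_mfi, truth.ros_sigma).sample(rng, n)
    ros_dead = LogNormal(60.0, 0.4).sample(rng, n)
    data["cfda"] = np.where(
        debris, LogNormal(20.0, 0.5).sample(rng, n),
        np.where(viable, ros_viable, ros_dead),
    )
    for name, positive in (("mx", mx), ("mtdr", mtdr)):
        vals, c = _marker(rng, positive & ~debris, th.channel_max)
        n_clipped += c
        data[name] = np.where(debris, LogNormal(20.0, 0.5).sample(rng, n), vals)
    data = {k: np.clip(v, 0.0, th.channel_max) for k, v in data.items()}
    labels = np.where(debris, "debris", np.where(viable, "viable", "dead"))
    rec: dict[str, Any] = truth.implied(th)
    rec["params"] = dataclasses.asdict(truth)
    return EventTable(
        sample_id=sample_id,
        assay="PHYS2",
        data=pd.DataFrame(data),
        channel_max=th.channel_max,
        n_clipped=n_clipped,
        truth=rec,
        labels=labels,
    )


# ---------------------------------------------------------------------------
# CASA kinematics

@dataclass(frozen=True)
class KinematicComponent:
    """One swimming pattern: VCL is log-normal around ``vcl``; STR = VSL/VAP
    and WOB = VAP/VCL are logit-normal around ``str_frac``/``wob_frac`` so
    VSL <= VAP <= VCL holds for every sampled cell by construction."""

    vcl: float
    str_frac: float
    wob_frac: float
    alh: float
    bcf: float
    vcl_sigma: float = 0.35
    ratio_sigma: float = 0.5
    alh_sigma: float = 0.3
    bcf_sigma: float = 0.4

    def __post_init__(self) -> None:
        if self.vcl <= 0 or self.alh <= 0 or self.bcf <= 0:
            raise ValueError("vcl, alh, bcf must be positive")
        if not (0 < self.str_frac <= 1 and 0 < self.wob_frac <= 1):
            raise ValueError("str_frac and wob_frac must be in (0, 1]")

    @classmethod
    def from_velocities(
        cls, vcl: float, vsl: float, vap: float, alh: float, bcf: float,
        **kwargs: float,
    ) -> "KinematicComponent":
        if not (0 < vsl <= vap <= vcl):
            raise ValueError("component means must satisfy VSL <= VAP <= VCL")
        return cls(
            vcl=vcl, str_frac=vsl / vap, wob_frac=vap / vcl,
            alh=alh, bcf=bcf, **kwargs,
        )

    def sample(self, rng: Generator, n: int) -> pd.DataFrame:
        vcl = LogNormal(self.vcl, self.vcl_sigma).sample(rng, n)
        if self.ratio_sigma == 0:
            str_f = np.full(n, self.str_frac)
            wob_f = np.full(n, self.wob_frac)
        else:
            str_f = expit(
                logit(min(self.str_frac, 1 - 1e-12))
                + self.ratio_sigma * rng.standard_normal(n)
            )
            wob_f = expit(
                logit(min(self.wob_frac, 1 - 1e-12))
                + self.ratio_sigma * rng.standard_normal(n)
            )
        vap = wob_f * vcl
        vsl = str_f * vap
        alh = LogNormal(self.alh, self.alh_sigma).sample(rng, n)
        bcf = LogNormal(self.bcf, self.bcf_sigma).sample(rng, n)
        return kinematics_frame(vcl, vsl, vap, alh, bcf)


def default_casa_components() -> tuple[tuple[KinematicComponent, ...], tuple[float, ...]]:
    """Slow / Fast / Hyperactivated swimming patterns typical of boar sperm
    (medians close to published CASA subpopulation tables)."""
    slow = KinematicComponent.from_velocities(50.0, 14.4, 27.4, alh=1.4, bcf=9.0)
    fast = KinematicComponent.from_velocities(117.3, 34.5, 67.8, alh=2.6, bcf=20.0)
    hyper = KinematicComponent.from_velocities(113.5, 9.1, 51.7, alh=2.9, bcf=13.0)
    return (slow, fast, hyper), (0.30, 0.52, 0.18)


_IMMOTILE = KinematicComponent(
    vcl=4.0, str_frac=0.4, wob_frac=0.6, alh=0.4, bcf=3.0,
    vcl_sigma=0.5, ratio_sigma=0.8, alh_sigma=0.4, bcf_sigma=0.5,
)


@dataclass(frozen=True)
class CasaTruth:
    """Mixture of motile swimming patterns plus an immotile fraction."""

    components: tuple[KinematicComponent, ...] = ()
    weights: tuple[float, ...] = ()
    immotile: float = 0.20
    slow_day_shift: float = 0.40      # logit shift of the first (slow) weight
    immotile_day_shift: float = 0.50
    boar_sd: float = 0.15
    ejaculate_sd: float = 0.08

    def __post_init__(self) -> None:
        comps, weights = self.components, self.weights
        if not comps:
            comps, weights = default_casa_components()
            object.__setattr__(self, "components", comps)
            object.__setattr__(self, "weights", weights)
        if len(self.components) != len(self.weights):
            raise ValueError("one weight per component required")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("component weights must be nonnegative and sum to 1")
        _check_fraction("immotile", self.immotile)

    @classmethod
    def effect_names(cls) -> list[str]:
        return ["slow_weight", "immotile"]

    def realize(
        self, zb: Mapping[str, float], ze: Mapping[str, float], day_on: bool
    ) -> "CasaTruth":
        eff_w = Effect("logit", self.boar_sd, self.ejaculate_sd, self.slow_day_shift)
        eff_i = Effect("logit", self.boar_sd, self.ejaculate_sd, self.immotile_day_shift)
        w = np.asarray(self.weights, dtype=float)
        new_slow = eff_w.apply(
            float(w[0]), zb.get("slow_weight", 0.0), ze.get("slow_weight", 0.0), day_on
        )
        rest = w[1:] * (1.0 - new_slow) / w[1:].sum() if len(w) > 1 else w[1:]
        new_immotile = eff_i.apply(
            self.immotile, zb.get("immotile", 0.0), ze.get("immotile", 0.0), day_on
        )
        return dataclasses.replace(
            self,
            weights=tuple([new_slow, *rest.tolist()]),
            immotile=new_immotile,
        )

    def implied(self) -> dict[str, float]:
        return {
            "weights": list(self.weights),
            "immotile": 100.0 * self.immotile,
            "pct_motile": 100.0 * (1.0 - self.immotile),
        }


def simulate_casa_sample(
    truth: CasaTruth,
    n: int,
    seed: int | SeedSequence | Generator | None = None,
    sample_id: str = "sample",
) -> KinematicTable:
    """Simulate one CASA acquisition of ``n`` tracked cells."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = as_rng(seed)
    weights = np.array([*(w * (1 - truth.immotile) for w in truth.weights),
                        truth.immotile])
    comps = [*truth.components, _IMMOTILE]
    idx = rng.choice(len(comps), size=n, p=weights / weights.sum())
    frames = []
    for i, comp in enumerate(comps):
        k = int(np.sum(idx == i))
        if k == 0:
            continue
        frames.append((np.where(idx == i)[0], comp.sample(rng, k)))
    data = pd.DataFrame(np.empty((n, 10)), columns=list(KINEMATIC_COLUMNS))
    for rows, frame in frames:
        data.iloc[rows] = frame.to_numpy()
    labels = np.where(idx == len(comps) - 1, -1, idx)
    rec: dict[str, Any] = truth.implied()
    return KinematicTable(
        sample_id=sample_id, data=data, truth=rec, labels=labels
    )


# ---------------------------------------------------------------------------
# study orchestration

ASSAYS = ("SCSA", "MBBR", "CMA3", "OXODG", "PHYS1", "PHYS2", "CASA")


def default_truths() -> dict[str, Any]:
    """One truth object per assay, at the study-condition defaults."""
    return {
        "SCSA": ScsaTruth(),
        "MBBR": MbbrTruth(),
        "CMA3": Cma3Truth(),
        "OXODG": OxoDgTruth(),
        "PHYS1": Phys1Truth(),
        "PHYS2": Phys2Truth(),
        "CASA": CasaTruth(),
    }


@dataclass
class SampleData:
    """All simulated material for one dose x day."""

    sample_id: str
    boar: str
    ejaculate: str
    day: str
    events: dict[str, EventTable]
    kinematics: KinematicTable | None
    truth: dict[str, float]


@dataclass
class StudyBundle:
    """Materialised synthetic study."""

    design: StudyDesign
    design_table: pd.DataFrame
    events: dict[tuple[str, str], EventTable]
    kinematics: dict[str, KinematicTable]
    truth_table: pd.DataFrame


def _draw_effects(
    rng: Generator, truths: Mapping[str, Any]
) -> Callable[[str], dict[str, float]]:
    z: dict[str, float] = {}
    for assay in sorted(truths):
        for name in truths[assay].effect_names():
            z[f"{assay}.{name}"] = float(rng.standard_normal())

    def for_assay(assay: str) -> dict[str, float]:
        prefix = f"{assay}."
        return {k[len(prefix):]: v for k, v in z.items() if k.startswith(prefix)}

    return for_assay


def iter_study(
    design: StudyDesign,
    truths: Mapping[str, Any] | None = None,
    thresholds: Thresholds | None = None,
) -> Iterator[SampleData]:
    """Yield one :class:`SampleData` per dose x day, deterministically.

    Event streams are seeded with ``SeedSequence(design.seed,
    spawn_key=(boar, ejaculate, day, assay))`` so repeated calls (and
    different consumption orders) give bit-identical samples.
    """
    truths = dict(truths) if truths is not None else default_truths()
    unknown = set(truths) - set(ASSAYS)
    if unknown:
        raise ValueError(f"unknown assay truths: {sorted(unknown)}")
    if design.n_samples == 0:
        raise ValueError("design has zero samples")
    th = thresholds or Thresholds()

    boar_effects = {}
    ejac_effects = {}
    for b in range(design.boars):
        rng_b = default_rng(SeedSequence(design.seed, spawn_key=(0, b)))
        boar_effects[b] = _draw_effects(rng_b, truths)
        for e in range(design.ejaculates_per_boar):
            rng_e = default_rng(SeedSequence(design.seed, spawn_key=(1, b, e)))
            ejac_effects[(b, e)] = _draw_effects(rng_e, truths)

    simulators = {
        "SCSA": simulate_scsa_events,
        "CMA3": simulate_cma3_events,
        "OXODG": simulate_oxodg_events,
        "PHYS1": simulate_phys1_events,
        "PHYS2": simulate_phys2_events,
    }

    for b in range(design.boars):
        for e in range(design.ejaculates_per_boar):
            for d, day in enumerate(design.days):
                sid = f"B{b + 1:02d}_E{e + 1}_{day}"
                day_on = d > 0
                kin: KinematicTable | None = None
                events: dict[str, EventTable] = {}
                truth_row: dict[str, Any] = {
                    "sample_id": sid,
                    "boar": f"B{b + 1:02d}",
                    "ejaculate": f"E{e + 1}",
                    "day": day,
                }
                for a, assay in enumerate(ASSAYS):
                    if assay not in truths:
                        continue
                    realized = truths[assay].realize(
                        boar_effects[b](assay),
                        ejac_effects[(b, e)](assay),
                        day_on,
                    )
                    seed = SeedSequence(design.seed, spawn_key=(2, b, e, d, a))
                    if assay == "CASA":
                        kin = simulate_casa_sample(
                            realized, design.casa_cells_per_sample, seed,
                            sample_id=sid,
                        )
                        for k, v in kin.truth.items():
                            if np.isscalar(v):
                                truth_row[f"casa_{k}"] = v
                        continue
                    if assay == "MBBR":
                        untr, dtt = simulate_stain_pair_mbbr(
                            realized, design.events_per_sample, seed,
                            thresholds=th, sample_id=sid,
                        )
                        events["MBBR"] = untr
                        events["MBBR_DTT"] = dtt
                        rec = untr.truth
                    else:
                        table = simulators[assay](
                            realized, design.events_per_sample, seed,
                            thresholds=th, sample_id=sid,
                        )
                        events[assay] = table
                        rec = table.truth
                    for k, v in rec.items():
                        if np.isscalar(v):
                            truth_row[f"{assay.lower()}_{k}"] = v
                yield SampleData(
                    sample_id=sid,
                    boar=f"B{b + 1:02d}",
                    ejaculate=f"E{e + 1}",
                    day=day,
                    events=events,
                    kinematics=kin,
                    truth=truth_row,
                )


def generate_study(
    design: StudyDesign,
    truths: Mapping[str, Any] | None = None,
    thresholds: Thresholds | None = None,
) -> StudyBundle:
    """Materialise the full synthetic study (see :func:`iter_study`)."""
    events: dict[tuple[str, str], EventTable] = {}
    kinematics: dict[str, KinematicTable] = {}
    truth_rows = []
    for sample in iter_study(design, truths, thresholds):
        for assay, table in sample.events.items():
            events[(sample.sample_id, assay)] = table
        kinematics[sample.sample_id] = sample.kinematics
        truth_rows.append(sample.truth)
    return StudyBundle(
        design=design,
        design_table=design.sample_frame(),
        events=events,
        kinematics=kinematics,
        truth_table=pd.DataFrame(truth_rows),
    )
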