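"""Per-sample chromatin and physiology statistics from gated event tables.

Statistics follow standard single-cell chromatin assay practice:

* SCSA — per-cell DNA fragmentation index ``DFI = 1000 * red/(red+green)``;
  %DFI is the fraction of cells with DFI strictly above 250, SD-DFI the
  sample standard deviation of DFI, and %HDS the fraction with green
  fluorescence above a fixed channel cut (0.65 x full scale by default).
* mBBr — median fluorescence (optionally normalised to a daily standard
  sample), low/moderate/high fractions, and the disulfide-bridge index
  ``(median_DTT - median_untreated) / 2`` from the paired reduced split.
* CMA3 / 8-oxo-dG — median fluorescence plus gate fractions.
* Physiology panels — conditional positive fractions within their stated
  denominators (e.g. early-apoptotic among viable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Thresholds
from .tables import EventTable

__all__ = [
    "Gate",
    "GatingReport",
    "EmptyGateError",
    "ScsaResult",
    "MbbrResult",
    "Cma3Result",
    "OxoDgResult",
    "PhysiologyResult",
    "gate_events",
    "default_gate",
    "scsa_statistics",
    "median_fluorescence",
    "gate_fractions",
    "mbbr_statistics",
    "cma3_statistics",
    "oxodg_statistics",
    "physiology_statistics",
    "reference_bounds",
]


class EmptyGateError(ValueError):
    """All events fell in the debris region."""


@dataclass(frozen=True)
class Gate:
    """Debris-exclusion rule: keep an event if *any* listed channel exceeds
    ``cut``.  With one channel this is a simple nuclear-stain (or scatter)
    positivity gate; with the two acridine-orange channels it implements the
    AO double-negative debris rule."""

    channels: tuple[str, ...]
    cut: float

    def mask(self, events: EventTable) -> np.ndarray:
        missing = [c for c in self.channels if c not in events.data.columns]
        if missing:
            raise ValueError(f"unknown gate channel(s): {missing}")
        return (
            events.data.loc[:, list(self.channels)].to_numpy() > self.cut
        ).any(axis=1)


def default_gate(assay: str, thresholds: Thresholds | None = None) -> Gate:
    """The study's debris-exclusion rule for each assay."""
    th = thresholds or Thresholds()
    rules: dict[str, Gate] = {
        "SCSA": Gate(("green", "red"), th.nuclear_cut),
        "MBBR": Gate(("pi",), th.nuclear_cut),
        "MBBR_DTT": Gate(("pi",), th.nuclear_cut),
        "CMA3": Gate(("h342",), th.nuclear_cut),
        "OXODG": Gate(("h342",), th.nuclear_cut),
        "PHYS1": Gate(("h342",), th.nuclear_cut),
        "PHYS2": Gate(("ssc",), th.scatter_cut),
    }
    try:
        return rules[assay]
    except KeyError:
        raise ValueError(f"no default gate for assay {assay!r}") from None


@dataclass
class GatingReport:
    n_total: int
    n_debris: int
    n_sperm: int
    thresholds: dict[str, float]
    warnings: list[str] = field(default_factory=list)


def gate_events(
    events: EventTable,
    gate: Gate,
    min_events: int = 5000,
) -> tuple[EventTable, GatingReport]:
    """Exclude debris; every input event is accounted for in the report.

    A gated count below ``min_events`` is flagged (and warned about), never
    silently dropped.  Raises :class:`EmptyGateError` when nothing survives.
    """
    keep = gate.mask(events)
    n_total = len(keep)
    n_sperm = int(keep.sum())
    if n_sperm == 0:
        raise EmptyGateError(
            f"empty gate: all {n_total} events below threshold for "
            f"{events.sample_id}/{events.assay}"
        )
    report = GatingReport(
        n_total=n_total,
        n_debris=n_total - n_sperm,
        n_sperm=n_sperm,
        thresholds={ch: gate.cut for ch in gate.channels},
    )
    if n_sperm < min_events:
        msg = (
            f"{events.sample_id}/{events.assay}: only {n_sperm} gated events "
            f"(< {min_events})"
        )
        report.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    return events.subset(keep), report


# ---------------------------------------------------------------------------
# SCSA

@dataclass(frozen=True)
class ScsaResult:
    sd_dfi: float
    pct_dfi: float
    pct_hds: float
    n_events: int


def per_cell_dfi(
    events: EventTable, green: str = "green", red: str = "red"
) -> np.ndarray:
    """DFI = 1000 * red / (red + green) per cell, in [0, 1000]."""
    g = events.data[green].to_numpy(dtype=float)
    r = events.data[red].to_numpy(dtype=float)
    total = g + r
    if np.any(total == 0):
        raise ValueError(
            "event with zero total AO fluorescence; such events are debris "
            "and must be gated out first"
        )
    return 1000.0 * r / total


def scsa_statistics(
    events: EventTable,
    hds_threshold: float,
    dfi_cut: float = 250.0,
    green: str = "green",
    red: str = "red",
) -> ScsaResult:
    """SCSA summary of a gated acquisition.

    %DFI counts cells with DFI strictly above ``dfi_cut``; %HDS counts
    cells with green fluorescence strictly above ``hds_threshold`` (a fixed
    position on the channel scale).  SD-DFI is the (n-1) standard deviation
    of the per-cell DFI.
    """
    dfi = per_cell_dfi(events, green=green, red=red)
    n = len(dfi)
    g = events.data[green].to_numpy(dtype=float)
    return ScsaResult(
        sd_dfi=float(np.std(dfi, ddof=1)) if n > 1 else 0.0,
        pct_dfi=100.0 * float(np.mean(dfi > dfi_cut)),
        pct_hds=100.0 * float(np.mean(g > hds_threshold)),
        n_events=n,
    )


# ---------------------------------------------------------------------------
# shared fluorescence summaries

def median_fluorescence(
    events: EventTable, channel: str, reference_mfi: float = 1.0
) -> float:
    """Sample median of ``channel`` divided by the daily-standard median."""
    if reference_mfi <= 0:
        raise ValueError("reference_mfi must be positive")
    if channel not in events.data.columns:
        raise ValueError(f"unknown channel {channel!r}")
    if len(events.data) == 0:
        raise ValueError("empty event table")
    return float(np.median(events.data[channel].to_numpy(dtype=float))) / reference_mfi


def gate_fractions(
    events: EventTable, channel: str, bounds: tuple[float, float]
) -> tuple[float, float, float]:
    """(low, moderate, high) percentages from fixed channel bounds.

    low: value <= low_cut; high: value > high_cut; moderate: the rest.  The
    three always sum to 100.
    """
    low_cut, high_cut = bounds
    if not low_cut < high_cut:
        raise ValueError("bounds must satisfy low_cut < high_cut")
    x = events.data[channel].to_numpy(dtype=float)
    n = len(x)
    low = 100.0 * float(np.sum(x <= low_cut)) / n
    high = 100.0 * float(np.sum(x > high_cut)) / n
    return low, 100.0 - low - high, high


def reference_bounds(
    reference_values: np.ndarray, lo: float = 5.0, hi: float = 95.0
) -> tuple[float, float]:
    """Low/high gate bounds from a pooled reference distribution
    (percentiles of the day-0 pooled signal), to be frozen in config."""
    values = np.asarray(reference_values, dtype=float)
    return (
        float(np.percentile(values, lo)),
        float(np.percentile(values, hi)),
    )


# ---------------------------------------------------------------------------
# mBBr

@dataclass(frozen=True)
class MbbrResult:
    mfi_norm: float
    pct_low: float
    pct_moderate: float
    pct_high: float
    disulfide_index: float
    n_events: int
    flags: tuple[str, ...] = ()


def mbbr_statistics(
    untreated: EventTable,
    dtt: EventTable,
    reference_mfi: float = 1.0,
    bounds: tuple[float, float] = (110.0, 360.0),
    channel: str = "mbbr",
) -> MbbrResult:
    """Thiol/disulfide summary from the gated untreated/DTT split pair.

    The disulfide-bridge index is half the excess of the DTT-reduced median
    over the untreated one, on the reference-normalised scale; a negative
    index (reduced split dimmer than untreated) is returned but flagged.
    """
    if untreated.sample_id != dtt.sample_id:
        raise ValueError(
            f"mismatched sample ids: {untreated.sample_id!r} vs {dtt.sample_id!r}"
        )
    mfi_untr = median_fluorescence(untreated, channel, reference_mfi)
    mfi_dtt = median_fluorescence(dtt, channel, reference_mfi)
    low, mod, high = gate_fractions(untreated, channel, bounds)
    index = (mfi_dtt - mfi_untr) / 2.0
    flags = ("negative_disulfide_index",) if index < 0 else ()
    return MbbrResult(
        mfi_norm=mfi_untr,
        pct_low=low,
        pct_moderate=mod,
        pct_high=high,
        disulfide_index=index,
        n_events=untreated.n_events,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# CMA3 / 8-oxo-dG

@dataclass(frozen=True)
class Cma3Result:
    mfi_norm: float
    pct_low: float
    pct_moderate: float
    pct_high: float
    n_events: int


def cma3_statistics(
    events: EventTable,
    reference_mfi: float = 1.0,
    bounds: tuple[float, float] = (110.0, 360.0),
    channel: str = "cma3",
) -> Cma3Result:
    low, mod, high = gate_fractions(events, channel, bounds)
    return Cma3Result(
        mfi_norm=median_fluorescence(events, channel, reference_mfi),
        pct_low=low,
        pct_moderate=mod,
        pct_high=high,
        n_events=events.n_events,
    )


@dataclass(frozen=True)
class OxoDgResult:
    mfi_norm: float
    pct_high: float
    n_events: int


def oxodg_statistics(
    events: EventTable,
    reference_mfi: float = 1.0,
    high_cut: float = 220.0,
    channel: str = "fitc",
) -> OxoDgResult:
    x = events.data[channel].to_numpy(dtype=float)
    return OxoDgResult(
        mfi_norm=median_fluorescence(events, channel, reference_mfi),
        pct_high=100.0 * float(np.mean(x > high_cut)),
        n_events=events.n_events,
    )


# ---------------------------------------------------------------------------
# physiology panels

@dataclass(frozen=True)
class PhysiologyResult:
    pct_viable: float
    pct_apoptotic_of_viable: float
    pct_acrosome_damaged_total: float
    pct_acrosome_damaged_of_nonapoptotic: float
    pct_capacitated_of_nonapoptotic: float
    pct_active_mitochondria: float
    pct_high_superoxide_of_viable: float
    cytoplasmic_ros_mfi: float
    flags: tuple[str, ...] = ()


def _conditional_pct(
    numerator: np.ndarray, denominator: np.ndarray, name: str, flags: list[str]
) -> float:
    n_den = int(denominator.sum())
    if n_den == 0:
        flags.append(f"empty_denominator:{name}")
        return float("nan")
    return 100.0 * float(numerator[denominator].mean())


def physiology_statistics(
    panel1: EventTable,
    panel2: EventTable,
    thresholds: Thresholds | None = None,
    ros_reference: float | None = None,
) -> PhysiologyResult:
    """Physiology summary from the two gated panels.

    Panel 1 (H342/PI/YP/M540/PNA): viability, early apoptosis among viable,
    capacitation and acrosomal damage among non-apoptotic, total acrosomal
    damage.  Panel 2 (SSC/H258/CFDA/MX/MTdr): mitochondrial activity,
    superoxide among viable (H258-negative), and cytoplasmic ROS as the CFDA
    median of viable cells.  Empty denominator subpopulations yield NaN with
    a flag, never a failure.
    """
    th = thresholds or Thresholds()
    cut = th.positivity_cut
    flags: list[str] = []

    d1 = panel1.data
    viable1 = d1["pi"].to_numpy(dtype=float) <= cut
    yp = d1["yp"].to_numpy(dtype=float) > cut
    m540 = d1["m540"].to_numpy(dtype=float) > cut
    pna = d1["pna"].to_numpy(dtype=float) > cut

    pct_viable = 100.0 * float(viable1.mean())
    pct_apo = _conditional_pct(yp, viable1, "apoptotic_of_viable", flags)
    pct_cap = _conditional_pct(m540, ~yp, "capacitated_of_nonapoptotic", flags)
    pct_acro_nonapo = _conditional_pct(
        pna, ~yp, "acrosome_damaged_of_nonapoptotic", flags
    )
    pct_acro_total = 100.0 * float(pna.mean())

    d2 = panel2.data
    viable2 = d2["h258"].to_numpy(dtype=float) <= cut
    mx = d2["mx"].to_numpy(dtype=float) > cut
    mtdr = d2["mtdr"].to_numpy(dtype=float) > cut
    pct_mito = 100.0 * float(mtdr.mean())
    pct_superox = _conditional_pct(mx, viable2, "high_superoxide_of_viable", flags)
    ref = ros_reference if ros_reference is not None else th.ros_reference
    if viable2.sum() == 0:
        flags.append("empty_denominator:cytoplasmic_ros")
        ros = float("nan")
    else:
        ros = float(np.median(d2["cfda"].to_numpy(dtype=float)[viable2])) / ref

    return PhysiologyResult(
        pct_viable=pct_viable,
        pct_apoptotic_of_viable=pct_apo,
        pct_acrosome_damaged_total=pct_acro_total,
        pct_acrosome_damaged_of_nonapoptotic=pct_acro_nonapo,
        pct_capacitated_of_nonapoptotic=pct_cap,
        pct_active_mitochondria=pct_mito,
        pct_high_superoxide_of_viable=pct_superox,
        cytoplasmic_ros_mfi=ros,
        flags=tuple(flags),
    )
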