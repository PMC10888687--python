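"""Analysis configuration: gate thresholds, references, clustering knobs.

All tunable cut-offs of the cytometry and motility layers live in one place
so that the synthetic-data generator and the estimators agree on the rules of
the game, and so a real-data run can override any of them from a YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: Full-scale channel value of the (10-bit display) cytometer scale.
CHANNEL_MAX = 1023.0


@dataclass(frozen=True)
class Thresholds:
    """Gating and statistic cut-offs, in channel units unless noted.

    Attributes
    ----------
    channel_max:
        Full-scale channel value; fluorescence above it piles up at the scale
        edge.
    nuclear_cut:
        Positivity cut for nuclear stains (Hoechst, PI) and for the acridine
        orange double-negative debris rule: events at or below this value on
        the relevant stain channel(s) are debris.
    scatter_cut:
        Side-scatter cut separating cells from debris in the second
        physiology panel.
    positivity_cut:
        Generic marker positivity cut for the physiology panels (YO-PRO-1,
        M540, PNA, MitoSOX, MitoTracker).
    hds_fraction:
        Position of the high-DNA-stainability cut as a fraction of
        ``channel_max`` on the green (dsDNA) channel.
    dfi_cut:
        Per-cell DNA fragmentation index threshold; cells strictly above it
        count toward %DFI.
    mbbr_bounds / cma3_bounds:
        (low_cut, high_cut) for the low/moderate/high fluorescence fractions.
    oxodg_high_cut:
        FITC cut above which a cell counts as carrying high oxidative DNA
        damage.
    *_reference:
        Daily standard-sample median used to normalise MFIs; 1.0 keeps raw
        channel medians.
    motile_vcl_cut:
        VCL (um/s) at or above which a cell counts as motile.
    min_events:
        Gated-event count below which a sample is flagged (never dropped).
    """

    channel_max: float = CHANNEL_MAX
    nuclear_cut: float = 100.0
    scatter_cut: float = 150.0
    positivity_cut: float = 150.0
    hds_fraction: float = 0.65
    dfi_cut: float = 250.0
    mbbr_bounds: tuple[float, float] = (110.0, 360.0)
    cma3_bounds: tuple[float, float] = (110.0, 360.0)
    oxodg_high_cut: float = 220.0
    mbbr_reference: float = 1.0
    cma3_reference: float = 1.0
    oxodg_reference: float = 1.0
    ros_reference: float = 1.0
    motile_vcl_cut: float = 10.0
    min_events: int = 5000

    @property
    def hds_cut(self) -> float:
        return self.hds_fraction * self.channel_max

    def replace(self, **kwargs: Any) -> "Thresholds":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class ClusteringConfig:
    """Knobs of the two-stage motility subpopulation clustering."""

    stage1_k: int = 40
    k_min: int = 2
    k_max: int = 6
    features: tuple[str, ...] = (
        "vcl", "vsl", "vap", "lin", "str", "wob", "alh", "bcf",
    )


@dataclass(frozen=True)
class MultivariateConfig:
    """Knobs of the statistical layer."""

    fdr_alpha: float = 0.05
    n_pcs_for_observation_clustering: int = 2
    observation_clusters: int = 2
    variable_linkage: str = "average"


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    ``mode`` is either ``"synthetic"`` (events are generated from the study
    design below) or ``"files"`` (events are read from ``input_dir``, one CSV
    per sample x assay, plus a design table).
    """

    mode: str = "synthetic"
    input_dir: str | None = None
    output_dir: str = "spermflow_out"
    seed: int = 0
    boars: int = 36
    ejaculates_per_boar: int = 3
    days: tuple[str, ...] = ("D0", "D11")
    events_per_sample: int = 5000
    casa_cells_per_sample: int = 1000
    thresholds: Thresholds = field(default_factory=Thresholds)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    multivariate: MultivariateConfig = field(default_factory=MultivariateConfig)
    channel_map: dict[str, dict[str, str]] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["days"] = list(self.days)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            t = dict(d["thresholds"])
            for key in ("mbbr_bounds", "cma3_bounds"):
                if key in t and t[key] is not None:
                    t[key] = tuple(t[key])
            d["thresholds"] = Thresholds(**t)
        if "clustering" in d and isinstance(d["clustering"], dict):
            c = dict(d["clustering"])
            if "features" in c:
                c["features"] = tuple(c["features"])
            d["clustering"] = ClusteringConfig(**c)
        if "multivariate" in d and isinstance(d["multivariate"], dict):
            d["multivariate"] = MultivariateConfig(**d["multivariate"])
        if "days" in d:
            d["days"] = tuple(d["days"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
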