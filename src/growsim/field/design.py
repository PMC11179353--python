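"""Factorial design of the crop-mixture field experiment.

A design crosses faba-bean (FB) cultivars and spring-wheat (SW) entries
into 1:1 mixtures plus the monocultures of each, at every sowing
density, so the number of treatments is ``(f*s + f + s) * d``.  Each
treatment is replicated into plots; FB monocultures carry their own
(typically doubled) replicate count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

DENSITY_LEVELS = ("low", "high")


class InvalidDesignError(ValueError):
    pass


@dataclass(frozen=True)
class DesignSpec:
    """Counts defining the mixture factorial.

    Defaults are the field experiment this testbed emulates: 2 FB
    cultivars x 12 SW entries x 2 densities -> 76 treatments; 4
    replicates (8 for FB monocultures) -> 320 plots; 7 image clippings
    per plot.
    """

    n_fb_cultivars: int = 2
    n_sw_entries: int = 12
    n_densities: int = 2
    replicates_default: int = 4
    replicates_fb_mono: int = 8
    clippings_per_plot: int = 7

    def __post_init__(self):
        for name in (
            "n_fb_cultivars",
            "n_sw_entries",
            "n_densities",
            "replicates_default",
            "replicates_fb_mono",
            "clippings_per_plot",
        ):
            if getattr(self, name) < 1:
                raise InvalidDesignError(f"{name} must be >= 1")
        if self.n_densities > len(DENSITY_LEVELS):
            raise InvalidDesignError(
                f"at most {len(DENSITY_LEVELS)} density levels supported"
            )

    @property
    def n_treatments(self) -> int:
        f, s, d = self.n_fb_cultivars, self.n_sw_entries, self.n_densities
        return (f * s + f + s) * d


@dataclass(frozen=True)
class TreatmentSpec:
    """One treatment: a composition (mixture or monoculture) at a density."""

    treatment_id: int
    kind: str  # "mixture" | "fb_mono" | "sw_mono"
    fb_cultivar: Optional[int]
    sw_entry: Optional[int]
    density: str

    def __post_init__(self):
        if self.kind not in ("mixture", "fb_mono", "sw_mono"):
            raise ValueError(f"unknown composition kind {self.kind!r}")
        if self.density not in DENSITY_LEVELS:
            raise ValueError(f"density must be one of {DENSITY_LEVELS}")


@dataclass(frozen=True)
class PlotAssignment:
    plot_id: int
    treatment_id: int
    replicate: int


def enumerate_treatments(design: DesignSpec) -> List[TreatmentSpec]:
    """All treatments of the factorial, with stable ids.

    Order: for each density level, all FB x SW mixtures (FB-major), then
    FB monocultures, then SW monocultures.
    """
    treatments: List[TreatmentSpec] = []
    tid = 0
    for di in range(design.n_densities):
        density = DENSITY_LEVELS[di]
        for fb in range(design.n_fb_cultivars):
            for sw in range(design.n_sw_entries):
                treatments.append(TreatmentSpec(tid, "mixture", fb, sw, density))
                tid += 1
        for fb in range(design.n_fb_cultivars):
            treatments.append(TreatmentSpec(tid, "fb_mono", fb, None, density))
            tid += 1
        for sw in range(design.n_sw_entries):
            treatments.append(TreatmentSpec(tid, "sw_mono", None, sw, density))
            tid += 1
    assert len(treatments) == design.n_treatments
    return treatments


def enumerate_plots(
    treatments: List[TreatmentSpec], design: DesignSpec
) -> List[PlotAssignment]:
    """Replicate every treatment into plots with unique ids.

    FB monocultures get ``replicates_fb_mono`` plots, everything else
    ``replicates_default``.
    """
    plots: List[PlotAssignment] = []
    pid = 0
    for trt in treatments:
        reps = (
            design.replicates_fb_mono
            if trt.kind == "fb_mono"
            else design.replicates_default
        )
        for r in range(reps):
            plots.append(PlotAssignment(pid, trt.treatment_id, r))
            pid += 1
    return plots


def species_fractions(trt: TreatmentSpec) -> Tuple[float, float]:
    """Seed-share fractions (sw, fb) for a composition.

    Mixtures are sown 1:1, i.e. 50% of each species' monoculture rate.
    """
    if trt.kind == "mixture":
        return 0.5, 0.5
    if trt.kind == "sw_mono":
        return 1.0, 0.0
    return 0.0, 1.0
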