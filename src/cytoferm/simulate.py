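"""Synthetic cytometry events and diauxic fermentation time courses.

Every downstream stage is testable without external data because the
generators attach ground truth: event tables carry the mixture
component each event was drawn from, and fermentation series expose the
diauxic-shift time and phenotype group that produced them.

Event channels are log-normal per mixture component (fluorescence
height signals span decades and are well described on a log10 scale).
Acquisition is emulated instrument-side: events below the FSC-H trigger
threshold are discarded and the table is truncated at the registered
event cap, mirroring how a bench cytometer acquires 10 000 events above
an 80 000 forward-scatter trigger.

The fermentation generator is phenomenological — piecewise logistic
growth plus first-order clearance — not a mechanistic metabolic model.
Its job is to produce time courses with the qualitative structure of
diauxic yeast cultivations in the three growth-profile groups:

* group I — wild-type profile: glucose phase, diauxic shift, second
  growth phase on ethanol; no MPPA.
* group II — alanine-transaminase-deleted slow growers: glucose phase
  only, no ethanol growth, pyruvate persists post-shift in the
  0.13–0.20 g/L band, elevated glycerol yield; no MPPA.
* group III — producers: both growth phases, pyruvate cleared after the
  shift, MPPA production starting exactly at the diauxic shift.

BA (benzylacetone) declines continuously for all groups — a basal,
growth-independent consumption — with additional conversion to MPPA in
group III.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .events import CHANNELS, EventTable

# --------------------------------------------------------------------------
# cytometry events
# --------------------------------------------------------------------------

#: Known mixture component names.
COMPONENT_NAMES = (
    "live_singlet_gfp_pos",
    "live_singlet_gfp_neg",
    "dead",
    "doublet",
    "debris",
)


@dataclass(frozen=True)
class ComponentSpec:
    """One mixture component: weight plus per-channel log10 moments."""

    name: str
    weight: float
    log10_mean: dict[str, float]
    log10_sd: dict[str, float]

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("component weight must be non-negative")
        for ch in CHANNELS:
            if ch not in self.log10_mean or ch not in self.log10_sd:
                raise ValueError(f"component {self.name} missing channel {ch}")
            if self.log10_sd[ch] <= 0:
                raise ValueError("log10 standard deviations must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """A mixture of event components; weights must sum to one."""

    components: tuple[ComponentSpec, ...]

    def __post_init__(self) -> None:
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {total}")


# Default channel moments: singlet cells trigger well above the FSC-H
# threshold; doublets have 2x the singlet pulse width; dead (PI-stained)
# cells sit ~2 decades above live cells in FL3-H; GFP-positive cells sit
# ~2 decades above negative ones in FL1-H.
_SINGLET = {"fsc_h": 5.3, "width": 1.7}
_DOUBLET_WIDTH = _SINGLET["width"] + np.log10(2)
_SD = {"fsc_h": 0.10, "width": 0.05, "fl1_h": 0.20, "fl3_h": 0.15}
_FL1_POS, _FL1_NEG = 3.5, 1.5
_FL3_LIVE, _FL3_DEAD = 2.0, 4.2


def _component(name, weight, fl1, fl3, width=None, fsc=None, fl3_sd=None):
    return ComponentSpec(
        name=name,
        weight=weight,
        log10_mean={
            "fsc_h": fsc if fsc is not None else _SINGLET["fsc_h"],
            "width": width if width is not None else _SINGLET["width"],
            "fl1_h": fl1,
            "fl3_h": fl3,
        },
        log10_sd={**_SD, "fl3_h": fl3_sd if fl3_sd is not None else _SD["fl3_h"]},
    )


def default_population_spec(
    live_fraction: float = 0.70,
    gfp_pos_fraction: float = 0.50,
    doublet_fraction: float = 0.05,
    debris_fraction: float = 0.03,
) -> PopulationSpec:
    """Realistic five-component mixture with configurable headline fractions.

    ``live_fraction`` refers to live *singlet* events among the
    non-debris population; ``gfp_pos_fraction`` splits the live
    singlets into GFP-positive/negative.
    """
    core = 1.0 - debris_fraction
    live_w = core * (1 - doublet_fraction) * live_fraction
    dead_w = core * (1 - doublet_fraction) * (1 - live_fraction)
    components = (
        _component(
            "live_singlet_gfp_pos", live_w * gfp_pos_fraction, _FL1_POS, _FL3_LIVE
        ),
        _component(
            "live_singlet_gfp_neg", live_w * (1 - gfp_pos_fraction), _FL1_NEG, _FL3_LIVE
        ),
        _component("dead", dead_w, _FL1_NEG, _FL3_DEAD, fl3_sd=0.20),
        _component(
            "doublet", core * doublet_fraction, _FL1_POS, _FL3_LIVE,
            width=_DOUBLET_WIDTH,
        ),
        _component("debris", debris_fraction, _FL1_NEG, _FL3_LIVE, fsc=4.5),
    )
    return PopulationSpec(components)


def live_dead_spec(live_fraction: float = 0.70) -> PopulationSpec:
    """Minimal two-component live/dead mixture (all singlets, GFP+)."""
    return PopulationSpec(
        (
            _component("live_singlet_gfp_pos", live_fraction, _FL1_POS, _FL3_LIVE),
            _component("dead", 1 - live_fraction, _FL1_NEG, _FL3_DEAD, fl3_sd=0.20),
        )
    )


#: Live components for ground-truth live-fraction bookkeeping.
LIVE_COMPONENTS = frozenset(
    {"live_singlet_gfp_pos", "live_singlet_gfp_neg", "doublet"}
)


def simulate_events(
    spec: PopulationSpec,
    n: int,
    seed: int,
    fsc_threshold: float = 80_000.0,
    max_events: int = 10_000,
) -> EventTable:
    """Draw ``n`` events from the mixture and emulate acquisition.

    Events whose FSC-H falls below the trigger threshold are never
    registered, and at most ``max_events`` events are kept (in draw
    order). Identical seeds give bit-identical tables.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    weights = np.array([c.weight for c in spec.components])
    assignment = rng.choice(len(spec.components), size=n, p=weights)

    channels = {ch: np.empty(n) for ch in CHANNELS}
    for idx, component in enumerate(spec.components):
        sel = assignment == idx
        count = int(sel.sum())
        for ch in CHANNELS:
            channels[ch][sel] = 10 ** rng.normal(
                component.log10_mean[ch], component.log10_sd[ch], size=count
            )
    labels = np.array([spec.components[i].name for i in assignment])

    acquired = channels["fsc_h"] >= fsc_threshold
    table = EventTable.from_arrays(
        fsc_h=channels["fsc_h"][acquired],
        width=channels["width"][acquired],
        fl1_h=channels["fl1_h"][acquired],
        fl3_h=channels["fl3_h"][acquired],
        label=labels[acquired],
    )
    if len(table) > max_events:
        table = EventTable(table.data.iloc[:max_events].reset_index(drop=True))
    return table


def make_gate_fixture() -> EventTable:
    """The canonical 5-event toy table used throughout the documentation.

    With width cut-off 80, FL1-H cut-off 100 and a live threshold
    between the two FL3-H clusters (e.g. 1000):

    ========  ======  =====  =====  =====  ==========================
    event     fsc_h   width  fl1_h  fl3_h  role
    ========  ======  =====  =====  =====  ==========================
    0         200000     50   1000    100  live singlet, GFP-positive
    1         200000     50     10    100  live singlet, GFP-negative
    2         200000    120   1000    100  live doublet
    3         200000     50     10  20000  dead singlet
    4         200000     50      0    100  removed by the static filter
    ========  ======  =====  =====  =====  ==========================
    """
    return EventTable.from_arrays(
        fsc_h=[200_000.0] * 5,
        width=[50.0, 50.0, 120.0, 50.0, 50.0],
        fl1_h=[1000.0, 10.0, 1000.0, 10.0, 0.0],
        fl3_h=[100.0, 100.0, 100.0, 20_000.0, 100.0],
        label=[
            "live_singlet_gfp_pos",
            "live_singlet_gfp_neg",
            "doublet",
            "dead",
            "debris",
        ],
    )


# --------------------------------------------------------------------------
# fermentation time courses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeSpec:
    """Growth-profile phenotype parameters for one strain group.

    Rates are first-order specific rates in 1/h; concentrations in the
    units of the series columns. Group II must have a zero ethanol-phase
    rate and zero pyruvate clearance; only group III produces MPPA.
    """

    group: str
    mu_glucose: float
    mu_ethanol: float
    biomass_yield_glucose: float  # gDW per g glucose
    pyruvate_peak_gl: float
    pyruvate_clearance: float
    mppa_final_mm: float
    mppa_rate: float
    glycerol_yield_multiplier: float
    noise_sd: float = 0.02  # relative measurement noise per channel

    def __post_init__(self) -> None:
        if self.group not in ("I", "II", "III"):
            raise ValueError("group must be 'I', 'II' or 'III'")
        for name in (
            "mu_glucose", "mu_ethanol", "biomass_yield_glucose",
            "pyruvate_peak_gl", "pyruvate_clearance", "mppa_final_mm",
            "mppa_rate", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.group == "II" and self.mu_ethanol != 0:
            raise ValueError("group II has no ethanol growth phase")
        if self.group in ("I", "II") and self.mppa_final_mm != 0:
            raise ValueError("only group III produces MPPA")


_PHENOTYPE_DEFAULTS = {
    "I": dict(
        mu_glucose=0.35, mu_ethanol=0.12, biomass_yield_glucose=0.15,
        pyruvate_peak_gl=0.10, pyruvate_clearance=0.30,
        mppa_final_mm=0.0, mppa_rate=0.0, glycerol_yield_multiplier=1.0,
    ),
    "II": dict(
        mu_glucose=0.22, mu_ethanol=0.0, biomass_yield_glucose=0.10,
        pyruvate_peak_gl=0.165, pyruvate_clearance=0.0,
        mppa_final_mm=0.0, mppa_rate=0.0, glycerol_yield_multiplier=2.5,
    ),
    "III": dict(
        mu_glucose=0.30, mu_ethanol=0.10, biomass_yield_glucose=0.15,
        pyruvate_peak_gl=0.12, pyruvate_clearance=0.30,
        mppa_final_mm=2.9, mppa_rate=0.08, glycerol_yield_multiplier=1.0,
    ),
}


def phenotype(group: str, **overrides) -> PhenotypeSpec:
    """Default phenotype parameters for growth-profile group I/II/III."""
    if group not in _PHENOTYPE_DEFAULTS:
        raise ValueError("group must be 'I', 'II' or 'III'")
    params = {**_PHENOTYPE_DEFAULTS[group], **overrides}
    return PhenotypeSpec(group=group, **params)


@dataclass
class FermentationSeries:
    """A time-indexed fermentation record for one culture."""

    frame: pd.DataFrame = field(repr=False)
    group: str = "I"
    t_shift: float = float("nan")  # diauxic-shift time, h

    def __len__(self) -> int:
        return len(self.frame)


#: Ethanol yield on glucose during fermentative growth, g/g.
ETHANOL_YIELD = 0.40
#: Biomass yield on ethanol during respiratory growth, gDW/g.
BIOMASS_YIELD_ETHANOL = 0.25
#: Baseline glycerol yield on glucose, g/g.
GLYCEROL_YIELD = 0.030
#: Fraction of supplied BA lost to basal (growth-independent) consumption
#: at long times, and its first-order rate (1/h).
BA_BASAL_FRACTION = 0.35
BA_BASAL_RATE = 0.04
#: OH (4-phenylbutan-2-ol) plateau for strains with an intact native
#: alanine transaminase (group I); ALT1-deleted strains form none.
OH_FINAL_MM_GROUP_I = 0.20
#: gDW/L per OD600 unit.
DW_PER_OD = 0.50


def _logistic_fraction(t: np.ndarray, mu: float, seed_fraction: float) -> np.ndarray:
    """Logistic progress curve from ``seed_fraction`` toward 1."""
    return 1.0 / (1.0 + (1.0 - seed_fraction) / seed_fraction * np.exp(-mu * t))


def simulate_timecourse(
    spec: PhenotypeSpec,
    seed: int,
    t_end: float = 80.0,
    dt: float = 0.5,
    glucose0: float = 20.0,
    ba0_mm: float = 5.0,
    x0: float = 0.1,
) -> FermentationSeries:
    """Simulate one diauxic cultivation for the given phenotype.

    Defaults follow the cultivation setup: 2% glucose (20 g/L), 5 mM BA,
    a small inoculum, sampled every 30 min for 80 h. Glucose depletion
    defines the diauxic-shift time. Measurement noise is multiplicative
    with sd ``spec.noise_sd``; monotone channels (glucose down, biomass
    up, BA down, post-shift MPPA up) are re-monotonised after noise so
    the series keeps its physical structure.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end + dt / 2, dt)

    # glucose phase: logistic biomass, glucose depleted proportionally
    span1 = spec.biomass_yield_glucose * glucose0
    g = _logistic_fraction(t, spec.mu_glucose, x0 / (x0 + span1))
    g0 = g[0]
    progress1 = np.clip((g - g0) / (0.99 * (1 - g0)), 0.0, 1.0)
    biomass = x0 + span1 * progress1
    glucose = glucose0 * (1.0 - progress1)

    depleted = np.flatnonzero(glucose <= 0)
    shift_idx = int(depleted[0]) if depleted.size else len(t) - 1
    t_shift = float(t[shift_idx])
    tau = np.clip(t - t_shift, 0.0, None)

    ethanol_peak = ETHANOL_YIELD * (glucose0 - glucose[shift_idx])
    ethanol = ETHANOL_YIELD * (glucose0 - glucose)
    if spec.mu_ethanol > 0:
        h = _logistic_fraction(tau, spec.mu_ethanol, 0.02)
        progress2 = np.clip((h - h[0]) / (0.99 * (1 - h[0])), 0.0, 1.0)
        progress2[t < t_shift] = 0.0
        biomass = biomass + BIOMASS_YIELD_ETHANOL * ethanol_peak * progress2
        ethanol = np.where(
            t < t_shift, ethanol, ethanol_peak * (1.0 - progress2)
        )
    # group II: ethanol persists at its peak

    pyruvate = spec.pyruvate_peak_gl * (1.0 - glucose / glucose0)
    if spec.pyruvate_clearance > 0:
        post = spec.pyruvate_peak_gl * np.exp(-spec.pyruvate_clearance * tau)
        pyruvate = np.where(t < t_shift, pyruvate, post)

    glycerol = (
        GLYCEROL_YIELD * spec.glycerol_yield_multiplier * (glucose0 - glucose)
    )

    basal_loss = ba0_mm * BA_BASAL_FRACTION * (1.0 - np.exp(-BA_BASAL_RATE * t))
    mppa = np.zeros_like(t)
    if spec.mppa_final_mm > 0:
        mppa = np.where(
            t < t_shift,
            0.0,
            spec.mppa_final_mm * (1.0 - np.exp(-spec.mppa_rate * tau)),
        )
    oh = (
        OH_FINAL_MM_GROUP_I * (1.0 - np.exp(-0.02 * t))
        if spec.group == "I"
        else np.zeros_like(t)
    )
    ba = np.clip(ba0_mm - basal_loss - mppa - oh, 0.0, None)

    def noisy(values: np.ndarray) -> np.ndarray:
        if spec.noise_sd == 0:
            return values
        return np.clip(
            values * (1.0 + spec.noise_sd * rng.standard_normal(values.shape)),
            0.0,
            None,
        )

    glucose_n = np.minimum.accumulate(noisy(glucose))
    biomass_n = np.maximum.accumulate(noisy(biomass))
    ba_n = np.minimum.accumulate(noisy(ba))
    mppa_n = noisy(mppa)
    mppa_n[t < t_shift] = 0.0
    mppa_n[t >= t_shift] = np.maximum.accumulate(mppa_n[t >= t_shift])

    frame = pd.DataFrame(
        {
            "time_h": t,
            "glucose_gl": glucose_n,
            "ethanol_gl": noisy(ethanol),
            "pyruvate_gl": noisy(pyruvate),
            "glycerol_gl": noisy(glycerol),
            "biomass_gdw_l": biomass_n,
            "od600": biomass_n / DW_PER_OD,
            "ba_mm": ba_n,
            "mppa_mm": mppa_n,
            "oh_mm": noisy(oh),
        }
    )
    return FermentationSeries(frame=frame, group=spec.group, t_shift=t_shift)


def gfp_trajectory(series: FermentationSeries) -> pd.DataFrame:
    """Ground-truth GFP-positive and live fractions along a cultivation.

    The GFP growth reporter tracks growth activity: the positive
    fraction rises during the glucose phase, dips around the diauxic
    shift, and recovers only in groups with an ethanol phase. Viability
    declines slowly with culture age. Used to parameterise per-timepoint
    event mixtures for gating-recovery experiments.
    """
    t = series.frame["time_h"].to_numpy()
    growing1 = np.clip(1.0 - np.abs(t - series.t_shift / 2) / (series.t_shift / 2), 0, 1)
    gfp = 0.30 + 0.55 * growing1
    if series.group in ("I", "III"):
        tau = np.clip(t - series.t_shift, 0, None)
        gfp = gfp + 0.35 * (1 - np.exp(-0.1 * tau)) * np.exp(-0.01 * tau)
    gfp = np.clip(gfp, 0.05, 0.95)
    live = np.clip(0.95 - 0.002 * t, 0.05, 1.0)
    return pd.DataFrame({"time_h": t, "gfp_pos_fraction": gfp, "live_fraction": live})
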