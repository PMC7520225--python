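"""Synthetic field campaign with known ground truth.

The real study cannot be re-run at a desk, so every input the pipeline
consumes is generated here with a known generating process: daily weather
for two growing seasons, "true" per-cm rooting densities per growth form,
and noisy depth-specific tracer sample tables laid out exactly like the
field design (six campaigns over two seasons, 3 replicate plots per
injection depth, pooled control plots).

The tracer signal model is deliberately the simplest one consistent with
the design's one-day-uptake assumption: a plant's expected uptake fraction
from the labelled depth d is f_d proportional to b(d) * alpha(h_d)
(root density times water-stress availability, normalized over the
campaign's depth set), and the measured deuterium excess is

    d_e = control_mean + label_strength * f_d + Normal(0, noise_sd).

d2H and d18O are back-computed consistently with the deuterium-excess
definition, so the water channel round-trips exactly at zero noise.
Everything is a pure function of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .isotope import CONTROL_LABEL
from .profiles import depth50
from .soilwater import FEDDES_ALFALFA, FeddesParams, feddes_alpha

__all__ = [
    "SpeciesDef",
    "SeasonDesign",
    "Scenario",
    "paper_like_scenario",
    "generate_weather",
    "generate_true_roots",
    "simulate_tracer_campaign",
    "simulate_n15_campaign",
    "generate_scenario_tables",
]


@dataclass(frozen=True)
class SpeciesDef:
    name: str
    growth_form: str  # "tree" | "grass"
    presence_prob: float = 1.0


@dataclass
class SeasonDesign:
    """One growing season's layout: dates, rain target, campaign depth sets."""

    name: str
    start_date: str
    n_days: int
    precip_target_mm: float
    campaign_days: list  # day indices into the season
    campaign_depths: list  # one depth list per campaign
    knots: list  # spline basis dimension per campaign

    def campaign_label(self, idx: int) -> str:
        date = pd.Timestamp(self.start_date) + pd.Timedelta(days=int(self.campaign_days[idx]))
        return date.strftime("%Y-%m-%d")


@dataclass
class Scenario:
    """Study conditions for the synthetic campaign; defaults mirror the
    two-season design the pipeline is meant to analyze."""

    seasons: list = field(default_factory=list)
    species: list = field(default_factory=list)
    plots_per_depth: int = 3
    control_plots: int = 3
    control_samples_per_plot: int = 8
    subreplicates: tuple = (2, 4)  # inclusive range per species-plot
    # water channel
    control_d2H_mean: float = -65.0
    control_d2H_sd: float = 30.0
    d18O_base: float = -6.0
    d18O_sd: float = 0.5
    tracer_label_strength: float = 200.0  # permil d_e per unit uptake fraction
    noise_sd: float = 30.0  # permil, treated-sample d_e noise
    # nitrogen channel
    control_d15N_mean: float = 3.4
    control_d15N_sd: float = 2.1
    n15_label_strength: float = 200.0
    n15_noise_sd: float = 10.0
    # true rooting distributions (depth at which half the activity lies)
    tree_d50_cm: float = 22.0
    grass_d50_cm: float = 17.0
    n15_tree_d50_cm: float = 15.0
    n15_grass_d50_cm: float = 18.0
    root_shape: float = 1.0
    n_cells: int = 125
    dz: float = 1.0

    @property
    def growth_forms(self):
        return sorted({s.growth_form for s in self.species})

    def true_root_density(self, growth_form: str, channel: str = "water") -> np.ndarray:
        if channel == "water":
            d50 = self.tree_d50_cm if growth_form == "tree" else self.grass_d50_cm
        else:
            d50 = self.n15_tree_d50_cm if growth_form == "tree" else self.n15_grass_d50_cm
        return generate_true_roots(d50, self.root_shape, self.n_cells, self.dz)


def paper_like_scenario() -> Scenario:
    """The bundled two-season scenario: depth sets {5,10,20,30,50,100} cm in
    season one (30 cm in the first campaign only) and {10,20,30,50,70} cm in
    season two, 3 plots per depth, growing-season rain targets 587 and
    866 mm, tree/grass D50 of 22/17 cm."""
    season1 = SeasonDesign(
        name="2010/11",
        start_date="2010-10-01",
        n_days=243,
        precip_target_mm=587.0,
        campaign_days=[45, 137, 221],
        campaign_depths=[
            [5, 10, 20, 30, 50, 100],
            [5, 10, 20, 50, 100],
            [5, 10, 20, 50, 100],
        ],
        knots=[5, 4, 4],
    )
    season2 = SeasonDesign(
        name="2012/13",
        start_date="2012-10-01",
        n_days=243,
        precip_target_mm=866.0,
        campaign_days=[45, 137, 221],
        campaign_depths=[
            [10, 20, 30, 50, 70],
            [10, 20, 30, 50, 70],
            [10, 20, 30, 50, 70],
        ],
        knots=[4, 4, 4],
    )
    # ten common species (five per growth form): with 2-4 tissue
    # subreplicates per species-plot this reproduces the field campaign's
    # sample volume (~575 plant samples per six-depth campaign)
    species = [
        SpeciesDef("Dichrostachys cinerea", "tree"),
        SpeciesDef("Senegalia nigrescens", "tree"),
        SpeciesDef("Flueggea virosa", "tree"),
        SpeciesDef("Sclerocarya birrea", "tree"),
        SpeciesDef("Combretum apiculatum", "tree"),
        SpeciesDef("Panicum maximum", "grass"),
        SpeciesDef("Urochloa mosambicensis", "grass"),
        SpeciesDef("Themeda triandra", "grass"),
        SpeciesDef("Digitaria eriantha", "grass"),
        SpeciesDef("Bothriochloa radicans", "grass"),
    ]
    return Scenario(seasons=[season1, season2], species=species)


# ---------------------------------------------------------------------------
# weather


def generate_weather(
    seed,
    target_total_mm: float,
    n_days: int = 243,
    start_date: str = "2010-10-01",
    wet_day_prob: float = 0.30,
    gamma_shape: float = 0.7,
) -> pd.DataFrame:
    """Stochastic daily weather for one (southern-hemisphere) growing season.

    Rain is a marked Bernoulli/Gamma process scaled so the *expected* season
    total equals ``target_total_mm``; temperature, humidity, radiation and
    wind follow seasonal sinusoids (summer peak mid-January) plus bounded
    noise.  ``seed`` may be an int or a numpy Generator.
    """
    if target_total_mm <= 0:
        raise ValueError("target precipitation must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n_days)
    dates = pd.date_range(start_date, periods=n_days, freq="D")

    wet = rng.random(n_days) < wet_day_prob
    mean_event_mm = target_total_mm / (n_days * wet_day_prob)
    depths_mm = rng.gamma(gamma_shape, mean_event_mm / gamma_shape, size=n_days)
    precip_cm = np.where(wet, depths_mm, 0.0) / 10.0

    # summer (mid-January ~ day 107 from 1 October) temperature peak
    season_phase = np.cos(2.0 * np.pi * (t - 107.0) / 365.0)
    tmean = 23.0 + 3.5 * season_phase + rng.normal(0.0, 1.2, n_days)
    spread = 6.0 + rng.normal(0.0, 0.8, n_days).clip(-2.5, 2.5)
    tmax = tmean + spread
    tmin = tmean - spread
    rh = np.clip(60.0 + 12.0 * wet + rng.normal(0.0, 6.0, n_days), 20.0, 100.0)
    solar = np.clip(
        (24.0 + 4.0 * season_phase) * np.where(wet, 0.55, 1.0)
        + rng.normal(0.0, 1.5, n_days),
        2.0,
        32.0,
    )
    wind = np.clip(rng.normal(2.0, 0.7, n_days), 0.3, None)

    return pd.DataFrame(
        {
            "date": dates.strftime("%Y-%m-%d"),
            "precip_cm": precip_cm,
            "tmin_C": tmin,
            "tmax_C": tmax,
            "rh_mean_pct": rh,
            "wind_m_s": wind,
            "solar_MJ_m2": solar,
        }
    )


# ---------------------------------------------------------------------------
# true rooting distributions


def generate_true_roots(
    d50_target_cm: float,
    shape: float = 1.0,
    n_cells: int = 125,
    dz: float = 1.0,
) -> np.ndarray:
    """Weibull-shaped per-cm root density whose D50 equals the target.

    density(z) ~ (z/scale)^(shape-1) exp(-(z/scale)^shape), truncated to the
    column and normalized; the scale is solved numerically so the discrete
    depth50 of the output matches ``d50_target_cm`` (within 0.5 cm).
    """
    if not 0 < d50_target_cm < n_cells * dz:
        raise ValueError("d50 target must lie inside the column")
    centers = (np.arange(n_cells) + 0.5) * dz

    def density(scale):
        x = centers / scale
        with np.errstate(over="ignore"):
            d = x ** (shape - 1.0) * np.exp(-(x**shape))
        return d / (d.sum() * dz)

    def gap(scale):
        return depth50(density(scale), dz) - d50_target_cm

    lo, hi = 0.5, 4.0 * n_cells * dz
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"d50 target {d50_target_cm} cm infeasible for shape {shape} "
            f"on a {n_cells * dz:.0f} cm column"
        )
    scale = brentq(gap, lo, hi, xtol=1e-6)
    out = density(scale)
    assert abs(depth50(out, dz) - d50_target_cm) <= 0.5
    return out


# ---------------------------------------------------------------------------
# tracer campaigns


def _uptake_fractions(
    depths, density, dz: float, head_profile=None, feddes: FeddesParams = FEDDES_ALFALFA
) -> np.ndarray:
    """Expected uptake fraction from each labelled depth: f_d ~ b(d) alpha(h_d),
    normalized over the campaign's depth set."""
    depths = np.asarray(depths, dtype=float)
    idx = np.clip((depths / dz).astype(int), 0, density.size - 1)
    b = density[idx]
    if head_profile is not None:
        alpha = feddes_alpha(np.asarray(head_profile, dtype=float)[idx], feddes)
    else:
        alpha = np.ones_like(b)
    w = b * alpha
    total = w.sum()
    if total <= 0:
        raise ValueError("no active uptake at any labelled depth")
    return w / total


def _campaign_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "campaign",
            "plot_id",
            "species",
            "growth_form",
            "injection_depth_cm",
            "d2H_permil",
            "d18O_permil",
            "d15N_permil",
        ],
    )


def simulate_tracer_campaign(
    scenario: Scenario,
    season_idx: int,
    campaign_idx: int,
    rng: np.random.Generator,
    true_roots: dict | None = None,
    head_profile=None,
    feddes: FeddesParams = FEDDES_ALFALFA,
) -> pd.DataFrame:
    """One water-tracer campaign's plant isotope sample table.

    ``true_roots`` maps growth form to a per-cm density (defaults to the
    scenario's water-channel profiles).  ``head_profile`` (optional, from a
    soil water run) imposes water-stress availability on uptake; without it
    all labelled depths are treated as plant-available, matching moist
    sampling-date conditions.
    """
    season = scenario.seasons[season_idx]
    depths = season.campaign_depths[campaign_idx]
    label = season.campaign_label(campaign_idx)
    if true_roots is None:
        true_roots = {
            gf: scenario.true_root_density(gf, "water") for gf in scenario.growth_forms
        }
    mu_e = scenario.control_d2H_mean - (8.0 * scenario.d18O_base + 10.0)

    fractions = {
        gf: _uptake_fractions(
            depths, true_roots[gf], scenario.dz, head_profile, feddes
        )
        for gf in scenario.growth_forms
    }

    rows = []
    counter = 0

    def water_row(plot_id, species, growth_form, depth_label, d_excess):
        nonlocal counter
        counter += 1
        d18o = scenario.d18O_base + rng.normal(0.0, scenario.d18O_sd)
        d2h = d_excess + 8.0 * d18o + 10.0
        return {
            "sample_id": f"{label}-{counter:04d}",
            "campaign": label,
            "plot_id": plot_id,
            "species": species,
            "growth_form": growth_form,
            "injection_depth_cm": depth_label,
            "d2H_permil": d2h,
            "d18O_permil": d18o,
            "d15N_permil": np.nan,
        }

    lo, hi = scenario.subreplicates
    for d_i, depth in enumerate(depths):
        for p in range(scenario.plots_per_depth):
            plot_id = f"{label}-d{depth:g}-p{p + 1}"
            for sp in scenario.species:
                if rng.random() >= sp.presence_prob:
                    continue
                f = fractions[sp.growth_form][d_i]
                n_sub = int(rng.integers(lo, hi + 1))
                for _ in range(n_sub):
                    de = (
                        mu_e
                        + scenario.tracer_label_strength * f
                        + rng.normal(0.0, scenario.noise_sd)
                    )
                    rows.append(water_row(plot_id, sp.name, sp.growth_form, depth, de))
    for p in range(scenario.control_plots):
        plot_id = f"{label}-control-p{p + 1}"
        for sp in scenario.species:
            n_ctrl = max(1, scenario.control_samples_per_plot // len(scenario.species))
            for _ in range(n_ctrl):
                de = mu_e + rng.normal(0.0, scenario.control_d2H_sd)
                rows.append(
                    water_row(plot_id, sp.name, sp.growth_form, CONTROL_LABEL, de)
                )
    return _campaign_frame(rows)


def simulate_n15_campaign(
    scenario: Scenario,
    season_idx: int,
    campaign_idx: int,
    rng: np.random.Generator,
    true_roots: dict | None = None,
    head_profile=None,
    feddes: FeddesParams = FEDDES_ALFALFA,
) -> pd.DataFrame:
    """One 15N campaign table; analogous to the water channel with an
    independently configurable nitrogen uptake profile and d15N signal."""
    season = scenario.seasons[season_idx]
    depths = season.campaign_depths[campaign_idx]
    label = season.campaign_label(campaign_idx) + "-15N"
    if true_roots is None:
        true_roots = {
            gf: scenario.true_root_density(gf, "nitrogen")
            for gf in scenario.growth_forms
        }
    fractions = {
        gf: _uptake_fractions(depths, true_roots[gf], scenario.dz, head_profile, feddes)
        for gf in scenario.growth_forms
    }
    rows = []
    counter = 0

    def n_row(plot_id, species, growth_form, depth_label, d15n):
        nonlocal counter
        counter += 1
        return {
            "sample_id": f"{label}-{counter:04d}",
            "campaign": label,
            "plot_id": plot_id,
            "species": species,
            "growth_form": growth_form,
            "injection_depth_cm": depth_label,
            "d2H_permil": np.nan,
            "d18O_permil": np.nan,
            "d15N_permil": d15n,
        }

    lo, hi = scenario.subreplicates
    for d_i, depth in enumerate(depths):
        for p in range(scenario.plots_per_depth):
            plot_id = f"{label}-d{depth:g}-p{p + 1}"
            for sp in scenario.species:
                if rng.random() >= sp.presence_prob:
                    continue
                f = fractions[sp.growth_form][d_i]
                for _ in range(int(rng.integers(lo, hi + 1))):
                    val = (
                        scenario.control_d15N_mean
                        + scenario.n15_label_strength * f
                        + rng.normal(0.0, scenario.n15_noise_sd)
                    )
                    rows.append(n_row(plot_id, sp.name, sp.growth_form, depth, val))
    for p in range(scenario.control_plots):
        plot_id = f"{label}-control-p{p + 1}"
        for sp in scenario.species[: max(1, len(scenario.species) // 2)]:
            val = scenario.control_d15N_mean + rng.normal(0.0, scenario.control_d15N_sd)
            rows.append(n_row(plot_id, sp.name, sp.growth_form, CONTROL_LABEL, val))
    return _campaign_frame(rows)


def generate_scenario_tables(scenario: Scenario, seed: int) -> dict:
    """All pipeline inputs for a scenario: per-season weather tables and
    per-campaign water-tracer sample tables, from one master seed.

    A single :class:`numpy.random.SeedSequence` spawns an independent
    substream per season and campaign, so outputs are bitwise reproducible
    and insensitive to generation order.
    """
    master = np.random.SeedSequence(seed)
    seasons_out = []
    n_campaigns = sum(len(s.campaign_days) for s in scenario.seasons)
    streams = master.spawn(len(scenario.seasons) + n_campaigns)
    weather_streams = streams[: len(scenario.seasons)]
    campaign_streams = iter(streams[len(scenario.seasons) :])
    for s_i, season in enumerate(scenario.seasons):
        weather = generate_weather(
            np.random.default_rng(weather_streams[s_i]),
            season.precip_target_mm,
            season.n_days,
            season.start_date,
        )
        campaigns = []
        for c_i in range(len(season.campaign_days)):
            rng = np.random.default_rng(next(campaign_streams))
            campaigns.append(
                {
                    "label": season.campaign_label(c_i),
                    "day": season.campaign_days[c_i],
                    "depths": season.campaign_depths[c_i],
                    "knots": season.knots[c_i],
                    "samples": simulate_tracer_campaign(scenario, s_i, c_i, rng),
                }
            )
        seasons_out.append(
            {"design": season, "weather": weather, "campaigns": campaigns}
        )
    return {"scenario": scenario, "seasons": seasons_out, "seed": seed}
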