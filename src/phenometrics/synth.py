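"""Synthetic woodland generator with known ground-truth phenology.

Simulates a temperate deciduous woodland in spring: each tree leafs out along
a latent logistic trajectory (midpoint = the tree's true half-date), and the
caterpillar community feeding on it descends into interception traps with a
unimodal (Gaussian-shaped) daily intensity whose timing depends linearly on
the host tree's timing plus a sampling-area offset.  Five observation streams
of differing fidelity are emitted at the already-extracted measurement level:

* ordinal bud scores (mean of 12 crown sections, observer jitter),
* effective leaf-area index (LAI) and crown NDVI (lagged, noisy logistics),
* water-trap caterpillar counts (Poisson, accumulating between visits) with a
  final-instar winter-moth substream (binomial thinning, retention drifting
  upward through the season so the thinned peak falls slightly later),
* frass mass in grams (unimodal, leading the count peak by a few days),
* one end-of-season herbivory fraction per tree, decreasing with tree timing.

Everything is driven by a single seed; identical configs and seeds reproduce
identical tables byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

__all__ = [
    "SpeciesConfig",
    "AreaConfig",
    "WoodlandConfig",
    "SyntheticTruth",
    "generate_woodland",
    "default_config",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class SpeciesConfig:
    """One tree species: sample size, mean budburst day-of-year, bud-scale
    maximum (7 for oaks, 5 otherwise) and mean peak caterpillar intensity."""

    name: str
    n_trees: int
    mean_budburst: float
    max_stage: int
    peak_abundance: float

    def validate(self) -> None:
        if self.n_trees < 0:
            raise ValueError(f"{self.name}: n_trees must be >= 0")
        if self.max_stage not in (5, 7):
            raise ValueError(f"{self.name}: max_stage must be 5 or 7")
        if not math.isfinite(self.mean_budburst):
            raise ValueError(f"{self.name}: non-finite mean_budburst")
        if not (self.peak_abundance > 0 and math.isfinite(self.peak_abundance)):
            raise ValueError(f"{self.name}: peak_abundance must be positive finite")


@dataclass
class AreaConfig:
    """A sampling area: name, additive timing offset (days) applied to the
    caterpillar stream, and the area's centre on the simulated 100 m grid."""

    name: str
    timing_offset: float
    center: tuple[float, float]

    def validate(self) -> None:
        if not math.isfinite(self.timing_offset):
            raise ValueError(f"{self.name}: non-finite timing_offset")


@dataclass
class WoodlandConfig:
    species: list[SpeciesConfig] = field(default_factory=list)
    areas: list[AreaConfig] = field(default_factory=list)
    n_trees_per_species: int | None = None  # overrides SpeciesConfig.n_trees
    between_species_spread: float | None = None  # rescale species means to this range
    within_species_sd: float = 5.0  # days, per-tree budburst deviation
    rate_mean: float = 0.35  # logistic rate k (logit units / day)
    rate_sd: float = 0.05

    # cross-trophic linkage: caterpillar peak day = a + b * half_date + area + noise
    cross_trophic_intercept: float = 127.6
    cross_trophic_slope: float = 0.20
    cross_trophic_sd: float = 2.0
    count_sigma: float = 6.0  # Gaussian intensity width (days)
    abundance_cv: float = 0.3  # lognormal sd of per-tree peak intensity

    # frass stream
    frass_lead_days: float = 4.0  # frass biomass peak precedes count peak
    frass_sigma: float = 6.0
    frass_mass_scale: float = 0.012  # grams/day at peak per unit count intensity
    frass_noise_sd: float = 0.25  # lognormal sd on visit masses

    # final-instar winter-moth thinning: retention p0 + slope*(t - peak)
    fwm_retention: float = 0.4
    fwm_retention_slope: float = 0.011  # per day; shifts thinned peak later ~1 day

    # observation-stream noise (documented assumptions, not field estimates)
    bud_section_sd: float = 0.5  # logit-scale sd per crown section
    n_sections: int = 12
    observer_sd: float = 0.3  # logit-scale observer intercept sd
    n_observers: int = 4
    lai_base: float = 0.5
    lai_amplitude: float = 3.0
    lai_noise_sd: float = 0.15
    lai_lag: float = 10.0  # days between budburst and half-leaf
    ndvi_base: float = 0.35
    ndvi_amplitude: float = 0.45
    ndvi_noise_sd: float = 0.02
    ndvi_lag: float = 6.0
    outlier_prob: float = 0.02
    outlier_sd_lai: float = 1.0
    outlier_sd_ndvi: float = 0.15

    # herbivory link: logit(mean fraction) = h0 + h1 * half_date + canopy effect
    herbivory_intercept: float = 5.85
    herbivory_slope: float = -0.07
    herbivory_precision: float = 25.0
    canopy_effects: dict = field(
        default_factory=lambda: {"lower": 0.2, "middle": 0.0, "upper": -0.2}
    )

    # visit schedules (day-of-year windows per stream)
    visit_interval: float = 3.0
    missed_visit_prob: float = 0.05
    bud_window: tuple[float, float] = (84.0, 146.0)
    lai_window: tuple[float, float] = (84.0, 160.0)
    ndvi_window: tuple[float, float] = (80.0, 160.0)
    trap_window: tuple[float, float] = (123.0, 172.0)
    frass_window: tuple[float, float] = (119.0, 167.0)

    rng_seed: int = 0

    def __post_init__(self):
        if not self.species:
            self.species = _default_species()
        if not self.areas:
            self.areas = _default_areas()

    def validate(self) -> None:
        for sp in self.species:
            sp.validate()
        for ar in self.areas:
            ar.validate()
        n_total = sum(
            self.n_trees_per_species if self.n_trees_per_species is not None else sp.n_trees
            for sp in self.species
        )
        if n_total <= 0:
            raise ValueError("woodland must contain at least one tree")
        positive = {
            "within_species_sd": self.within_species_sd,
            "rate_mean": self.rate_mean,
            "count_sigma": self.count_sigma,
            "frass_sigma": self.frass_sigma,
            "frass_mass_scale": self.frass_mass_scale,
            "herbivory_precision": self.herbivory_precision,
            "visit_interval": self.visit_interval,
        }
        for name, v in positive.items():
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        nonneg = {
            "rate_sd": self.rate_sd,
            "cross_trophic_sd": self.cross_trophic_sd,
            "bud_section_sd": self.bud_section_sd,
            "observer_sd": self.observer_sd,
            "lai_noise_sd": self.lai_noise_sd,
            "ndvi_noise_sd": self.ndvi_noise_sd,
            "frass_noise_sd": self.frass_noise_sd,
            "abundance_cv": self.abundance_cv,
        }
        for name, v in nonneg.items():
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be nonnegative and finite, got {v!r}")
        for name, p in {
            "missed_visit_prob": self.missed_visit_prob,
            "fwm_retention": self.fwm_retention,
            "outlier_prob": self.outlier_prob,
        }.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
        for name in ("cross_trophic_intercept", "cross_trophic_slope",
                     "herbivory_intercept", "herbivory_slope", "frass_lead_days"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    # -- config file round-trip (key-value text, nested sections) --

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WoodlandConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["species"] = [SpeciesConfig(**s) for s in d.get("species", [])]
        d["areas"] = [
            AreaConfig(a["name"], a["timing_offset"], tuple(a["center"]))
            for a in d.get("areas", [])
        ]
        for key in ("bud_window", "lai_window", "ndvi_window", "trap_window", "frass_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _default_species() -> list[SpeciesConfig]:
    # six common UK broadleaf species; budburst means span ~32 days
    return [
        SpeciesConfig("hazel", 30, 92.0, 5, 10.0),
        SpeciesConfig("sycamore", 18, 100.0, 5, 9.0),
        SpeciesConfig("birch", 17, 104.0, 5, 12.0),
        SpeciesConfig("beech", 5, 108.0, 5, 6.0),
        SpeciesConfig("oak", 77, 112.0, 7, 30.0),
        SpeciesConfig("ash", 23, 124.0, 5, 8.0),
    ]


def _default_areas() -> list[AreaConfig]:
    return [
        AreaConfig("Great Wood", 0.0, (0.0, 0.0)),
        AreaConfig("ForestGEO", 2.3, (800.0, 600.0)),
        AreaConfig("Marley", -1.2, (1200.0, -500.0)),
    ]


def default_config(**overrides) -> WoodlandConfig:
    """The default study conditions; keyword overrides replace single fields."""
    return dataclasses.replace(WoodlandConfig(), **overrides)


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated woodland.

    ``per_tree`` has one row per tree with the latent half-dates of every
    stream, the latent logistic rate, the true caterpillar peak day/intensity,
    true trap-stream half-fall days, and the latent herbivory mean fraction.
    The global linkage parameters are kept alongside.
    """

    per_tree: pd.DataFrame
    cross_trophic_intercept: float
    cross_trophic_slope: float
    area_offsets: dict

    def write_csv(self, path) -> None:
        df = self.per_tree.copy()
        df["cross_trophic_intercept"] = self.cross_trophic_intercept
        df["cross_trophic_slope"] = self.cross_trophic_slope
        df.to_csv(path, index=False)


def _visit_days(window, interval, rng, missed_prob):
    days = np.arange(window[0], window[1] + 1e-9, interval)
    if missed_prob > 0:
        keep = rng.random(days.size) >= missed_prob
        keep[0] = True  # season start always observed
        keep[-1] = True
        days = days[keep]
    return days


def _gauss_interval_mass(lo, hi, mu, sigma):
    """Integral of a unit-height Gaussian bump A=1 over [lo, hi]."""
    z = sigma * math.sqrt(2.0 * math.pi)
    return z * (norm.cdf((hi - mu) / sigma) - norm.cdf((lo - mu) / sigma))


def _truncated_gauss_median(mu, sigma, lo, hi):
    a, b = norm.cdf((lo - mu) / sigma), norm.cdf((hi - mu) / sigma)
    return mu + sigma * norm.ppf(0.5 * (a + b))


def _thinned_half_day(mu, sigma, lo, hi, p0, slope):
    """Numeric median day of the thinned intensity I(t) * p(t) on [lo, hi]."""
    t = np.arange(lo, hi, 0.01)
    inten = np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    p = np.clip(p0 + slope * (t - mu), 0.01, 0.99)
    cum = np.cumsum(inten * p)
    cum /= cum[-1]
    return float(t[np.searchsorted(cum, 0.5)])


def _thinned_peak_day(mu, sigma, lo, hi, p0, slope):
    t = np.arange(lo, hi, 0.01)
    inten = np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    p = np.clip(p0 + slope * (t - mu), 0.01, 0.99)
    return float(t[np.argmax(inten * p)])


def generate_woodland(config: WoodlandConfig):
    """Simulate one woodland.

    Returns
    -------
    trees : DataFrame
        One row per tree: tree_id, species, area, x, y, max_stage,
        herbivory (observed fraction of leaf area consumed), canopy_level.
    observations : DataFrame
        Long format: tree_id, species, area, method, day, value, observer_id.
    truth : SyntheticTruth
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    species_means = np.array([sp.mean_budburst for sp in config.species], dtype=float)
    if config.between_species_spread is not None and len(config.species) > 1:
        lo, hi = species_means.min(), species_means.max()
        if hi > lo:
            center = species_means.mean()
            scale = config.between_species_spread / (hi - lo)
            species_means = center + (species_means - center) * scale

    area_names = [a.name for a in config.areas]
    area_offsets = {a.name: a.timing_offset for a in config.areas}
    area_centers = {a.name: a.center for a in config.areas}

    tree_rows, truth_rows, obs_frames = [], [], []
    tree_counter = 0

    for sp, sp_mean in zip(config.species, species_means):
        n = config.n_trees_per_species if config.n_trees_per_species is not None else sp.n_trees
        for i in range(n):
            tree_id = f"{sp.name}_{i + 1:03d}"
            area = area_names[tree_counter % len(area_names)]
            cx, cy = area_centers[area]
            # trees sit near 100 m grid posts clustered inside their area
            gx = cx + 100.0 * rng.integers(0, 4) + rng.uniform(-30, 30)
            gy = cy + 100.0 * rng.integers(0, 4) + rng.uniform(-30, 30)

            half_date = sp_mean + config.within_species_sd * rng.standard_normal()
            rate = max(0.05, config.rate_mean + config.rate_sd * rng.standard_normal())
            tree_counter += 1

            # --- caterpillar stream truth ---
            mu_cat = (
                config.cross_trophic_intercept
                + config.cross_trophic_slope * half_date
                + area_offsets[area]
                + config.cross_trophic_sd * rng.standard_normal()
            )
            amp = sp.peak_abundance * math.exp(
                config.abundance_cv * rng.standard_normal()
                - 0.5 * config.abundance_cv**2
            )
            mu_frass = mu_cat - config.frass_lead_days
            tw, fw = config.trap_window, config.frass_window
            truth_rows.append(
                {
                    "tree_id": tree_id,
                    "species": sp.name,
                    "area": area,
                    "half_date": half_date,
                    "rate": rate,
                    "lai_half_date": half_date + config.lai_lag,
                    "ndvi_half_date": half_date + config.ndvi_lag,
                    "cat_peak_day": mu_cat,
                    "cat_peak_intensity": amp,
                    "fwm_peak_day": _thinned_peak_day(
                        mu_cat, config.count_sigma, tw[0], tw[1],
                        config.fwm_retention, config.fwm_retention_slope,
                    ),
                    "frass_peak_day": mu_frass,
                    "cat_half_day": _truncated_gauss_median(
                        mu_cat, config.count_sigma, tw[0], tw[1]
                    ),
                    "fwm_half_day": _thinned_half_day(
                        mu_cat, config.count_sigma, tw[0], tw[1],
                        config.fwm_retention, config.fwm_retention_slope,
                    ),
                    "frass_half_day": _truncated_gauss_median(
                        mu_frass, config.frass_sigma, fw[0], fw[1]
                    ),
                }
            )

            # --- bud scores ---
            bud_days = _visit_days(config.bud_window, config.visit_interval,
                                   rng, config.missed_visit_prob)
            observers = rng.integers(0, config.n_observers, size=bud_days.size)
            obs_effect = config.observer_sd * rng.standard_normal(config.n_observers)
            scores = np.empty(bud_days.size)
            for j, d in enumerate(bud_days):
                latent = rate * (d - half_date) + obs_effect[observers[j]]
                section = latent + config.bud_section_sd * rng.standard_normal(
                    config.n_sections
                )
                stages = 1 + np.clip(
                    np.round(_sigmoid(section) * (sp.max_stage - 1)), 0, sp.max_stage - 1
                )
                scores[j] = stages.mean()
            obs_frames.append(
                pd.DataFrame(
                    {
                        "tree_id": tree_id,
                        "species": sp.name,
                        "area": area,
                        "method": "bud_score",
                        "day": bud_days,
                        "value": scores,
                        "observer_id": [f"obs_{o + 1}" for o in observers],
                    }
                )
            )

            # --- LAI and NDVI (lagged noisy logistics with rare outliers) ---
            for method, window, base, amp_s, lag, noise_sd, out_sd in (
                ("lai", config.lai_window, config.lai_base, config.lai_amplitude,
                 config.lai_lag, config.lai_noise_sd, config.outlier_sd_lai),
                ("ndvi", config.ndvi_window, config.ndvi_base, config.ndvi_amplitude,
                 config.ndvi_lag, config.ndvi_noise_sd, config.outlier_sd_ndvi),
            ):
                days = _visit_days(window, config.visit_interval, rng,
                                   config.missed_visit_prob)
                mean = base + amp_s * _sigmoid(rate * (days - half_date - lag))
                vals = mean + noise_sd * rng.standard_normal(days.size)
                if config.outlier_prob > 0:
                    hit = rng.random(days.size) < config.outlier_prob
                    vals = vals + hit * out_sd * rng.standard_normal(days.size)
                vals = np.maximum(vals, 0.0)  # physical floor for LAI/NDVI
                obs_frames.append(
                    pd.DataFrame(
                        {
                            "tree_id": tree_id,
                            "species": sp.name,
                            "area": area,
                            "method": method,
                            "day": days,
                            "value": vals,
                            "observer_id": "",
                        }
                    )
                )

            # --- water-trap counts (accumulate between kept visits) ---
            trap_days = _visit_days(config.trap_window, config.visit_interval,
                                    rng, config.missed_visit_prob)
            prev = np.concatenate([[config.trap_window[0] - config.visit_interval],
                                   trap_days[:-1]])
            masses = np.array(
                [
                    amp * _gauss_interval_mass(lo, hi, mu_cat, config.count_sigma)
                    for lo, hi in zip(prev, trap_days)
                ]
            )
            totals = rng.poisson(masses)
            mid = 0.5 * (prev + trap_days)
            p_fwm = np.clip(
                config.fwm_retention + config.fwm_retention_slope * (mid - mu_cat),
                0.01, 0.99,
            )
            fwm = rng.binomial(totals, p_fwm)
            for method, vals in (("count_total", totals), ("count_fwm", fwm)):
                obs_frames.append(
                    pd.DataFrame(
                        {
                            "tree_id": tree_id,
                            "species": sp.name,
                            "area": area,
                            "method": method,
                            "day": trap_days,
                            "value": vals.astype(float),
                            "observer_id": "",
                        }
                    )
                )

            # --- frass masses ---
            frass_days = _visit_days(config.frass_window, config.visit_interval,
                                     rng, config.missed_visit_prob)
            prevf = np.concatenate([[config.frass_window[0] - config.visit_interval],
                                    frass_days[:-1]])
            fmass = np.array(
                [
                    config.frass_mass_scale * amp
                    * _gauss_interval_mass(lo, hi, mu_frass, config.frass_sigma)
                    for lo, hi in zip(prevf, frass_days)
                ]
            )
            if config.frass_noise_sd > 0:
                fmass = fmass * np.exp(
                    config.frass_noise_sd * rng.standard_normal(fmass.size)
                    - 0.5 * config.frass_noise_sd**2
                )
            obs_frames.append(
                pd.DataFrame(
                    {
                        "tree_id": tree_id,
                        "species": sp.name,
                        "area": area,
                        "method": "frass_mass_g",
                        "day": frass_days,
                        "value": fmass,
                        "observer_id": "",
                    }
                )
            )

            # --- herbivory (one bounded fraction per tree) ---
            canopy = ("lower", "middle", "upper")[int(rng.integers(0, 3))]
            logit_mu = (
                config.herbivory_intercept
                + config.herbivory_slope * half_date
                + config.canopy_effects.get(canopy, 0.0)
            )
            mu_h = float(_sigmoid(logit_mu))
            phi = config.herbivory_precision
            herb = float(rng.beta(mu_h * phi, (1.0 - mu_h) * phi))
            truth_rows[-1]["herbivory_mean"] = mu_h

            tree_rows.append(
                {
                    "tree_id": tree_id,
                    "species": sp.name,
                    "area": area,
                    "x": gx,
                    "y": gy,
                    "max_stage": sp.max_stage,
                    "herbivory": herb,
                    "canopy_level": canopy,
                }
            )

    trees = pd.DataFrame(tree_rows)
    observations = pd.concat(obs_frames, ignore_index=True)
    truth = SyntheticTruth(
        per_tree=pd.DataFrame(truth_rows),
        cross_trophic_intercept=config.cross_trophic_intercept,
        cross_trophic_slope=config.cross_trophic_slope,
        area_offsets=area_offsets,
    )
    return trees, observations, truth
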