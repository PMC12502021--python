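"""Synthetic leaf-level datasets with the statistical structure of a
multi-species common-garden heat-tolerance campaign.

The generator emulates four tables: (1) Fv/Fm measurements of detached
leaves heated to a set of target temperatures (plus an ambient pre-treatment
control per leaf), following the negative-exponential decay model with
additive Gaussian noise truncated at zero; (2) right-skewed midday leaf
temperatures of sun-exposed leaves (skew-normal); (3) thylakoid lipidomes
whose per-class double-bond index is a linear function of the group's true
T50; (4) species-site trait tables (leaf area, stomatal conductance, LMA,
growth temperature, maximum air temperature, osmolality) with configurable
linear coupling to the true T50.

One global seed governs all four generators through a fixed stream-splitting
rule: ``numpy.random.SeedSequence(random_seed).spawn(4)`` yields the streams
for, in order, fluorescence, leaf temperatures, lipidome and traits.  The
same seed and config therefore reproduce every table bit-identically, and
the tables are mutually independent given the config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import skewnorm

from .response import eq1

GroupKey = tuple[str, str]

#: default species codes (twelve tropical montane tree species)
DEFAULT_SPECIES = (
    "Afa", "Cgr", "Cme", "Eex", "Fsa", "Fth",
    "Hmo", "Mki", "Mla", "Mlu", "Pfu", "Sgu",
)
#: default site codes, high- to low-elevation
DEFAULT_SITES = ("HE", "ME", "LE")

#: the four thylakoid membrane lipid classes
LIPID_CLASSES = ("MGDG", "DGDG", "PG", "SQDG")

#: molecular species anchors (acyl carbons, double bonds) used to hit a
#: target class DBI by mixing a low- and a high-unsaturation species
_CLASS_ANCHORS: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "MGDG": ((36, 2), (36, 6)),
    "DGDG": ((36, 1), (36, 6)),
    "PG": ((34, 0), (34, 3)),
    "SQDG": ((34, 0), (36, 6)),
}

TRAIT_NAMES = (
    "leaf_area", "gs", "lma", "growth_temperature", "max_air_temperature",
    "osmolality",
)


@dataclass
class SimulationConfig:
    """Study design and generating truth for the synthetic campaign.

    ``true_thetas`` maps each (species, site) group to the decay-curve
    parameters (theta_a, theta_b, theta_c < 0).  ``leaf_temp_params`` maps
    each group to a skew-normal (location degC, scale degC, skew).
    ``dbi_params`` maps each lipid class to (intercept, slope per degC of
    true T50, noise SD).  ``trait_params`` maps each trait to (base, slope
    per degC of true-T50 anomaly, noise SD, lower bound, upper bound);
    growth and maximum air temperature instead come from the per-site maps.
    """

    species_labels: tuple[str, ...]
    site_labels: tuple[str, ...]
    true_thetas: dict[GroupKey, tuple[float, float, float]]
    leaf_temp_params: dict[GroupKey, tuple[float, float, float]]
    dbi_params: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    trait_params: dict[str, tuple[float, float, float, float, float]] = field(default_factory=dict)
    site_growth_temperature: dict[str, float] = field(default_factory=dict)
    site_max_air_temperature: dict[str, float] = field(default_factory=dict)
    target_temperatures: tuple[float, ...] = (34.0, 38.0, 42.0, 44.0, 46.0, 48.0, 50.0)
    leaves_per_temperature: int = 6
    control_fvfm_mean: float = 0.803
    control_fvfm_sd: float = 0.04
    control_fvfm_max: float = 0.87
    control_temperature: float = 22.5
    noise_sd: float = 0.03
    temperature_jitter: float = 1.0
    random_seed: int = 0

    def groups(self) -> list[GroupKey]:
        return [(sp, site) for sp in self.species_labels for site in self.site_labels]

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.leaves_per_temperature < 1:
            raise ValueError("leaves_per_temperature must be at least 1")
        if self.control_fvfm_sd < 0:
            raise ValueError("control_fvfm_sd must be non-negative")
        for key in self.groups():
            if key not in self.true_thetas:
                raise ValueError(f"missing true_thetas for group {key}")
            a, b, c = self.true_thetas[key]
            if not all(math.isfinite(v) for v in (a, b, c)):
                raise ValueError(f"non-finite theta for group {key}: {(a, b, c)}")
            if not (a > 0 and c < 0):
                raise ValueError(
                    f"group {key} violates theta_a > 0, theta_c < 0: {(a, b, c)}"
                )
        for cls, (icpt, slope, nsd) in self.dbi_params.items():
            if not (math.isfinite(icpt) and math.isfinite(slope)):
                raise ValueError(f"non-finite DBI intercept/slope for class {cls}")
            if nsd < 0:
                raise ValueError(f"negative DBI noise SD for class {cls}")

    def streams(self) -> dict[str, np.random.Generator]:
        """The four named random streams split from the global seed."""
        children = np.random.SeedSequence(self.random_seed).spawn(4)
        names = ("fluorescence", "leaf_temperature", "lipidome", "traits")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}

    # ---- generating truth -------------------------------------------------

    def true_t50(self, species: str, site: str) -> float:
        a, b, c = self.true_thetas[(species, site)]
        target = 0.5 * self.control_fvfm_mean
        return -(b + math.log(1.0 - target / a)) / c

    def true_t95(self, species: str, site: str) -> float:
        a, b, c = self.true_thetas[(species, site)]
        target = 0.05 * self.control_fvfm_mean
        return -(b + math.log(1.0 - target / a)) / c

    def true_tcrit(self, species: str, site: str, slope_fraction: float = 0.15) -> float:
        _, _, c = self.true_thetas[(species, site)]
        return max(self.target_temperatures) + math.log(slope_fraction) / abs(c)

    def true_thresholds(self) -> pd.DataFrame:
        rows = [
            {
                "species": sp, "site": site,
                "Tcrit": self.true_tcrit(sp, site),
                "T50": self.true_t50(sp, site),
                "T95": self.true_t95(sp, site),
            }
            for sp, site in self.groups()
        ]
        return pd.DataFrame(rows)


def thetas_from_thresholds(
    tcrit: float,
    t50: float,
    reference: float = 0.803,
    control_temperature: float = 22.5,
    domain_high: float = 50.0,
    slope_fraction: float = 0.15,
) -> tuple[float, float, float]:
    """Back-solve decay-curve parameters from target Tcrit and T50.

    The decay parameter follows from the Tcrit closed form over the domain
    ending at ``domain_high``; theta_a and theta_b are then solved so that
    the curve passes exactly through ``reference`` at the ambient control
    temperature and through ``reference/2`` at ``t50``.  With those two
    anchors the model is fully determined, so T95 is implied rather than
    free.
    """
    if not tcrit < domain_high:
        raise ValueError("tcrit must lie below the domain's upper edge")
    if not control_temperature < t50:
        raise ValueError("t50 must exceed the control temperature")
    c = math.log(slope_fraction) / (domain_high - tcrit)  # negative
    big_a = math.exp(-c * control_temperature)
    big_b = math.exp(-c * t50)
    theta_b = math.log(2.0 * big_b - big_a)
    theta_a = reference * (2.0 * big_b - big_a) / (2.0 * (big_b - big_a))
    return (theta_a, theta_b, c)


def skewnorm_upper_quartile_mean(skew: float, loc: float = 0.0, scale: float = 1.0) -> float:
    """Population mean of the upper quartile of a skew-normal distribution.

    Computed as ``4 * integral of ppf(q) over q in [0.75, 1]``; location and
    scale enter affinely.
    """
    val, _ = integrate.quad(lambda q: skewnorm.ppf(q, skew), 0.75, 1.0 - 1e-12)
    return loc + scale * 4.0 * val


def leaf_temp_location_for_uq_mean(
    target: float, scale: float, skew: float
) -> float:
    """Location parameter putting the skew-normal upper-quartile mean at ``target``."""
    return target - scale * skewnorm_upper_quartile_mean(skew)


# ---------------------------------------------------------------------------
# default study conditions


def default_config(random_seed: int = 0, noise_sd: float = 0.03) -> SimulationConfig:
    """Default synthetic study: 12 species x 3 sites along a warming gradient.

    Site-mean Tcrit (35.6/38.1/38.9 degC) and T50 (42.8/44.3/45.3 degC for
    the high-, mid- and low-elevation sites) anchor the generating curves;
    fixed, zero-centred species offsets spread T50 by about +/-2 degC and
    Tcrit by 1.8x that, reproducing the interspecific ranges of the
    campaign the generator emulates.  Leaf-temperature distributions are
    calibrated so the upper-quartile means give species-mean leaf-based
    thermal safety margins of about 9.3/4.6/1.4 degC per site, with the
    species offsets amplified at the warmest site so a handful of species
    exceed their T50 there.  Lipid-class DBI declines linearly with true
    T50 (no decline for PG); traits covary linearly with true T50.
    """
    species = DEFAULT_SPECIES
    sites = DEFAULT_SITES
    # zero-centred interspecific T50 offsets (degC)
    t50_offsets = {
        "Cme": 1.9, "Mlu": 1.3, "Fsa": 1.5, "Sgu": 1.4, "Afa": 0.3, "Eex": 0.2,
        "Cgr": -0.3, "Mki": -0.6, "Fth": -0.9, "Hmo": -1.0, "Mla": -1.6, "Pfu": -2.2,
    }
    site_t50 = {"HE": 42.8, "ME": 44.3, "LE": 45.3}
    site_tcrit = {"HE": 35.6, "ME": 38.1, "LE": 38.9}
    site_uq_leaf_temp = {"HE": 33.5, "ME": 39.7, "LE": 43.9}
    leaf_offset_gain = {"HE": 0.5, "ME": 0.7, "LE": 2.2}
    leaf_scale, leaf_skew = 3.0, 4.0

    thetas: dict[GroupKey, tuple[float, float, float]] = {}
    leaf_params: dict[GroupKey, tuple[float, float, float]] = {}
    m0 = skewnorm_upper_quartile_mean(leaf_skew)
    for sp in species:
        for site in sites:
            off = t50_offsets[sp]
            thetas[(sp, site)] = thetas_from_thresholds(
                tcrit=site_tcrit[site] + 1.8 * off,
                t50=site_t50[site] + off,
            )
            uq_target = site_uq_leaf_temp[site] + leaf_offset_gain[site] * off
            leaf_params[(sp, site)] = (
                uq_target - leaf_scale * m0, leaf_scale, leaf_skew,
            )

    dbi_params = {
        # intercepts put class DBI at realistic thylakoid values near the
        # grand-mean T50 (~44.1 degC); PG is flat across sites
        "MGDG": (10.32, -0.125, 0.08),
        "DGDG": (8.31, -0.10, 0.08),
        "PG": (1.60, 0.0, 0.10),
        "SQDG": (4.55, -0.06, 0.08),
    }
    trait_params = {
        # (base, slope per degC of T50 anomaly, noise SD, lower, upper)
        "leaf_area": (70.0, 28.0, 10.0, 5.0, 228.0),
        "gs": (0.22, -0.045, 0.015, 0.08, 0.40),
        "lma": (100.0, -8.0, 10.0, 65.0, 147.0),
        "osmolality": (550.0, 0.0, 50.0, 300.0, 900.0),
    }
    return SimulationConfig(
        species_labels=species,
        site_labels=sites,
        true_thetas=thetas,
        leaf_temp_params=leaf_params,
        dbi_params=dbi_params,
        trait_params=trait_params,
        site_growth_temperature={"HE": 17.5, "ME": 22.5, "LE": 23.8},
        site_max_air_temperature={"HE": 28.3, "ME": 31.7, "LE": 35.2},
        random_seed=random_seed,
        noise_sd=noise_sd,
    )


def shifted_config(config: SimulationConfig, delta_c: float) -> SimulationConfig:
    """Config whose every curve is shifted ``delta_c`` degC warmer.

    Implements the model's translation equivariance: theta_b absorbs the
    shift (theta_b' = theta_b - theta_c*delta), so all thresholds move by
    exactly ``delta_c``.  Used to construct a recovery-protocol arm whose
    thresholds sit a known distance above the direct-measurement arm.
    """
    thetas = {
        key: (a, b - c * delta_c, c) for key, (a, b, c) in config.true_thetas.items()
    }
    return replace(config, true_thetas=thetas)


# ---------------------------------------------------------------------------
# generators


def simulate_fluorescence_dataset(
    config: SimulationConfig, protocol: str = "direct"
) -> pd.DataFrame:
    """One row per heated leaf: measured leaf temperature, Fv/Fm, control Fv/Fm.

    Fv/Fm is the decay model evaluated at the measured temperature (target
    plus uniform jitter within +/- ``temperature_jitter``) with additive
    Gaussian noise truncated at zero.  Each leaf carries an ambient-control
    Fv/Fm drawn from a normal distribution truncated to
    (0, ``control_fvfm_max``].
    """
    config.validate()
    rng = config.streams()["fluorescence"]
    rows = []
    for sp, site in config.groups():
        a, b, c = config.true_thetas[(sp, site)]
        leaf_no = 0
        for target in config.target_temperatures:
            for _ in range(config.leaves_per_temperature):
                leaf_no += 1
                t_meas = target + rng.uniform(-1.0, 1.0) * config.temperature_jitter
                y = eq1(t_meas, a, b, c) + rng.normal(0.0, config.noise_sd)
                ctrl = rng.normal(config.control_fvfm_mean, config.control_fvfm_sd)
                while not (0.0 < ctrl <= config.control_fvfm_max):
                    ctrl = rng.normal(config.control_fvfm_mean, config.control_fvfm_sd)
                rows.append(
                    {
                        "species": sp, "site": site,
                        "leaf_id": f"{sp}-{site}-L{leaf_no:03d}",
                        "temperature": t_meas,
                        "fvfm": max(float(y), 0.0),
                        "control_fvfm": float(ctrl),
                        "protocol": protocol,
                    }
                )
    return pd.DataFrame(rows)


def simulate_leaf_temperatures(
    config: SimulationConfig, n_per_group: int = 60, campaign: str = "synthetic"
) -> pd.DataFrame:
    """Right-skewed midday leaf-temperature samples per species-site group."""
    config.validate()
    if n_per_group < 4:
        raise ValueError("n_per_group must be at least 4 (upper quartile undefined)")
    rng = config.streams()["leaf_temperature"]
    rows = []
    for sp, site in config.groups():
        loc, scale, skew = config.leaf_temp_params[(sp, site)]
        if scale > 0:
            vals = skewnorm.rvs(skew, loc=loc, scale=scale, size=n_per_group, random_state=rng)
        else:
            vals = np.full(n_per_group, loc)
        for v in vals:
            rows.append(
                {"species": sp, "site": site, "leaf_temperature": float(v),
                 "campaign": campaign}
            )
    return pd.DataFrame(rows)


def simulate_lipidome(config: SimulationConfig, total_abundance: float = 100.0) -> pd.DataFrame:
    """Lipid molecular-species table whose class DBI tracks the group's true T50.

    For each species-site group and lipid class, the target DBI is
    ``intercept + slope * true_T50`` plus Gaussian noise; the emitted table
    mixes the class's low- and high-unsaturation anchor species with
    abundances whose weighted mean double-bond count equals the target
    exactly (targets are clipped into the anchors' span).
    """
    config.validate()
    rng = config.streams()["lipidome"]
    rows = []
    for sp, site in config.groups():
        t50 = config.true_t50(sp, site)
        for cls in LIPID_CLASSES:
            if cls not in config.dbi_params:
                continue
            icpt, slope, nsd = config.dbi_params[cls]
            target = icpt + slope * t50 + (rng.normal(0.0, nsd) if nsd > 0 else 0.0)
            (c_lo, db_lo), (c_hi, db_hi) = _CLASS_ANCHORS[cls]
            target = float(np.clip(target, db_lo, db_hi))
            w_hi = (target - db_lo) / (db_hi - db_lo)
            for (carbons, bonds, frac) in (
                (c_lo, db_lo, 1.0 - w_hi), (c_hi, db_hi, w_hi),
            ):
                rows.append(
                    {
                        "species": sp, "site": site, "lipid_class": cls,
                        "acyl_carbons": carbons, "double_bonds": bonds,
                        "abundance": total_abundance * frac,
                    }
                )
    return pd.DataFrame(rows)


def simulate_traits(config: SimulationConfig) -> pd.DataFrame:
    """Species-site trait rows with configurable linear coupling to true T50.

    Trait values are ``base + slope * (true_T50 - grand mean T50) + noise``,
    clipped to the configured bounds; growth temperature and maximum air
    temperature are per-site constants from the config.
    """
    config.validate()
    rng = config.streams()["traits"]
    t50s = {key: config.true_t50(*key) for key in config.groups()}
    grand = float(np.mean(list(t50s.values())))
    rows = []
    for sp, site in config.groups():
        anomaly = t50s[(sp, site)] - grand
        row: dict[str, object] = {"species": sp, "site": site}
        for trait, (base, slope, nsd, lo, hi) in config.trait_params.items():
            val = base + slope * anomaly + (rng.normal(0.0, nsd) if nsd > 0 else 0.0)
            row[trait] = float(np.clip(val, lo, hi))
        row["growth_temperature"] = config.site_growth_temperature.get(site, np.nan)
        row["max_air_temperature"] = config.site_max_air_temperature.get(site, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_pulse_recovery(
    config: SimulationConfig,
    site: str = "ME",
    n_leaves: int = 6,
    direct_decline: float = 0.40,
    residual_declines: Mapping[float, float] | None = None,
    noise_sd: float = 0.03,
) -> pd.DataFrame:
    """Pulse-experiment table: Fv/Fm directly after a T50-magnitude heat pulse
    and after recovery intervals, relative to each leaf's pre-treatment control.

    Defaults emulate a 40% mean direct decline relaxing to a 14% residual
    decline after 4 h, with further recovery at 8/24/48 h.
    """
    if residual_declines is None:
        residual_declines = {4.0: 0.14, 8.0: 0.10, 24.0: 0.06, 48.0: 0.04}
    rng = np.random.default_rng(np.random.SeedSequence(config.random_seed).spawn(5)[4])
    rows = []
    for sp in config.species_labels:
        t50 = config.true_t50(sp, site)
        for leaf in range(1, n_leaves + 1):
            ctrl = rng.normal(config.control_fvfm_mean, config.control_fvfm_sd)
            while not (0.0 < ctrl <= config.control_fvfm_max):
                ctrl = rng.normal(config.control_fvfm_mean, config.control_fvfm_sd)
            arms = [("direct", 0.0, direct_decline)] + [
                ("recovered", h, d) for h, d in sorted(residual_declines.items())
            ]
            for protocol, hours, decline in arms:
                y = ctrl * (1.0 - decline) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append(
                    {
                        "species": sp, "site": site,
                        "leaf_id": f"{sp}-{site}-P{leaf:02d}",
                        "temperature": t50,
                        "fvfm": float(np.clip(y, 0.0, 1.0)),
                        "control_fvfm": float(ctrl),
                        "protocol": protocol,
                        "recovery_hours": hours,
                    }
                )
    return pd.DataFrame(rows)
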