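"""Synthetic common-garden provenance trial with known ground truth.

The generator emulates the design of the controlled-environment study
this package models: per species, 4 growth-chamber environments x 8
incomplete blocks x 90 seedlings (2880 seedlings), with 254 (spruce) or
281 (pine) seedlots sampled from ecologically structured origins, and
five traits (height, diameter, budbreak, budset, cold injury) generated
under the nested random-effects model

    Y = mu + P_i + E_j + (PxE)_ij + B(E)_jk + L(B)_kl + e

so every downstream stage (injury index, REML decomposition, trait
matrix, regression tree) can be tested against planted truth.

Seedlot origins are drawn around ecoregion archetypes of western Canada
(boreal plains, montane, sub-boreal plateau, interior wet mountains,
warm dry interior valleys).  Climate invariants hold by construction:
MWMT and MCMT are generated as positive offsets from MAT, TD is their
difference, degree-day variables are nonnegative monotone functions of
temperature, and summer precipitation is a fraction of annual.  The
population effect for each trait is piecewise-constant over planted
ecoregion groups plus a within-group climate slope plus an individual
deviation, with the three shares of the among-population variance
configurable.

Per-block "locations" are trays of :data:`POSITIONS_PER_LOCATION`
adjacent positions; a tray effect shared by a handful of seedlings is
what makes the location variance separable from the residual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLIMATE_VARS",
    "TRAITS",
    "SimulationTruth",
    "generate_origins",
    "generate_design",
    "simulate_observations",
    "simulate_freeze_batch",
    "default_variances",
]

CLIMATE_VARS = ["MAT", "MWMT", "MCMT", "TD", "DD5", "DD0", "MAP", "MSP"]
TRAITS = ["height", "diameter", "budbreak", "budset", "cold_injury"]

#: Seedlings per tray ("location" in the phenotypic model).
POSITIONS_PER_LOCATION = 6

#: Trait means: cm, mm, day of season, day of season, % injury.
TRAIT_MEANS = {"height": 25.0, "diameter": 4.0, "budbreak": 40.0, "budset": 120.0, "cold_injury": 50.0}

# Ecoregion archetypes: (name, MAT, warm offset, cold offset, MAP, elevation, latitude, longitude)
_ARCHETYPES = [
    ("boreal", -1.0, 17.0, 19.0, 450.0, 600.0, 58.0, -118.0),
    ("montane", 1.0, 11.0, 11.0, 900.0, 1700.0, 52.0, -117.0),
    ("subboreal", 3.0, 11.0, 11.0, 600.0, 900.0, 54.0, -123.0),
    ("wet_mountain", 5.0, 11.0, 11.0, 1100.0, 800.0, 51.0, -118.0),
    ("dry_valley", 8.0, 11.0, 11.0, 400.0, 500.0, 50.0, -120.0),
]


def default_variances(species: str = "spruce") -> dict[str, dict[str, float]]:
    """Per-trait variance magnitudes matching the published percent tables.

    Only ratios matter downstream, so the percent-scale components of the
    published study double as absolute magnitudes for the generator.
    """
    from genecol import reference

    table = reference.COMPONENTS[species]
    out = {}
    for trait in TRAITS:
        col = table[trait]
        out[trait] = {term: float(col[term]) for term in reference.TERMS}
    return out


@dataclass
class SimulationTruth:
    """Ground truth behind a synthetic provenance trial.

    Attributes
    ----------
    group_of : Series
        Planted ecoregion group per seedlot (a partition of the seedlots).
    variances : dict
        Per trait, the true magnitude of each model term
        (``population, environment, pop_env, block, location, residual``).
    population_effects : DataFrame
        The realized P_i per seedlot and trait (group effect + climate
        slope + individual deviation); its generative variance is the
        ``population`` entry of ``variances``.
    group_effects : DataFrame
        Piecewise-constant trait effect per planted group.
    climate_slopes : dict
        Per-trait slope on the standardized within-group MAT deviation.
    """

    seed: int
    group_of: pd.Series
    variances: dict[str, dict[str, float]]
    population_effects: pd.DataFrame
    group_effects: pd.DataFrame
    climate_slopes: dict[str, float]
    trait_means: dict[str, float] = field(default_factory=lambda: dict(TRAIT_MEANS))
    positions_per_location: int = POSITIONS_PER_LOCATION

    def __post_init__(self):
        if any(v < 0 for trait in self.variances.values() for v in trait.values()):
            raise ValueError("variance magnitudes must be nonnegative")

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "group_of": {k: int(v) for k, v in self.group_of.items()},
            "variances": self.variances,
            "population_effects": {
                "index": list(self.population_effects.index),
                "columns": list(self.population_effects.columns),
                "data": self.population_effects.to_numpy().tolist(),
            },
            "group_effects": {
                "index": [int(i) for i in self.group_effects.index],
                "columns": list(self.group_effects.columns),
                "data": self.group_effects.to_numpy().tolist(),
            },
            "climate_slopes": self.climate_slopes,
            "trait_means": self.trait_means,
            "positions_per_location": self.positions_per_location,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        d = json.loads(text)
        return cls(
            seed=d["seed"],
            group_of=pd.Series(d["group_of"]),
            variances=d["variances"],
            population_effects=pd.DataFrame(
                d["population_effects"]["data"],
                index=d["population_effects"]["index"],
                columns=d["population_effects"]["columns"],
            ),
            group_effects=pd.DataFrame(
                d["group_effects"]["data"],
                index=d["group_effects"]["index"],
                columns=d["group_effects"]["columns"],
            ),
            climate_slopes=d["climate_slopes"],
            trait_means=d["trait_means"],
            positions_per_location=d["positions_per_location"],
        )


def _chunk_sizes(total: int, low: int, high: int, rng: np.random.Generator) -> list[int]:
    """Partition `total` into chunks of size low..high (last may be smaller)."""
    sizes = []
    left = total
    while left > 0:
        s = int(rng.integers(low, high + 1))
        sizes.append(min(s, left))
        left -= sizes[-1]
    return sizes


def generate_origins(
    n_seedlots: int,
    n_groups: int,
    seed: int,
    species: str = "spruce",
    separation: float = 1.0,
    variances: dict[str, dict[str, float]] | None = None,
    between_group_fraction: float = 0.65,
    slope_fraction: float = 0.20,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Seedlot origin table with climate/ecosystem structure, plus truth.

    Parameters
    ----------
    n_seedlots, n_groups : int
        Seedlots to generate and number of planted ecoregion groups
        (254 and 5 emulate the spruce study; 281 for pine).
    seed : int
        Seed for all randomness.
    species : {"spruce", "pine"}
    separation : float
        Multiplier on the between-group climate spread; 1.0 is the
        realistic western-Canada default, larger values make groups
        trivially separable (useful for recovery oracles).
    variances : dict, optional
        Per-trait model-term magnitudes; defaults to the published
        percent tables for the species (:func:`default_variances`).
    between_group_fraction, slope_fraction : float
        Shares of the among-population variance carried by the
        piecewise-constant group effects and by the within-group climate
        slope; the remainder is individual seedlot deviation.

    Returns
    -------
    (origins, truth)
        ``origins`` has one row per seedlot with geography, the eight
        climate normals, ``ecosystem_variant`` and ``ecozone``;
        ``truth`` is the matching :class:`SimulationTruth`.

    Notes
    -----
    Every ecosystem variant holds 2-6 seedlots (the sampling density of
    the original study), variants nest in ecozones and ecozones in the
    planted groups, so the categorical predictors are consistent with
    the latent group structure by construction.
    """
    if n_seedlots < 1 or n_groups < 1:
        raise ValueError("n_seedlots and n_groups must be positive")
    if n_seedlots < n_groups:
        raise ValueError("need at least one seedlot per group")
    if species not in ("spruce", "pine"):
        raise ValueError(f"unknown species {species!r}")
    if not 0 <= between_group_fraction + slope_fraction <= 1:
        raise ValueError("variance fractions must sum to at most 1")
    rng = np.random.default_rng(seed)
    variances = variances if variances is not None else default_variances(species)

    base = n_seedlots // n_groups
    sizes = np.full(n_groups, base)
    sizes[: n_seedlots - base * n_groups] += 1

    rows = []
    group_of = {}
    mat_dev = {}
    sid = 0
    for g in range(n_groups):
        arch = _ARCHETYPES[g % len(_ARCHETYPES)]
        _, mat0, warm0, cold0, map0, elev0, lat0, lon0 = arch
        jitter = (g // len(_ARCHETYPES)) * 1.5  # extra groups beyond 5: shifted copies
        mat0 = mat0 * separation + jitter
        variant_sizes = _chunk_sizes(int(sizes[g]), 2, 6, rng)
        variant_labels = []
        for vi, vs in enumerate(variant_sizes):
            variant_labels += [f"V{g + 1}.{vi // 3 + 1}.{vi % 3 + 1}"] * vs
        for j in range(int(sizes[g])):
            mat = mat0 + rng.normal(0, 0.8)
            warm = max(warm0 + rng.normal(0, 0.8), 1.0)
            cold = max(cold0 * separation + rng.normal(0, 1.0), 1.0)
            mwmt = mat + warm
            mcmt = mat - cold
            dd5 = max(0.0, 180.0 * (mat + 3.0) + rng.normal(0, 60.0))
            dd0 = max(0.0, 85.0 * (-mcmt) - 150.0 + rng.normal(0, 50.0))
            annual = float(map0 * np.exp(rng.normal(0, 0.15)))
            variant = variant_labels[j]
            ecozone = variant.rsplit(".", 1)[0].replace("V", "Z", 1)
            rows.append(
                {
                    "seedlot_id": f"S{sid:04d}",
                    "species": species,
                    "latitude": lat0 + rng.normal(0, 0.8),
                    "longitude": lon0 + rng.normal(0, 1.5),
                    "elevation": max(elev0 + rng.normal(0, 120.0), 0.0),
                    "MAT": mat,
                    "MWMT": mwmt,
                    "MCMT": mcmt,
                    "TD": mwmt - mcmt,
                    "DD5": dd5,
                    "DD0": dd0,
                    "MAP": annual,
                    "MSP": annual * float(rng.uniform(0.30, 0.55)),
                    "ecosystem_variant": variant,
                    "ecozone": ecozone,
                }
            )
            group_of[f"S{sid:04d}"] = g
            mat_dev[f"S{sid:04d}"] = mat - mat0
            sid += 1
    origins = pd.DataFrame(rows)

    # population effects: group step + within-group climate slope + individual
    group_of = pd.Series(group_of, name="group")
    dev = pd.Series(mat_dev).reindex(group_of.index)
    sd_dev = dev.groupby(group_of).transform(
        lambda s: s.std(ddof=0) if s.std(ddof=0) > 0 else 1.0
    )
    z = (dev / sd_dev).to_numpy()
    group_effects = {}
    pop_effects = {}
    slopes = {}
    for trait in TRAITS:
        s2p = variances[trait]["population"]
        # With G planted groups the across-population variance of the group
        # part has expectation tau2*(G-1)/G, so the group-effect variance
        # carries the G/(G-1) factor to make the marginal among-population
        # variance equal s2p.  With a single group the share moves to the
        # individual deviation.
        if n_groups > 1:
            tau2 = between_group_fraction * s2p * n_groups / (n_groups - 1)
            indiv_frac = max(1 - between_group_fraction - slope_fraction, 0)
        else:
            tau2 = 0.0
            indiv_frac = max(1 - slope_fraction, 0)
        ge = rng.normal(0, np.sqrt(tau2), n_groups)
        slope = float(np.sqrt(slope_fraction * s2p)) * (1 if rng.random() < 0.5 else -1)
        indiv = rng.normal(0, np.sqrt(indiv_frac * s2p), n_seedlots)
        group_effects[trait] = ge
        slopes[trait] = slope
        pop_effects[trait] = ge[group_of.to_numpy()] + slope * z + indiv
    truth = SimulationTruth(
        seed=seed,
        group_of=group_of,
        variances=variances,
        population_effects=pd.DataFrame(pop_effects, index=group_of.index),
        group_effects=pd.DataFrame(group_effects, index=pd.RangeIndex(n_groups)),
        climate_slopes=slopes,
    )
    return origins, truth


def generate_design(
    seedlots: pd.DataFrame,
    n_chambers: int = 4,
    blocks_per_chamber: int = 8,
    block_size: int = 90,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomized incomplete-block layout with even seedlot replication.

    Each chamber holds ``blocks_per_chamber * block_size`` seedlings.
    Chamber capacity is allocated as evenly as possible over seedlots
    (floor/ceil of capacity over the number of seedlots, the extra
    replicate going to a random subset per chamber), then shuffled into
    blocks.  This randomized allocator stands in for a formal resolvable
    alpha-design construction; downstream models treat block as an
    unstructured random label, for which even replication is what
    matters.

    Returns a DataFrame with ``chamber_id, block_id, position, seedlot_id``
    and exactly ``n_chambers * blocks_per_chamber * block_size`` rows.
    """
    ids = seedlots["seedlot_id"].to_numpy()
    n = len(ids)
    capacity = blocks_per_chamber * block_size
    if capacity < 2 * n:
        raise ValueError(
            f"chamber capacity {capacity} cannot hold 2 replicates of {n} seedlots"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_chambers):
        reps = np.full(n, capacity // n)
        extra = rng.choice(n, capacity - reps.sum(), replace=False)
        reps[extra] += 1
        pool = np.repeat(np.arange(n), reps)
        rng.shuffle(pool)
        for b in range(blocks_per_chamber):
            blockmates = pool[b * block_size : (b + 1) * block_size]
            for pos, idx in enumerate(blockmates, start=1):
                rows.append((f"C{c + 1}", f"B{b + 1}", pos, ids[idx]))
    return pd.DataFrame(rows, columns=["chamber_id", "block_id", "position", "seedlot_id"])


def simulate_observations(
    layout: pd.DataFrame,
    origins: pd.DataFrame,
    truth: SimulationTruth,
    seed: int = 0,
) -> pd.DataFrame:
    """Five seedling traits under the nested random-effects model.

    Each trait is the sum mu + P + E + PxE + B(E) + L(B) + e with the
    population effect taken from ``truth.population_effects`` and every
    other term drawn independently at the magnitudes in
    ``truth.variances``.  Locations are trays of
    ``truth.positions_per_location`` adjacent block positions.

    Returns the layout plus ``location_id`` and one column per trait.
    """
    unknown = set(layout["seedlot_id"]) - set(origins["seedlot_id"])
    if unknown:
        raise ValueError(f"layout references unknown seedlots: {sorted(unknown)[:5]}")
    missing_truth = set(layout["seedlot_id"]) - set(truth.population_effects.index)
    if missing_truth:
        raise ValueError(
            f"truth has no population effects for: {sorted(missing_truth)[:5]}"
        )
    rng = np.random.default_rng(seed)
    obs = layout.copy()
    obs["location_id"] = "L" + (
        (obs["position"] - 1) // truth.positions_per_location + 1
    ).astype(str)

    chambers = obs["chamber_id"].unique()
    blk_key = obs["chamber_id"] + "/" + obs["block_id"]
    loc_key = blk_key + "/" + obs["location_id"]
    pe_key = obs["seedlot_id"] + "/" + obs["chamber_id"]
    ub, ul, upe = blk_key.unique(), loc_key.unique(), pe_key.unique()

    for trait in TRAITS:
        v = truth.variances[trait]
        e_eff = dict(zip(chambers, rng.normal(0, np.sqrt(v["environment"]), len(chambers))))
        pe_eff = dict(zip(upe, rng.normal(0, np.sqrt(v["pop_env"]), len(upe))))
        b_eff = dict(zip(ub, rng.normal(0, np.sqrt(v["block"]), len(ub))))
        l_eff = dict(zip(ul, rng.normal(0, np.sqrt(v["location"]), len(ul))))
        obs[trait] = (
            truth.trait_means[trait]
            + truth.population_effects[trait].reindex(obs["seedlot_id"]).to_numpy()
            + obs["chamber_id"].map(e_eff).to_numpy()
            + pe_key.map(pe_eff).to_numpy()
            + blk_key.map(b_eff).to_numpy()
            + loc_key.map(l_eff).to_numpy()
            + rng.normal(0, np.sqrt(v["residual"]), len(obs))
        )
    return obs


def simulate_freeze_batch(
    observations: pd.DataFrame,
    temperatures: Sequence[float],
    seed: int = 0,
    noise: float = 0.0,
    logistic_scale: float = 2.0,
    reference_temperature: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Electrolyte-leakage samples consistent with each seedling's cold injury.

    Each seedling's latent injury follows a logistic curve in freeze
    temperature, anchored so that at the reference temperature (default:
    the median of ``temperatures``) the injury equals the seedling's
    ``cold_injury`` trait.  Conductances are then emitted so that the
    injury-index formula recovers the latent injury exactly when
    ``noise`` is 0; positive ``noise`` perturbs ``Lt`` multiplicatively
    (lognormal sigma = ``noise``).  A monotone sigmoid is all the latent
    curve needs to be; the logistic is chosen because it inverts in
    closed form.

    One control batch is emitted per chamber x temperature.

    Returns
    -------
    (samples, controls)
        ``samples``: ``sample_id, seedlot_id, chamber_id, batch_id,
        test_temperature, Lt, Lk, latent_injury``; ``controls``:
        ``batch_id, L0, Ld``.
    """
    temperatures = [float(t) for t in temperatures]
    if len(temperatures) < 1:
        raise ValueError("need at least one freeze temperature")
    if noise < 0:
        raise ValueError("conductance noise must be nonnegative")
    t_ref = (
        float(np.median(temperatures))
        if reference_temperature is None
        else float(reference_temperature)
    )
    rng = np.random.default_rng(seed)
    eps = 1e-9
    c = np.clip(observations["cold_injury"].to_numpy(float), 100 * eps, 100 * (1 - eps))
    # T50 such that injury(t_ref) equals the trait; injury rises as T drops
    t50 = t_ref + logistic_scale * np.log(c / (100.0 - c))

    samples = []
    controls = []
    l0, ld = 10.0, 50.0
    r0 = l0 / ld
    for t in temperatures:
        inj = 100.0 / (1.0 + np.exp((t - t50) / logistic_scale))
        for ch in observations["chamber_id"].unique():
            controls.append({"batch_id": f"{ch}@{t:g}", "L0": l0, "Ld": ld})
        lk = np.full(len(c), 60.0)
        rt = r0 + (inj / 100.0) * (1.0 - r0)
        lt = rt * lk
        if noise > 0:
            lt = np.minimum(lt * np.exp(rng.normal(0, noise, len(lt))), lk)
        df = observations[["seedlot_id", "chamber_id"]].copy()
        df["batch_id"] = df["chamber_id"] + "@" + f"{t:g}"
        df["test_temperature"] = t
        df["Lt"] = lt
        df["Lk"] = lk
        df["latent_injury"] = inj
        samples.append(df)
    out = pd.concat(samples, ignore_index=True)
    out.insert(0, "sample_id", [f"F{i:05d}" for i in range(len(out))])
    return out, pd.DataFrame(controls).drop_duplicates("batch_id").reset_index(drop=True)
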