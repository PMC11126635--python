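"""Seeded virtual-ecosystem generator with ground-truth oracles.

The generator emulates the statistical structure the modelling framework
assumes about opportunistic plant records:

* species with unimodal (Gaussian) niches along each environmental layer,
* seasonally unimodal observation activity whose peak day shifts linearly
  with elevation (a phenological lapse),
* spatial accessibility bias shared across species (recording intensity
  decays with distance to a few "roads"),
* per-species taxonomic reporting bias (a positive reporting rate rho),
* plot surveys recording relative cover-abundance.

Records are drawn as an exact categorical sample over the (species,
pixel, day) lattice with intensity

    Lambda_s(x, t) = suit_s(x) * act_s(x, t) * access(x) * rho_s,

where suit is the product-Gaussian niche, act is a Gaussian activity
curve centred on tau_s(x) = tau0_s + lapse_s * elev(x) / 100, and access
is the shared accessibility field. Every quantity a downstream stage is
supposed to recover (true suitability, true peak day, true dominant
species) is available as a closed-form oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import PredictorGrid
from .observations import ObservationTable
from .surveys import SurveyTable

__all__ = [
    "VirtualLandscape",
    "VirtualSpecies",
    "SyntheticBundle",
    "generate_landscape",
    "generate_species",
    "simulate_observations",
    "simulate_surveys",
    "suitability_maps",
    "conditional_probability_cube",
    "truth_peak",
    "truth_cover",
    "truth_dominant",
    "make_demo_bundle",
]

YEAR_DAYS = 365
DAYS = np.arange(1, YEAR_DAYS + 1, dtype=float)

#: landcover code used for the wooded mask in synthetic grids
WOODED_CODE = 1


def _smooth2d(a: np.ndarray, window: int) -> np.ndarray:
    """Separable moving-average smoothing with edge replication."""
    if window <= 1:
        return a
    k = np.ones(window) / window
    pad = window // 2
    for axis in (0, 1):
        a = np.apply_along_axis(
            lambda v: np.convolve(
                np.pad(v, pad, mode="edge"), k, mode="same"
            )[pad:-pad],
            axis,
            a,
        )
    return a


@dataclass
class VirtualLandscape:
    """Predictor layers plus the sampling fields of the virtual ecosystem."""

    grid: PredictorGrid  # raw (unscaled) environmental layers
    accessibility: np.ndarray  # in (0, 1], shape (rows, cols)
    wooded: np.ndarray  # boolean mask, shape (rows, cols)

    @property
    def elevation(self) -> np.ndarray:
        return self.grid.layer("elevation")

    @property
    def shape(self) -> tuple:
        return self.grid.shape


@dataclass
class VirtualSpecies:
    """Niche, phenology, and reporting parameters of one virtual species.

    ``floor`` is a small year-round base recording rate added to the
    seasonal activity bump: plants are occasionally reported outside
    their main activity period, and without this floor the off-season
    conditional observation probabilities would be ratios of vanishing
    quantities — a degenerate regime real communities do not show.
    """

    name: str
    mu: np.ndarray  # niche centre per predictor (raw units)
    sigma: np.ndarray  # niche breadth per predictor, > 0
    tau0: float  # base activity peak (day of year)
    lapse: float  # peak delay in days per 100 elevation units
    omega: float  # activity width in days, > 0
    rho: float  # reporting rate, > 0
    gamma: float  # abundance exponent used by cover surveys
    floor: float = 0.05  # year-round base activity in (0, 1)

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0) or self.omega <= 0 or self.rho <= 0:
            raise ValueError("sigma, omega, rho must be positive")
        if not 0.0 <= self.floor < 1.0:
            raise ValueError("floor must lie in [0, 1)")


def generate_landscape(
    size: int = 64, n_predictors: int = 3, seed: int = 0
) -> VirtualLandscape:
    """Build a deterministic virtual landscape.

    Elevation rises monotonically along the row axis (0 to 1000 units)
    with smooth correlated noise on top; the remaining predictors are
    smoothed random fields; accessibility decays with distance from a few
    seeded road lines and is strictly positive everywhere.
    """
    if size < 8:
        raise ValueError("size must be >= 8")
    if n_predictors < 1:
        raise ValueError("need at least one predictor (elevation)")
    rng = np.random.default_rng(seed)
    rows = np.arange(size, dtype=float)
    window = max(3, size // 8)

    elevation = np.tile(rows[:, None] * (1000.0 / (size - 1)), (1, size))
    elevation += 100.0 * _smooth2d(rng.standard_normal((size, size)), window)

    layers = [elevation]
    names = ["elevation"]
    for i in range(n_predictors - 1):
        f = _smooth2d(rng.standard_normal((size, size)), window)
        f = (f - f.min()) / (f.max() - f.min() + 1e-12)
        layers.append(f)
        names.append(f"env{i + 1}")

    # roads: straight lines at random rows/cols
    road = np.zeros((size, size), dtype=bool)
    for _ in range(3):
        pos = rng.integers(0, size)
        if rng.random() < 0.5:
            road[pos, :] = True
        else:
            road[:, pos] = True
    rr, cc = np.nonzero(road)
    gr, gc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    d2 = (gr[..., None] - rr) ** 2 + (gc[..., None] - cc) ** 2
    dist = np.sqrt(d2.min(axis=-1))
    accessibility = np.maximum(np.exp(-dist / (size / 8.0)), 0.02)

    # wooded where below the treeline and the noise field is favourable
    wood_field = _smooth2d(rng.standard_normal((size, size)), window)
    wooded = (elevation < 820.0) & (wood_field > np.quantile(wood_field, 0.25))
    landcover = np.where(wooded, WOODED_CODE, 0)

    grid = PredictorGrid(
        names=names,
        values=np.stack(layers),
        cell_size=1.0,
        origin=(0.0, 0.0),
        landcover=landcover,
    )
    return VirtualLandscape(grid=grid, accessibility=accessibility, wooded=wooded)


def generate_species(
    landscape: VirtualLandscape,
    n_species: int = 30,
    seed: int = 0,
    rho_range: tuple = (0.1, 1.0),
    lapse_range: tuple = (1.0, 4.0),
    omega_range: tuple = (10.0, 16.0),
    tau0_range: tuple = (80.0, 230.0),
    sigma_elev_range: tuple = (0.30, 0.50),
    sigma_other_range: tuple = (0.15, 0.30),
    gamma: float = 1.0,
    activity_floor: float = 0.05,
) -> list:
    """Draw a deterministic community of virtual species.

    Reporting rates are log-uniform over ``rho_range`` (the default spans
    a 10x spread, i.e. strong taxonomic reporting bias). Niche breadths
    are fractions of each predictor's observed range: broad along the
    elevation gradient (species span enough relief to express their
    phenological lapse) and narrower along the other axes (species
    segregate edaphically). Base peak days spread widely so community
    recording activity is not concentrated in one short season, and every
    species keeps a small year-round base activity ``activity_floor``.
    All species share the abundance exponent ``gamma`` (cover
    proportional to relative suitability by default).
    """
    rng = np.random.default_rng(seed)
    flat = landscape.grid.flat_features()
    lo, hi = flat.min(axis=0), flat.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    species = []
    for i in range(n_species):
        mu = lo + rng.uniform(0.1, 0.9, size=len(lo)) * span
        sigma = np.empty(len(lo))
        sigma[0] = rng.uniform(*sigma_elev_range) * span[0]
        sigma[1:] = rng.uniform(*sigma_other_range, size=len(lo) - 1) * span[1:]
        species.append(
            VirtualSpecies(
                name=f"sp{i:03d}",
                mu=mu,
                sigma=sigma,
                tau0=rng.uniform(*tau0_range),
                lapse=rng.uniform(*lapse_range),
                omega=rng.uniform(*omega_range),
                rho=float(np.exp(rng.uniform(*np.log(rho_range)))),
                gamma=gamma,
                floor=activity_floor,
            )
        )
    return species


def suitability_maps(
    landscape: VirtualLandscape, species: list
) -> np.ndarray:
    """(n_species, rows, cols) product-Gaussian suitability, in (0, 1]."""
    feats = landscape.grid.values  # (L, R, C)
    out = np.empty((len(species),) + landscape.shape)
    for k, sp in enumerate(species):
        z = (feats - sp.mu[:, None, None]) / sp.sigma[:, None, None]
        out[k] = np.exp(-0.5 * np.sum(z**2, axis=0))
    return out


def truth_peak(landscape: VirtualLandscape, sp: VirtualSpecies) -> np.ndarray:
    """True activity-peak day tau_s(x) = tau0 + lapse * elevation / 100."""
    return sp.tau0 + sp.lapse * landscape.elevation / 100.0


def truth_cover(landscape: VirtualLandscape, species: list) -> np.ndarray:
    """(n_species, rows, cols) relative cover in percent (sums to 100)."""
    suit = suitability_maps(landscape, species)
    powered = np.stack(
        [suit[k] ** sp.gamma for k, sp in enumerate(species)]
    )
    total = powered.sum(axis=0)
    return 100.0 * powered / np.maximum(total, 1e-300)


def truth_dominant(landscape: VirtualLandscape, species: list) -> np.ndarray:
    """Index of the species with highest true cover, ties to lowest index."""
    return np.argmax(truth_cover(landscape, species), axis=0)


def _activity(
    tau: np.ndarray, omega: float, floor: float = 0.0, days: np.ndarray = DAYS
) -> np.ndarray:
    """(pixels, days) seasonal activity for per-pixel peak days ``tau``.

    A Gaussian bump of width ``omega`` on top of a year-round base rate
    ``floor``: act = floor + (1 - floor) * exp(-(t - tau)^2 / (2 omega^2)).
    """
    bump = np.exp(-0.5 * ((days[None, :] - tau[:, None]) / omega) ** 2)
    return floor + (1.0 - floor) * bump


def simulate_observations(
    landscape: VirtualLandscape,
    species: list,
    n_obs: int = 100_000,
    seed: int = 0,
    year_range: tuple = (2000, 2020),
    bloom_fraction_of_omega: float = 0.5,
) -> ObservationTable:
    """Draw presence-only records from the space-time intensity field.

    The (species, pixel) margin is drawn exactly from the categorical
    distribution with weights suit * access * rho * sum_t act; the day is
    then drawn from the per-record conditional over days. Records within
    ``bloom_fraction_of_omega * omega`` days of the local activity peak
    are tagged with phenology_state "full bloom".
    """
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    rng = np.random.default_rng(seed)
    n_sp = len(species)
    n_pix = landscape.shape[0] * landscape.shape[1]
    suit = suitability_maps(landscape, species).reshape(n_sp, n_pix)
    access = landscape.accessibility.reshape(n_pix)
    elev = landscape.elevation.reshape(n_pix)

    # per-(species, pixel) marginal intensity
    weights = np.empty((n_sp, n_pix))
    taus = np.empty((n_sp, n_pix))
    for k, sp in enumerate(species):
        taus[k] = sp.tau0 + sp.lapse * elev / 100.0
        # closed-form day sum of the discretized activity curve
        act_sum = _activity(taus[k], sp.omega, sp.floor).sum(axis=1)
        weights[k] = suit[k] * access * sp.rho * act_sum
    total = weights.sum()
    if total <= 0:
        raise ValueError("all-zero observation intensity")
    p = (weights / total).reshape(-1)

    draw = rng.choice(n_sp * n_pix, size=n_obs, replace=True, p=p)
    sp_idx, pix_idx = np.divmod(draw, n_pix)

    # conditional day draw, chunked to bound memory
    doy = np.empty(n_obs, dtype=float)
    u = rng.random(n_obs)
    for k, sp in enumerate(species):
        sel = np.flatnonzero(sp_idx == k)
        for start in range(0, len(sel), 8192):
            part = sel[start : start + 8192]
            act = _activity(taus[k, pix_idx[part]], sp.omega, sp.floor)
            cdf = np.cumsum(act, axis=1)
            cdf /= cdf[:, -1:]
            pos = (cdf < u[part, None]).sum(axis=1)
            doy[part] = DAYS[np.minimum(pos, YEAR_DAYS - 1)]

    rows, cols = np.divmod(pix_idx, landscape.shape[1])
    x, y = landscape.grid.pixel_center(rows, cols)
    tau_rec = taus[sp_idx, pix_idx]
    omega_rec = np.array([species[k].omega for k in sp_idx])
    bloom = np.abs(doy - tau_rec) <= bloom_fraction_of_omega * omega_rec

    df = pd.DataFrame(
        {
            "taxon": [species[k].name for k in sp_idx],
            "x": x,
            "y": y,
            "doy": doy,
            "year": rng.integers(year_range[0], year_range[1] + 1, size=n_obs),
            "coord_uncertainty": 0.0,
            "phenology_state": np.where(bloom, "full bloom", None),
        }
    )
    return ObservationTable(df)


def simulate_surveys(
    landscape: VirtualLandscape,
    species: list,
    n_sites: int = 300,
    seed: int = 0,
    discretize: bool = False,
) -> SurveyTable:
    """Sample plot surveys of relative cover over the wooded mask.

    Per site, cover_s = suit_s^gamma / sum suit^gamma * 100 (rows sum to
    100); with ``discretize`` the percentages are passed through the
    Braun-Blanquet classes and back to midpoints, emulating the coarse
    field scale.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    wooded_flat = np.flatnonzero(landscape.wooded.reshape(-1))
    if len(wooded_flat) == 0:
        raise ValueError("landscape has no wooded pixels")
    pick = rng.choice(wooded_flat, size=n_sites, replace=n_sites > len(wooded_flat))
    rows, cols = np.divmod(pick, landscape.shape[1])
    x, y = landscape.grid.pixel_center(rows, cols)

    cover_maps = truth_cover(landscape, species).reshape(len(species), -1)
    cover = cover_maps[:, pick].T  # (sites, species)
    if discretize:
        from .surveys import DEFAULT_COVER_TRANSLATION

        bounds = [0.25, 1.0, 5.0, 25.0, 50.0, 75.0]  # class upper edges
        mids = list(DEFAULT_COVER_TRANSLATION.values())
        idx = np.searchsorted(bounds, cover)
        cover = np.where(cover <= 0, 0.0, np.asarray(mids)[idx])

    sites = pd.DataFrame(
        {"site": [f"site{i:04d}" for i in range(n_sites)], "x": x, "y": y}
    )
    cov = pd.DataFrame(
        cover, index=pd.Index(sites["site"]), columns=[sp.name for sp in species]
    )
    return SurveyTable(sites=sites, cover=cov)


def conditional_probability_cube(
    landscape: VirtualLandscape, species: list, days
):
    """Closed-form true conditional observation probabilities.

    The exact P(species | record at pixel, day) implied by the
    generator's intensity model — softmax-free oracle for what a
    perfectly fitted model would predict. The shared accessibility field
    cancels in the conditional and so does not appear. Returns a
    :class:`multisdm.inference.PredictionCube`.
    """
    from .inference import PredictionCube

    days = np.atleast_1d(np.asarray(days, dtype=float))
    n_sp = len(species)
    n_pix = landscape.shape[0] * landscape.shape[1]
    suit = suitability_maps(landscape, species).reshape(n_sp, n_pix)
    elev = landscape.elevation.reshape(n_pix)
    probs = np.empty((n_sp, len(days), n_pix))
    for k, sp in enumerate(species):
        tau = sp.tau0 + sp.lapse * elev / 100.0
        act = _activity(tau, sp.omega, sp.floor, days=days)  # (pix, days)
        probs[k] = (suit[k][:, None] * act * sp.rho).T
    probs /= probs.sum(axis=0, keepdims=True)
    return PredictionCube(
        probs=probs,
        taxa=[sp.name for sp in species],
        days=days,
        pixel_index=np.arange(n_pix),
        grid_shape=landscape.shape,
        cell_size=landscape.grid.cell_size,
        origin=landscape.grid.origin,
    )


@dataclass
class SyntheticBundle:
    """One fully specified virtual study: data plus ground truth."""

    landscape: VirtualLandscape
    species: list
    observations: ObservationTable
    surveys: SurveyTable
    seed: int

    @property
    def taxa(self) -> list:
        return [sp.name for sp in self.species]

    def truth_peak_map(self, taxon: str) -> np.ndarray:
        sp = self.species[self.taxa.index(taxon)]
        return truth_peak(self.landscape, sp)

    def truth_dominant_map(self) -> np.ndarray:
        return truth_dominant(self.landscape, self.species)


def make_demo_bundle(
    seed: int = 42,
    n_species: int = 30,
    size: int = 64,
    n_predictors: int = 3,
    n_obs: int = 100_000,
    n_sites: int = 300,
    **species_kwargs,
) -> SyntheticBundle:
    """The default virtual study: 30 species on a 64x64 grid with 3
    predictors, an elevational phenology lapse of 1-4 days per 100
    elevation units, 100,000 observations and 300 survey sites."""
    ss = np.random.SeedSequence(seed)
    s_land, s_sp, s_obs, s_srv = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    )
    landscape = generate_landscape(size=size, n_predictors=n_predictors, seed=s_land)
    species = generate_species(
        landscape, n_species=n_species, seed=s_sp, **species_kwargs
    )
    obs = simulate_observations(landscape, species, n_obs=n_obs, seed=s_obs)
    surveys = simulate_surveys(landscape, species, n_sites=n_sites, seed=s_srv)
    return SyntheticBundle(
        landscape=landscape,
        species=species,
        observations=obs,
        surveys=surveys,
        seed=seed,
    )
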