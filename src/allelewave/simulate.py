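"""Synthetic data generation: surface sampling designs and a spatially
explicit individual-based forward simulator.

Two routes produce validation datasets:

* deterministic-surface sampling — genotypes drawn Binomial(2, p(x, y, t))
  at designed locations/ages, with optional pseudohaploidisation;
* an individual-based forward simulation of a beneficial additive allele on
  the landscape, with local mate choice, Gaussian offspring dispersal and
  local logistic population regulation (an emulation of spatial competition,
  lightly corrected globally to hold the census size near its target).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .landscape import Landscape, locate
from .likelihood import Dataset, Observation
from .pde import FrequencySurface, frequency_at

__all__ = [
    "SamplingDesign",
    "ForwardSimParams",
    "AlleleLostError",
    "pseudohaploidize",
    "design_locations",
    "sample_from_surface",
    "forward_simulate",
    "subsample_individuals",
]

_KM_PER_DEG = 111.19493  # meridian degree on the R=6371 km sphere

SPATIAL_SCHEMES = ("homogeneous", "intermediate", "extreme")
# fraction of each bbox axis retained under the clustered sampling schemes
_SCHEME_FRACTION = {"homogeneous": 1.0, "intermediate": 0.5, "extreme": 0.15}


class AlleleLostError(RuntimeError):
    """Raised when the tracked allele is lost during a forward simulation."""

    def __init__(self, generation: int):
        super().__init__(f"allele lost at generation {generation}")
        self.generation = generation


@dataclass
class SamplingDesign:
    """Where, when and how to draw samples from a frequency surface."""

    n_samples: int
    spatial_scheme: str = "homogeneous"  # or explicit region via `region`
    temporal_split: float = 0.5  # fraction of samples older than the boundary
    age_distribution: str = "log-uniform"  # or "matched-to-table"
    mode: str = "pseudohaploid"  # or "diploid"
    seed: int = 0
    age_min_years_bp: float = 0.0
    age_max_years_bp: float | None = None
    region: tuple[float, float, float, float] | None = None  # lat0,lat1,lon0,lon1
    ages_table: np.ndarray | None = None

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.region is None and self.spatial_scheme not in SPATIAL_SCHEMES:
            raise ValueError(f"unknown spatial scheme {self.spatial_scheme!r}")
        if not 0.0 <= self.temporal_split <= 1.0:
            raise ValueError("temporal_split must be a fraction in [0, 1]")
        if self.mode not in ("diploid", "pseudohaploid"):
            raise ValueError(f"unknown sampling mode {self.mode!r}")
        if self.age_distribution not in ("log-uniform", "matched-to-table"):
            raise ValueError(f"unknown age distribution {self.age_distribution!r}")
        if self.age_distribution == "matched-to-table" and self.ages_table is None:
            raise ValueError("matched-to-table requires ages_table")


@dataclass
class ForwardSimParams:
    n_individuals: int = 20_000
    s: float = 0.03
    origin_lat: float = 50.0  # Central Europe
    origin_lon: float = 10.0
    start_years_bp: float = 15_000.0
    competition_mating_radius_km: float = 250.0
    offspring_dispersal_sd_km: float = 25.0
    generation_time: float = 29.0
    seed: int = 0
    growth_rate: float = 1.0  # Ricker growth used for local regulation
    # mate choice is weighted by a Gaussian distance kernel (truncated at the
    # interaction radius); without decay the father's gamete alone would give
    # the allele an effective dispersal far above the offspring kernel
    mating_kernel_sd_km: float = 25.0

    def __post_init__(self):
        if self.competition_mating_radius_km <= 0 or self.offspring_dispersal_sd_km <= 0:
            raise ValueError("interaction and dispersal radii must be positive")
        if self.s < 0:
            raise ValueError("selection coefficient must be non-negative")
        if self.n_individuals < 2:
            raise ValueError("need at least two individuals")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def pseudohaploidize(genotype: int, seed=0) -> int:
    """Collapse a diploid genotype to a single sampled allele.

    Homozygotes map deterministically (0→0, 2→1); a heterozygote carries the
    derived allele with probability ½.
    """
    if genotype not in (0, 1, 2):
        raise ValueError(f"invalid genotype {genotype!r}")
    if genotype == 0:
        return 0
    if genotype == 2:
        return 1
    return int(_as_rng(seed).random() < 0.5)


def _land_cells_in_region(landscape: Landscape, region) -> np.ndarray:
    lat0, lat1, lon0, lon1 = region
    lats = landscape.cell_center_lats
    lons = landscape.cell_center_lons
    rows_ok = (lats >= lat0) & (lats <= lat1)
    cols_ok = (lons >= lon0) & (lons <= lon1)
    mask = landscape.land_mask & rows_ok[:, None] & cols_ok[None, :]
    cells = np.argwhere(mask)
    if len(cells) == 0:
        raise ValueError(f"sampling region {region} contains no land")
    return cells


def _scheme_region(design: SamplingDesign, landscape: Landscape):
    if design.region is not None:
        return design.region
    f = _SCHEME_FRACTION[design.spatial_scheme]
    cells = np.argwhere(landscape.land_mask)
    if len(cells) == 0:
        raise ValueError("landscape has no land cells")
    # centre the restricted window on the land centroid
    clat = landscape.lat_min + (cells[:, 0].mean() + 0.5) * landscape.resolution
    clon = landscape.lon_min + (cells[:, 1].mean() + 0.5) * landscape.resolution
    half_lat = 0.5 * f * (landscape.lat_max - landscape.lat_min)
    half_lon = 0.5 * f * (landscape.lon_max - landscape.lon_min)
    return (
        max(landscape.lat_min, clat - half_lat),
        min(landscape.lat_max, clat + half_lat),
        max(landscape.lon_min, clon - half_lon),
        min(landscape.lon_max, clon + half_lon),
    )


def _draw_ages(design: SamplingDesign, epoch_boundary: float, rng) -> np.ndarray:
    n = design.n_samples
    if design.age_distribution == "matched-to-table":
        table = np.asarray(design.ages_table, dtype=float)
        if len(table) >= n:
            return rng.choice(table, size=n, replace=False)
        return rng.choice(table, size=n, replace=True)
    if design.age_max_years_bp is None:
        raise ValueError("log-uniform ages require age_max_years_bp")
    n_old = int(round(design.temporal_split * n))
    n_young = n - n_old
    lo = max(design.age_min_years_bp, 1.0)
    boundary = min(max(epoch_boundary, lo), design.age_max_years_bp)
    ages = []
    if n_old:
        ages.append(np.exp(rng.uniform(math.log(boundary),
                                       math.log(design.age_max_years_bp), n_old)))
    if n_young:
        ages.append(np.exp(rng.uniform(math.log(lo), math.log(boundary), n_young)))
    return np.concatenate(ages)


def design_locations(
    design: SamplingDesign,
    landscape: Landscape,
    epoch_boundary: float = 5000.0,
    rng=None,
) -> list[tuple[float, float, float]]:
    """Draw (lat, lon, age_years_bp) sampling points for a design.

    Locations are uniform over land cells of the scheme's region; ages are
    split across the epoch boundary by the design's temporal quota and drawn
    log-uniformly within each side (or matched to a provided table).
    """
    rng = _as_rng(design.seed if rng is None else rng)
    cells = _land_cells_in_region(landscape, _scheme_region(design, landscape))
    ages = _draw_ages(design, epoch_boundary, rng)
    picks = rng.integers(len(cells), size=design.n_samples)
    res = landscape.resolution
    out = []
    for k, age in zip(picks, ages):
        r, c = cells[k]
        lat = landscape.lat_min + (r + rng.random()) * res
        lon = landscape.lon_min + (c + rng.random()) * res
        out.append((float(lat), float(lon), float(age)))
    return out


def sample_from_surface(
    surface: FrequencySurface,
    design: SamplingDesign,
    epoch_boundary: float = 5000.0,
    locus: str = "sim",
) -> Dataset:
    """Binomial genotype draws from a solved surface under a sampling design."""
    rng = _as_rng(design.seed)
    if design.age_max_years_bp is None and design.age_distribution == "log-uniform":
        design = dataclasses_replace_age(design, 0.95 * surface.allele_age_years_bp)
    points = design_locations(design, surface.landscape, epoch_boundary, rng)
    observations = []
    for i, (lat, lon, age) in enumerate(points):
        p = frequency_at(surface, lat, lon, age)
        if not np.isfinite(p):
            raise ValueError(
                f"sample point ({lat:.3f}, {lon:.3f}, {age:.0f} BP) has no "
                "defined frequency"
            )
        g = int(rng.binomial(2, p))
        if design.mode == "pseudohaploid":
            observations.append(Observation(
                id=f"sim{i}", lat=lat, lon=lon, age_years_bp=age,
                kind="pseudohaploid", allele=pseudohaploidize(g, rng),
            ))
        else:
            observations.append(Observation(
                id=f"sim{i}", lat=lat, lon=lon, age_years_bp=age,
                kind="diploid_genotype", genotype=g,
            ))
    return Dataset(observations, locus=locus)


def dataclasses_replace_age(design: SamplingDesign, age_max: float) -> SamplingDesign:
    import dataclasses

    return dataclasses.replace(design, age_max_years_bp=age_max)


# ---------------------------------------------------------------------------
# individual-based forward simulation
# ---------------------------------------------------------------------------


@njit(cache=True)
def _seed_numba(seed):  # pragma: no cover - jitted
    np.random.seed(seed)


@njit(cache=True)
def _bin_individuals(lat, lon, lat_min, lon_min, res, n_rows, n_cols):  # pragma: no cover
    n = lat.size
    cell = np.empty(n, dtype=np.int64)
    counts = np.zeros(n_rows * n_cols + 1, dtype=np.int64)
    for i in range(n):
        r = int((lat[i] - lat_min) / res)
        c = int((lon[i] - lon_min) / res)
        if r < 0:
            r = 0
        if r >= n_rows:
            r = n_rows - 1
        if c < 0:
            c = 0
        if c >= n_cols:
            c = n_cols - 1
        cell[i] = r * n_cols + c
        counts[cell[i] + 1] += 1
    starts = np.cumsum(counts)
    order = np.empty(n, dtype=np.int64)
    pos = starts[:-1].copy()
    for i in range(n):
        order[pos[cell[i]]] = i
        pos[cell[i]] += 1
    return cell, starts, order


@njit(cache=True)
def _mean_neighbors(lat, lon, radius_km, lat_min, lon_min, res, n_rows, n_cols):  # pragma: no cover
    cell, starts, order = _bin_individuals(lat, lon, lat_min, lon_min, res,
                                           n_rows, n_cols)
    n = lat.size
    r2 = radius_km * radius_km
    dr = int(radius_km / (_KM_PER_DEG * res)) + 1
    total = 0.0
    for i in range(n):
        ri = cell[i] // n_cols
        ci = cell[i] % n_cols
        coslat = math.cos(math.radians(lat[i]))
        if coslat < 0.05:
            coslat = 0.05
        dc = int(radius_km / (_KM_PER_DEG * res * coslat)) + 1
        m = 0
        for rr in range(max(0, ri - dr), min(n_rows, ri + dr + 1)):
            for cc in range(max(0, ci - dc), min(n_cols, ci + dc + 1)):
                b = rr * n_cols + cc
                for k in range(starts[b], starts[b + 1]):
                    j = order[k]
                    if j == i:
                        continue
                    dy = (lat[j] - lat[i]) * _KM_PER_DEG
                    dx = (lon[j] - lon[i]) * _KM_PER_DEG * coslat
                    if dx * dx + dy * dy <= r2:
                        m += 1
        total += m
    return total / n


@njit(cache=True)
def _step(lat, lon, geno, s, radius_km, disp_sd, mate_sd, K, growth, n_target,
          land, lat_min, lon_min, lat_max, lon_max, res, n_rows, n_cols):  # pragma: no cover
    """One non-overlapping generation; returns child arrays and a flag.

    Expected offspring per mother combines fitness, local Ricker regulation
    against the neighbour count, and a global normalisation that pins the
    expected census at n_target; flag 1 signals capacity overflow.
    """
    n = lat.size
    cell, starts, order = _bin_individuals(lat, lon, lat_min, lon_min, res,
                                           n_rows, n_cols)
    r2 = radius_km * radius_km
    inv_2tau2 = 1.0 / (2.0 * mate_sd * mate_sd)
    dr = int(radius_km / (_KM_PER_DEG * res)) + 1

    wbar = 0.0
    for i in range(n):
        wbar += 1.0 + s * geno[i]
    wbar /= n

    # pass 1: neighbour census and fitness-weighted mate pools
    m_arr = np.zeros(n, dtype=np.int64)
    wsum_arr = np.zeros(n)
    lam = np.zeros(n)
    for i in range(n):
        ri = cell[i] // n_cols
        ci = cell[i] % n_cols
        coslat = math.cos(math.radians(lat[i]))
        if coslat < 0.05:
            coslat = 0.05
        dc = int(radius_km / (_KM_PER_DEG * res * coslat)) + 1
        m = 0
        wsum = 0.0
        for rr in range(max(0, ri - dr), min(n_rows, ri + dr + 1)):
            for cc in range(max(0, ci - dc), min(n_cols, ci + dc + 1)):
                b = rr * n_cols + cc
                for k in range(starts[b], starts[b + 1]):
                    j = order[k]
                    if j == i:
                        continue
                    dy = (lat[j] - lat[i]) * _KM_PER_DEG
                    dx = (lon[j] - lon[i]) * _KM_PER_DEG * coslat
                    d2 = dx * dx + dy * dy
                    if d2 <= r2:
                        m += 1
                        wsum += (1.0 + s * geno[j]) * math.exp(-d2 * inv_2tau2)
        m_arr[i] = m
        wsum_arr[i] = wsum
        if m > 0:
            w_i = 1.0 + s * geno[i]
            lam[i] = (w_i / wbar) * math.exp(growth * (1.0 - m / K))
    lam_total = lam.sum()
    if lam_total > 0.0:
        lam *= n_target / lam_total

    cap = 4 * n + 16
    c_lat = np.empty(cap)
    c_lon = np.empty(cap)
    c_geno = np.empty(cap, dtype=np.int8)
    c_parent = np.empty(cap, dtype=np.int64)
    n_children = 0
    flag = 0

    for i in range(n):
        if m_arr[i] == 0:
            continue
        ri = cell[i] // n_cols
        ci = cell[i] % n_cols
        coslat = math.cos(math.radians(lat[i]))
        if coslat < 0.05:
            coslat = 0.05
        dc = int(radius_km / (_KM_PER_DEG * res * coslat)) + 1
        wsum = wsum_arr[i]
        n_off = np.random.poisson(lam[i])
        for _ in range(n_off):
            if n_children >= cap:
                flag = 1
                break
            # fitness-proportional mate choice within the radius
            target = np.random.random() * wsum
            acc = 0.0
            mate = -1
            for rr in range(max(0, ri - dr), min(n_rows, ri + dr + 1)):
                if mate >= 0:
                    break
                for cc in range(max(0, ci - dc), min(n_cols, ci + dc + 1)):
                    if mate >= 0:
                        break
                    b = rr * n_cols + cc
                    for k in range(starts[b], starts[b + 1]):
                        j = order[k]
                        if j == i:
                            continue
                        dy = (lat[j] - lat[i]) * _KM_PER_DEG
                        dx = (lon[j] - lon[i]) * _KM_PER_DEG * coslat
                        d2 = dx * dx + dy * dy
                        if d2 <= r2:
                            acc += (1.0 + s * geno[j]) * math.exp(-d2 * inv_2tau2)
                            if acc >= target:
                                mate = j
                                break
            if mate < 0:
                continue
            # Mendelian gametes
            gm = 0
            if geno[i] == 2:
                gm = 1
            elif geno[i] == 1:
                gm = 1 if np.random.random() < 0.5 else 0
            gf = 0
            if geno[mate] == 2:
                gf = 1
            elif geno[mate] == 1:
                gf = 1 if np.random.random() < 0.5 else 0
            # Gaussian dispersal, rejected off water/map (fallback: stay put)
            nlat = lat[i]
            nlon = lon[i]
            for _try in range(10):
                dky = np.random.normal(0.0, disp_sd)
                dkx = np.random.normal(0.0, disp_sd)
                tlat = lat[i] + dky / _KM_PER_DEG
                tlon = lon[i] + dkx / (_KM_PER_DEG * coslat)
                if tlat <= lat_min or tlat >= lat_max:
                    continue
                if tlon <= lon_min or tlon >= lon_max:
                    continue
                rr = int((tlat - lat_min) / res)
                cc = int((tlon - lon_min) / res)
                if land[rr * n_cols + cc]:
                    nlat = tlat
                    nlon = tlon
                    break
            c_lat[n_children] = nlat
            c_lon[n_children] = nlon
            c_geno[n_children] = gm + gf
            c_parent[n_children] = i
            n_children += 1
        if flag == 1:
            break
    return (c_lat[:n_children], c_lon[:n_children], c_geno[:n_children],
            c_parent[:n_children], flag)


def forward_simulate(
    params: ForwardSimParams,
    landscape: Landscape,
    end_years_bp: float = 0.0,
    record_every: int = 1,
    on_loss: str = "raise",
    initial_carriers: int = 1,
) -> pd.DataFrame:
    """Run the individual-based simulation and return per-individual records.

    The derived allele starts as ``initial_carriers`` heterozygous copies in
    the individuals nearest the origin at the start generation.  Columns of
    the returned frame: id, generation, age_bp, lat, lon, genotype, parent
    (row id of the parent record, −1 for founders).

    Raises :class:`AlleleLostError` when the allele is lost and
    ``on_loss='raise'`` (the default); ``on_loss='keep'`` lets the
    simulation continue allele-free (useful for neutral expectations).
    """
    if on_loss not in ("raise", "keep"):
        raise ValueError("on_loss must be 'raise' or 'keep'")
    n_gens = int(round((params.start_years_bp - end_years_bp) / params.generation_time))
    if n_gens < 1:
        raise ValueError("simulation span shorter than one generation")
    rng = np.random.default_rng(params.seed)
    _seed_numba(int(rng.integers(2**31 - 1)))

    land_cells = np.argwhere(landscape.land_mask)
    if len(land_cells) == 0:
        raise ValueError("landscape has no land cells")
    origin_rc = locate(landscape, params.origin_lat, params.origin_lon)
    if not landscape.is_land(*origin_rc):
        raise ValueError("origin is not on land")

    n = params.n_individuals
    picks = rng.integers(len(land_cells), size=n)
    lat = landscape.lat_min + (land_cells[picks, 0] + rng.random(n)) * landscape.resolution
    lon = landscape.lon_min + (land_cells[picks, 1] + rng.random(n)) * landscape.resolution
    geno = np.zeros(n, dtype=np.int8)
    d2 = ((lat - params.origin_lat) * _KM_PER_DEG) ** 2 + (
        (lon - params.origin_lon) * _KM_PER_DEG
        * np.cos(np.radians(params.origin_lat))
    ) ** 2
    geno[np.argsort(d2)[:initial_carriers]] = 1

    K = _mean_neighbors(
        lat, lon, params.competition_mating_radius_km,
        landscape.lat_min, landscape.lon_min, landscape.resolution,
        landscape.n_rows, landscape.n_cols,
    )
    if K <= 0:
        raise ValueError(
            "initial population too sparse: no individual has a neighbour "
            "within the interaction radius"
        )

    land_flat = landscape.land_mask.ravel()
    frames = []
    next_id = 0
    prev_ids = None

    def record(gen, lat, lon, geno, parent_record_ids):
        nonlocal next_id
        ids = np.arange(next_id, next_id + len(lat))
        next_id += len(lat)
        frames.append(pd.DataFrame({
            "id": ids,
            "generation": gen,
            "age_bp": params.start_years_bp - gen * params.generation_time,
            "lat": lat,
            "lon": lon,
            "genotype": geno.astype(np.int64),
            "parent": parent_record_ids,
        }))
        return ids

    prev_ids = record(0, lat, lon, geno, np.full(n, -1, dtype=np.int64))

    for g in range(1, n_gens + 1):
        lat, lon, geno, parent_idx, flag = _step(
            lat, lon, geno, params.s,
            params.competition_mating_radius_km,
            params.offspring_dispersal_sd_km,
            params.mating_kernel_sd_km,
            K, params.growth_rate, float(params.n_individuals),
            land_flat, landscape.lat_min, landscape.lon_min,
            landscape.lat_max, landscape.lon_max,
            landscape.resolution, landscape.n_rows, landscape.n_cols,
        )
        if flag == 1:
            raise RuntimeError(f"population exploded at generation {g}")
        if len(lat) < 2:
            raise RuntimeError(f"population went extinct at generation {g}")
        if geno.sum() == 0 and on_loss == "raise":
            raise AlleleLostError(g)
        parent_ids = prev_ids[parent_idx]
        if g % record_every == 0 or g == n_gens:
            prev_ids = record(g, lat, lon, geno, parent_ids)
        else:
            # keep id continuity for parent links even on unrecorded generations
            prev_ids = np.arange(next_id, next_id + len(lat))
            next_id += len(lat)

    return pd.concat(frames, ignore_index=True)


def subsample_individuals(
    records: pd.DataFrame,
    n: int,
    age_distribution: str = "log-uniform",
    seed: int = 0,
    age_min_years_bp: float | None = None,
    age_max_years_bp: float | None = None,
    locus: str = "fwd",
) -> Dataset:
    """Draw n individuals with log-uniform ages and pseudohaploidise them.

    Each target age is matched to the nearest recorded generation; within a
    generation individuals are drawn without replacement.
    """
    if age_distribution != "log-uniform":
        raise ValueError("only log-uniform age sampling is supported")
    rng = np.random.default_rng(seed)
    ages_avail = np.sort(records["age_bp"].unique())
    lo = max(age_min_years_bp if age_min_years_bp is not None else ages_avail[0], 1.0)
    hi = age_max_years_bp if age_max_years_bp is not None else ages_avail[-1]
    if hi <= lo:
        raise ValueError("records do not span the requested age range")
    targets = np.exp(rng.uniform(math.log(lo), math.log(hi), n))

    by_gen = {a: records.index[records["age_bp"] == a].to_numpy() for a in ages_avail}
    used: dict[float, int] = {a: 0 for a in ages_avail}
    for a in ages_avail:
        by_gen[a] = rng.permutation(by_gen[a])

    observations = []
    for i, t in enumerate(np.sort(targets)[::-1]):
        order = np.argsort(np.abs(ages_avail - t))
        row = None
        for k in order:
            a = ages_avail[k]
            if used[a] < len(by_gen[a]):
                row = records.loc[by_gen[a][used[a]]]
                used[a] += 1
                break
        if row is None:
            raise ValueError(
                f"requested {n} samples but the records are exhausted"
            )
        observations.append(Observation(
            id=f"ind{int(row['id'])}",
            lat=float(row["lat"]),
            lon=float(row["lon"]),
            age_years_bp=float(row["age_bp"]),
            kind="pseudohaploid",
            allele=pseudohaploidize(int(row["genotype"]), rng),
        ))
    return Dataset(observations, locus=locus)
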