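"""Probability of genotype observations given a frequency surface.

Three observation kinds are supported per individual and locus:

* ``genotype_likelihood`` — a (possibly unnormalised) probability triplet
  over 0/1/2 copies of the derived allele, marginalised against the
  Hardy–Weinberg genotype prior at the local frequency;
* ``diploid_genotype`` — a hard call, equivalent to a degenerate triplet;
* ``pseudohaploid`` — a single sampled allele, Bernoulli(p) in the derived
  allele.

Log-likelihoods of impossible observations (e.g. a derived pseudohaploid
call where p = 0) are floored at a configurable small value so optimisers
can move away from impossible parameter regions; the offending observation
ids are reported in a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .pde import FrequencySurface, frequency_at

__all__ = [
    "Observation",
    "Dataset",
    "genotype_prior",
    "observation_loglik",
    "dataset_loglik",
    "LOGLIK_FLOOR",
]

KINDS = ("genotype_likelihood", "diploid_genotype", "pseudohaploid")
LOGLIK_FLOOR = math.log(1e-300)


@dataclass
class Observation:
    """One individual's georeferenced, dated genotype evidence at the locus."""

    id: str
    lat: float
    lon: float
    age_years_bp: float
    kind: str
    gl: tuple[float, float, float] | None = None
    genotype: int | None = None
    allele: int | None = None

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown observation kind {self.kind!r}")
        if self.age_years_bp < 0:
            raise ValueError(f"observation {self.id}: negative age")
        payloads = [self.gl is not None, self.genotype is not None,
                    self.allele is not None]
        if sum(payloads) != 1:
            raise ValueError(
                f"observation {self.id}: exactly one payload must be set"
            )
        if self.kind == "genotype_likelihood":
            if self.gl is None:
                raise ValueError(f"observation {self.id}: missing gl triplet")
            gl = np.asarray(self.gl, dtype=float)
            if gl.shape != (3,) or np.any(gl < 0) or not np.any(gl > 0):
                raise ValueError(
                    f"observation {self.id}: degenerate likelihood triplet"
                )
            self.gl = tuple(float(x) for x in gl)
        elif self.kind == "diploid_genotype":
            if self.genotype not in (0, 1, 2):
                raise ValueError(f"observation {self.id}: genotype must be 0/1/2")
        else:
            if self.allele not in (0, 1):
                raise ValueError(f"observation {self.id}: allele must be 0/1")


@dataclass
class Dataset:
    observations: list[Observation]
    locus: str = "locus"

    def __post_init__(self):
        if not isinstance(self.observations, list):
            self.observations = list(self.observations)

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    def require_nonempty(self) -> None:
        if not self.observations:
            raise ValueError("dataset is empty")


def genotype_prior(p: float) -> np.ndarray:
    """Hardy–Weinberg genotype probabilities ((1−p)², 2p(1−p), p²)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"frequency {p} outside [0, 1]")
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


def observation_loglik(
    obs: Observation, p: float, floor: float | None = LOGLIK_FLOOR
) -> float:
    """Log-probability of one observation at local derived-allele frequency p.

    With ``floor=None`` impossible observations return −inf; otherwise they
    are floored at ``floor``.
    """
    if obs.kind == "pseudohaploid":
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"frequency {p} outside [0, 1]")
        lik = p if obs.allele == 1 else 1.0 - p
    else:
        prior = genotype_prior(p)
        if obs.kind == "diploid_genotype":
            lik = prior[obs.genotype]
        else:
            lik = float(np.dot(obs.gl, prior))
    if lik <= 0.0:
        return -math.inf if floor is None else floor
    ll = math.log(lik)
    return ll if floor is None else max(ll, floor)


def dataset_loglik(
    data: Dataset,
    surface: FrequencySurface,
    floor: float | None = LOGLIK_FLOOR,
    snap_radius: int = 1,
    clamp_pre_origin: bool = False,
) -> float:
    """Sum of per-observation log-likelihoods against a solved surface.

    Observations are independent; each is evaluated at the frequency
    interpolated at its location and age.  Impossible observations are
    floored (or propagate −inf when ``floor=None``) and their ids listed in
    a warning.
    """
    data.require_nonempty()
    total = 0.0
    flagged: list[str] = []
    for obs in data:
        p = frequency_at(
            surface, obs.lat, obs.lon, obs.age_years_bp,
            snap_radius=snap_radius, clamp_pre_origin=clamp_pre_origin,
        )
        ll = observation_loglik(obs, p, floor=None)
        if not math.isfinite(ll):
            flagged.append(obs.id)
            ll = -math.inf if floor is None else floor
        elif floor is not None:
            ll = max(ll, floor)
        total += ll
    if flagged:
        warnings.warn(
            f"{len(flagged)} observation(s) with zero likelihood: "
            f"{flagged[:10]}{'...' if len(flagged) > 10 else ''}",
            RuntimeWarning,
            stacklevel=2,
        )
    return total
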