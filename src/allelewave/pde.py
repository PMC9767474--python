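"""Diffusion–advection–reaction dynamics of an allele-frequency surface.

Three nested model variants are supported:

* ``A`` — isotropic diffusion + logistic-type local growth,
* ``B`` — distinct longitudinal / latitudinal diffusion,
* ``C`` — model B plus advection velocities along each axis.

The surface evolves as

    dp/dt = ½ σx² ∂²p/∂x² + ½ σy² ∂²p/∂y² + vx ∂p/∂x + vy ∂p/∂y + γ(p, s, d)

with γ(p, s, d) = p(1−p)(p·d + s(1−2p)); the additive default d = 2s
reduces γ to logistic growth s·p(1−p).  Space is the metric grid of a
:class:`~allelewave.landscape.Landscape`: diffusion is discretised with
second-order central differences, advection with first-order upwind
differences.  Water cells act as interior no-flux boundaries; beyond the
outer map frame the frequency is absorbed (held at zero).

Integration uses an adaptive stiff-capable method-of-lines scheme (LSODA
with a banded Jacobian structure).  Parameters may change across epochs;
the state is continuous at epoch boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import odeint

from .landscape import Landscape, locate

__all__ = [
    "EpochParams",
    "ModelSpec",
    "FrequencySurface",
    "reaction_term",
    "spatial_operator",
    "initial_surface",
    "solve_surface",
    "frequency_at",
]

_P_TOL = 1e-3  # permitted numerical excursion outside [0, 1] before clipping


@dataclass
class EpochParams:
    """Spread parameters valid on a time interval (generations since origin).

    ``sigma_x`` / ``sigma_y`` are in km per sqrt(generation); the squared
    values are diffusion coefficients in km²/generation.  ``d`` defaults to
    the additive rule 2s when left as None.
    """

    s: float
    sigma_x: float
    sigma_y: float
    v_x: float = 0.0
    v_y: float = 0.0
    t_start: float = 0.0
    t_end: float = np.inf
    d: float | None = None

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError(f"epoch must have t_start < t_end, got "
                             f"[{self.t_start}, {self.t_end}]")

    @property
    def dominance(self) -> float:
        return 2.0 * self.s if self.d is None else self.d

    @classmethod
    def from_sigma2(cls, s, sigma2_x, sigma2_y, v_x=0.0, v_y=0.0,
                    t_start=0.0, t_end=np.inf, d=None) -> "EpochParams":
        if sigma2_x < 0 or sigma2_y < 0:
            raise ValueError("diffusion coefficients must be non-negative")
        return cls(s=s, sigma_x=math.sqrt(sigma2_x), sigma_y=math.sqrt(sigma2_y),
                   v_x=v_x, v_y=v_y, t_start=t_start, t_end=t_end, d=d)


@dataclass
class ModelSpec:
    """Configuration of one allele-spread model run."""

    variant: str  # 'A' | 'B' | 'C'
    allele_age_years_bp: float
    origin_cell: tuple[int, int]
    generation_time: float = 29.0
    epoch_boundary_years_bp: float = 5000.0
    founder_density: float = 2.5  # diploid individuals per km²

    def __post_init__(self):
        if self.variant not in ("A", "B", "C"):
            raise ValueError(f"unknown model variant {self.variant!r}")
        if self.allele_age_years_bp <= 0:
            raise ValueError("allele age must be positive")
        if not 0.0 <= self.epoch_boundary_years_bp <= self.allele_age_years_bp:
            raise ValueError("epoch boundary must lie within [0, allele age]")

    @property
    def total_generations(self) -> float:
        return self.allele_age_years_bp / self.generation_time

    @property
    def epoch_boundary_generation(self) -> float:
        """Generations since origin at which the epoch boundary falls."""
        return (
            self.allele_age_years_bp - self.epoch_boundary_years_bp
        ) / self.generation_time

    def age_to_generation(self, age_years_bp: float) -> float:
        return (self.allele_age_years_bp - age_years_bp) / self.generation_time


@dataclass
class FrequencySurface:
    """Solved allele-frequency field p(cell, t); water cells are NaN."""

    landscape: Landscape
    times: np.ndarray  # (n_times,) generations since origin, ascending
    p: np.ndarray  # (n_times, n_rows, n_cols)
    allele_age_years_bp: float
    generation_time: float = 29.0
    max_excursion: float = 0.0  # worst |p| outside [0,1] seen before clipping

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.p.shape != (len(self.times), self.landscape.n_rows,
                            self.landscape.n_cols):
            raise ValueError("surface array shape does not match times/grid")

    def snap_age_to_generation(self, age_years_bp: float) -> float:
        return (self.allele_age_years_bp - age_years_bp) / self.generation_time


def reaction_term(p, s: float, d: float | None = None):
    """Local growth rate γ(p, s, d) = p(1−p)(p·d + s(1−2p)); d=None means 2s."""
    p = np.asarray(p, dtype=float)
    if np.any(p < -_P_TOL) or np.any(p > 1.0 + _P_TOL):
        raise ValueError("frequency outside [0, 1]")
    if d is None:
        d = 2.0 * s
    out = p * (1.0 - p) * (p * d + s * (1.0 - 2.0 * p))
    return float(out) if out.ndim == 0 else out


@njit(cache=True)
def _rhs_kernel(p, out, land, dx, dy, n_rows, n_cols,
                sx2, sy2, vx, vy, s, d):  # pragma: no cover - jitted
    for r in range(n_rows):
        inv_dx = 1.0 / dx[r]
        inv_dx2 = inv_dx * inv_dx
        inv_dy = 1.0 / dy[r]
        inv_dy2 = inv_dy * inv_dy
        for c in range(n_cols):
            i = r * n_cols + c
            if not land[i]:
                out[i] = 0.0
                continue
            pc = p[i]
            # west / east neighbours: absorbing (0) past the frame,
            # reflecting (no-flux) into water
            if c == 0:
                pw = 0.0
            elif land[i - 1]:
                pw = p[i - 1]
            else:
                pw = pc
            if c == n_cols - 1:
                pe = 0.0
            elif land[i + 1]:
                pe = p[i + 1]
            else:
                pe = pc
            if r == 0:
                ps_ = 0.0
            elif land[i - n_cols]:
                ps_ = p[i - n_cols]
            else:
                ps_ = pc
            if r == n_rows - 1:
                pn = 0.0
            elif land[i + n_cols]:
                pn = p[i + n_cols]
            else:
                pn = pc

            val = 0.5 * sx2 * (pw - 2.0 * pc + pe) * inv_dx2
            val += 0.5 * sy2 * (ps_ - 2.0 * pc + pn) * inv_dy2
            # upwind: for +v dp/dx information travels from the +x side
            # when v > 0 (solution translates towards -x)
            if vx >= 0.0:
                val += vx * (pe - pc) * inv_dx
            else:
                val += vx * (pc - pw) * inv_dx
            if vy >= 0.0:
                val += vy * (pn - pc) * inv_dy
            else:
                val += vy * (pc - ps_) * inv_dy
            val += pc * (1.0 - pc) * (pc * d + s * (1.0 - 2.0 * pc))
            out[i] = val


@njit(cache=True)
def _jac_kernel(p, jb, land, dx, dy, n_rows, n_cols,
                sx2, sy2, vx, vy, s, d):  # pragma: no cover - jitted
    """Packed banded Jacobian: jb[uband + i - j, j] = dF_i/dp_j, uband = n_cols."""
    ub = n_cols
    jb[:, :] = 0.0
    for r in range(n_rows):
        inv_dx = 1.0 / dx[r]
        cdx = 0.5 * sx2 * inv_dx * inv_dx
        inv_dy = 1.0 / dy[r]
        cdy = 0.5 * sy2 * inv_dy * inv_dy
        for c in range(n_cols):
            i = r * n_cols + c
            if not land[i]:
                continue
            pc = p[i]
            diag = -2.0 * cdx - 2.0 * cdy
            # west neighbour
            if c > 0 and land[i - 1]:
                jb[ub + 1, i - 1] += cdx
                if vx < 0.0:
                    jb[ub + 1, i - 1] += -vx * inv_dx
            elif c > 0:  # water: reflected into the diagonal
                diag += cdx
                if vx < 0.0:
                    diag += -vx * inv_dx
            # east neighbour
            if c < n_cols - 1 and land[i + 1]:
                jb[ub - 1, i + 1] += cdx
                if vx >= 0.0:
                    jb[ub - 1, i + 1] += vx * inv_dx
            elif c < n_cols - 1:
                diag += cdx
                if vx >= 0.0:
                    diag += vx * inv_dx
            # south neighbour
            if r > 0 and land[i - n_cols]:
                jb[ub + n_cols, i - n_cols] += cdy
                if vy < 0.0:
                    jb[ub + n_cols, i - n_cols] += -vy * inv_dy
            elif r > 0:
                diag += cdy
                if vy < 0.0:
                    diag += -vy * inv_dy
            # north neighbour
            if r < n_rows - 1 and land[i + n_cols]:
                jb[ub - n_cols, i + n_cols] += cdy
                if vy >= 0.0:
                    jb[ub - n_cols, i + n_cols] += vy * inv_dy
            elif r < n_rows - 1:
                diag += cdy
                if vy >= 0.0:
                    diag += vy * inv_dy
            # upwind diagonal terms of the advection derivative
            if vx >= 0.0:
                diag += -vx * inv_dx
            else:
                diag += vx * inv_dx
            if vy >= 0.0:
                diag += -vy * inv_dy
            else:
                diag += vy * inv_dy
            # reaction derivative
            diag += (1.0 - 2.0 * pc) * (s + pc * (d - 2.0 * s)) \
                + (pc - pc * pc) * (d - 2.0 * s)
            jb[ub, i] += diag


def _check_variant(params: EpochParams, variant: str) -> None:
    if variant == "A":
        if not math.isclose(params.sigma_x, params.sigma_y, rel_tol=1e-12):
            raise ValueError("model A requires sigma_x == sigma_y")
        if params.v_x != 0.0 or params.v_y != 0.0:
            raise ValueError("model A does not admit advection")
    elif variant == "B":
        if params.v_x != 0.0 or params.v_y != 0.0:
            raise ValueError("model B does not admit advection")


def spatial_operator(
    state: np.ndarray, params: EpochParams, landscape: Landscape
) -> np.ndarray:
    """Full right-hand side dp/dt evaluated on a frequency field.

    ``state`` is (n_rows, n_cols); values on water cells are ignored (the
    returned derivative is zero there).
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state[landscape.land_mask])):
        raise ValueError("non-finite state values on land cells")
    flat = np.where(landscape.land_mask, state, 0.0).ravel()
    out = np.empty_like(flat)
    _rhs_kernel(
        flat, out,
        landscape.land_mask.ravel(),
        np.ascontiguousarray(landscape.dx_km[:, 0]),
        np.ascontiguousarray(landscape.dy_km[:, 0]),
        landscape.n_rows, landscape.n_cols,
        params.sigma_x ** 2, params.sigma_y ** 2,
        params.v_x, params.v_y, params.s, params.dominance,
    )
    return out.reshape(landscape.n_rows, landscape.n_cols)


def initial_surface(landscape: Landscape, spec: ModelSpec) -> np.ndarray:
    """Founder condition: p₀ = 1/(2·D·A) at the origin cell, zero elsewhere."""
    r, c = spec.origin_cell
    if not landscape.is_land(r, c):
        raise ValueError(f"origin cell ({r}, {c}) is water")
    p = np.zeros((landscape.n_rows, landscape.n_cols))
    p[r, c] = 1.0 / (2.0 * spec.founder_density * landscape.area_km2[r, c])
    return p


def _validate_epochs(epochs: list[EpochParams], total: float, variant: str) -> None:
    if not epochs:
        raise ValueError("at least one epoch required")
    tol = 1e-6 * max(total, 1.0)
    if abs(epochs[0].t_start) > tol:
        raise ValueError("first epoch must start at t = 0")
    for a, b in zip(epochs, epochs[1:]):
        if abs(a.t_end - b.t_start) > tol:
            raise ValueError(
                f"epochs leave a gap/overlap at t = {a.t_end} vs {b.t_start}"
            )
    if epochs[-1].t_end < total - tol:
        raise ValueError("epochs do not cover the full time span")
    for e in epochs:
        _check_variant(e, variant)


def solve_surface(
    landscape: Landscape,
    spec: ModelSpec,
    epochs: list[EpochParams],
    output_times: np.ndarray,
    initial: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-10,
    time_scale: float = 1.0,
) -> FrequencySurface:
    """Integrate the surface over [0, allele_age] generations.

    ``output_times`` are generations since origin; 0 is always included.
    ``initial`` overrides the founder condition (used for diagnostics and
    synthetic scenarios).  ``time_scale`` is an internal non-dimensionalisation
    of the time axis; results are invariant to it.
    """
    total = spec.total_generations
    _validate_epochs(epochs, total, spec.variant)
    output_times = np.asarray(output_times, dtype=float)
    if np.any(output_times < -1e-9) or np.any(output_times > total + 1e-6):
        raise ValueError("output_times outside [0, allele_age] span")
    output_times = np.unique(np.concatenate([[0.0], np.clip(output_times, 0.0, total)]))

    if initial is None:
        state = initial_surface(landscape, spec)
    else:
        state = np.asarray(initial, dtype=float).copy()
        if state.shape != (landscape.n_rows, landscape.n_cols):
            raise ValueError("initial field shape does not match grid")
    state = np.where(landscape.land_mask, state, 0.0).ravel()

    land = landscape.land_mask.ravel()
    dx = np.ascontiguousarray(landscape.dx_km[:, 0])
    dy = np.ascontiguousarray(landscape.dy_km[:, 0])
    nr, nc = landscape.n_rows, landscape.n_cols
    band = nc

    n_out = len(output_times)
    p_out = np.empty((n_out, nr * nc))
    p_out[0] = state
    max_exc = 0.0
    eps = 1e-9 * max(total, 1.0)

    for epoch in epochs:
        t0 = max(epoch.t_start, 0.0)
        t1 = min(epoch.t_end, total)
        if t1 <= t0:
            continue
        sx2, sy2 = epoch.sigma_x ** 2, epoch.sigma_y ** 2
        vx, vy, s, d = epoch.v_x, epoch.v_y, epoch.s, epoch.dominance

        def rhs(t, y, _sx2=sx2, _sy2=sy2, _vx=vx, _vy=vy, _s=s, _d=d):
            out = np.empty_like(y)
            _rhs_kernel(y, out, land, dx, dy, nr, nc, _sx2, _sy2, _vx, _vy, _s, _d)
            return out * time_scale

        jac_buf = np.zeros((2 * band + 1, nr * nc))

        def jac(t, y, _sx2=sx2, _sy2=sy2, _vx=vx, _vy=vy, _s=s, _d=d):
            _jac_kernel(y, jac_buf, land, dx, dy, nr, nc,
                        _sx2, _sy2, _vx, _vy, _s, _d)
            return jac_buf * time_scale

        # output slots inside (t0, t1]; the epoch end is always evaluated so
        # the state is continuous into the next epoch
        slots = np.nonzero((output_times > t0 + eps) & (output_times <= t1 + eps))[0]
        t_eval = np.minimum(output_times[slots], t1)  # clamp fp wobble at t1
        if len(t_eval) == 0 or t_eval[-1] < t1 - eps:
            t_eval = np.append(t_eval, t1)
        ts = np.concatenate([[t0], t_eval]) / time_scale
        ys, info = odeint(
            rhs,
            state,
            ts,
            Dfun=jac,
            ml=band,
            mu=band,
            rtol=rtol,
            atol=atol,
            tfirst=True,
            full_output=True,
        )
        if info["message"] != "Integration successful.":
            raise RuntimeError(
                f"integrator failed in epoch [{epoch.t_start}, {epoch.t_end}]: "
                f"{info['message']}"
            )
        ys = ys[1:]  # drop the t0 row
        max_exc = max(max_exc, float(max(0.0, ys.max() - 1.0, -ys.min())))
        for k, idx in enumerate(slots):
            p_out[idx] = ys[k]
        state = np.ascontiguousarray(ys[-1])

    times = output_times
    np.clip(p_out, 0.0, 1.0, out=p_out)
    p = p_out.reshape(n_out, nr, nc)
    p[:, ~landscape.land_mask] = np.nan
    return FrequencySurface(
        landscape=landscape,
        times=times,
        p=p,
        allele_age_years_bp=spec.allele_age_years_bp,
        generation_time=spec.generation_time,
        max_excursion=max_exc,
    )


def frequency_at(
    surface: FrequencySurface,
    lat: float,
    lon: float,
    age_years_bp: float,
    snap_radius: int = 1,
    clamp_pre_origin: bool = False,
) -> float:
    """Frequency at a geographic point and sample age (years BP).

    The sample time maps to t = (allele_age − age)/generation_time
    generations since origin; values are linearly interpolated between
    stored output times.  Samples predating the allele raise unless
    ``clamp_pre_origin`` clamps them to t = 0.
    """
    t = surface.snap_age_to_generation(age_years_bp)
    if t < -1e-9:
        if clamp_pre_origin:
            t = 0.0
        else:
            raise ValueError(
                f"sample age {age_years_bp} BP predates the allele "
                f"({surface.allele_age_years_bp} BP)"
            )
    t = min(max(t, 0.0), surface.times[-1])
    r, c = locate(surface.landscape, lat, lon, snap_radius=snap_radius)
    series = surface.p[:, r, c]
    return float(np.interp(t, surface.times, series))
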