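"""Strain-window bone-remodeling probability law.

The stimulus for each surface bone element is its equivalent strain
``eps_c`` (in microstrain) together with the nonuniformity ``Gamma_c`` of
the local equivalent-stress field.  Following the Mechanostat picture,
strain space is split into windows by four ordered thresholds
``eps_du < eps_pl < eps_pu < eps_ol``:

* disuse window, ``eps_c < eps_du``: resorption is certain, f* = -1;
* overuse window, ``eps_c >= eps_ol``: formation is certain, f* = +1;
* physiological window, ``eps_pl <= eps_c < eps_pu``: remodeling is
  stochastic and driven purely by stress nonuniformity, f* = f(Gamma_c);
* the two intermediate bands blend linearly between the neighbours, so
  f* is continuous and monotone non-decreasing in eps_c.

``Gamma_c`` is the relative deviation of the element's equivalent stress
from the inverse-distance-weighted mean over bone elements within a
sensing radius, and ``f(Gamma) = clamp(Gamma / Gamma_u, -1, 1)``: an
element stressed above its surroundings attracts bone, one shielded below
them loses bone — the classic lazy-zone-free uniformity-seeking surface
rule.  f* in [-1, 1] is read as a signed probability: its magnitude is the
chance of acting, its sign picks resorption (-) or formation (+).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "Action",
    "RemodelingParams",
    "nonuniformity",
    "nonuniformity_field",
    "f_gamma",
    "remodeling_probability",
    "decide",
]


class Action(IntEnum):
    REMOVE = -1
    NONE = 0
    ADD = 1


@dataclass
class RemodelingParams:
    """Parameters of the remodeling law.

    Thresholds are in microstrain and must satisfy
    ``0 < eps_du < eps_pl < eps_pu < eps_ol``.  Defaults put the
    physiological window at the 400–1500 microstrain healthy range with a
    disuse threshold of 100 and an overload threshold of 3000 microstrain.

    ``sensing_radius`` (m) bounds the neighborhood of the nonuniformity
    stimulus; ``gamma_scale`` is the nonuniformity at which the stochastic
    response saturates; ``n_act`` is the activation frequency — the number
    of decision sweeps executed per mechanical solve.
    """

    eps_du: float = 100.0
    eps_pl: float = 400.0
    eps_pu: float = 1500.0
    eps_ol: float = 3000.0
    sensing_radius: float = 150e-6
    gamma_scale: float = 1.0
    n_act: int = 1
    seed: Optional[int] = None
    decision_mode: Literal["stochastic", "deterministic"] = "stochastic"

    def __post_init__(self) -> None:
        if not (0.0 < self.eps_du < self.eps_pl < self.eps_pu < self.eps_ol):
            raise ValueError(
                "thresholds must satisfy 0 < eps_du < eps_pl < eps_pu < eps_ol"
            )
        if self.sensing_radius <= 0:
            raise ValueError("sensing_radius must be positive")
        if self.gamma_scale <= 0:
            raise ValueError("gamma_scale must be positive")
        if self.n_act < 1:
            raise ValueError("n_act must be >= 1")
        if self.decision_mode not in ("stochastic", "deterministic"):
            raise ValueError(f"unknown decision_mode {self.decision_mode!r}")


def nonuniformity(
    sigma_c: float,
    neighbor_stresses: Sequence[float],
    distances: Sequence[float],
) -> float:
    """Relative deviation of ``sigma_c`` from its weighted neighborhood mean.

    ``Gamma_c = (sigma_c - <sigma>_w) / <sigma>_w`` with ``<sigma>_w`` the
    inverse-distance-weighted mean of the neighbor stresses.  Raises
    ``ValueError`` for an empty neighborhood (isolated element) or a
    non-positive neighborhood mean.
    """
    s = np.asarray(neighbor_stresses, dtype=float)
    d = np.asarray(distances, dtype=float)
    if s.size == 0:
        raise ValueError("empty neighborhood: isolated element")
    if s.shape != d.shape:
        raise ValueError("neighbor_stresses and distances length mismatch")
    if np.any(d <= 0):
        raise ValueError("neighbor distances must be positive")
    w = 1.0 / d
    mean = float(np.sum(w * s) / np.sum(w))
    if mean <= 0.0:
        raise ValueError("non-positive neighborhood mean stress")
    return (float(sigma_c) - mean) / mean


def neighborhood_offsets(
    sensing_radius: float, spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Lattice offsets (n, 3) within the sensing radius (self excluded) and
    their center-to-center distances (m)."""
    m = int(np.floor(sensing_radius / spacing))
    if m < 1:
        raise ValueError("sensing_radius smaller than one voxel spacing")
    rng = np.arange(-m, m + 1)
    di, dj, dk = np.meshgrid(rng, rng, rng, indexing="ij")
    off = np.stack([di.ravel(), dj.ravel(), dk.ravel()], axis=1)
    dist = np.linalg.norm(off, axis=1) * spacing
    keep = (dist > 0) & (dist <= sensing_radius)
    return off[keep], dist[keep]


def nonuniformity_field(
    sigma: np.ndarray,
    bone_mask: np.ndarray,
    spacing: float,
    sensing_radius: float,
) -> np.ndarray:
    """Vectorized nonuniformity over a 3D equivalent-stress field.

    ``sigma`` holds per-voxel equivalent stress (Pa, any value outside
    ``bone_mask`` is ignored).  Returns a 3D array of Gamma values; voxels
    with no bone neighbor in range, or with a non-positive neighborhood
    mean (e.g. a completely unloaded model), get Gamma = 0 — there the
    window law alone decides.
    """
    if sigma.shape != bone_mask.shape:
        raise ValueError("sigma and bone_mask shape mismatch")
    offsets, dists = neighborhood_offsets(sensing_radius, spacing)
    num = np.zeros(sigma.shape)
    den = np.zeros(sigma.shape)
    sb = np.where(bone_mask, sigma, 0.0)
    bm = bone_mask.astype(float)
    for (di, dj, dk), dist in zip(offsets, dists):
        w = 1.0 / dist
        src = _shifted(sb, di, dj, dk)
        cnt = _shifted(bm, di, dj, dk)
        num += w * src
        den += w * cnt
    gamma = np.zeros(sigma.shape)
    ok = den > 0
    mean = np.zeros(sigma.shape)
    mean[ok] = num[ok] / den[ok]
    pos = ok & (mean > 0)
    gamma[pos] = (sigma[pos] - mean[pos]) / mean[pos]
    return gamma


def _shifted(a: np.ndarray, di: int, dj: int, dk: int) -> np.ndarray:
    """a shifted so out[x] = a[x + d], zero-padded at the boundary."""
    out = np.zeros_like(a)
    nx, ny, nz = a.shape

    def sl(n: int, d: int) -> tuple[slice, slice]:
        if d >= 0:
            return slice(0, n - d), slice(d, n)
        return slice(-d, n), slice(0, n + d)

    (dx0, sx0), (dy0, sy0), (dz0, sz0) = sl(nx, di), sl(ny, dj), sl(nz, dk)
    out[dx0, dy0, dz0] = a[sx0, sy0, sz0]
    return out


def f_gamma(gamma, gamma_scale: float):
    """Saturating linear response to nonuniformity: clamp(G/G_u, -1, 1)."""
    if gamma_scale <= 0:
        raise ValueError("gamma_scale must be positive")
    return np.clip(np.asarray(gamma, dtype=float) / gamma_scale, -1.0, 1.0)


def remodeling_probability(eps_c, gamma_c, params: RemodelingParams):
    """Signed remodeling probability f*(Gamma_c, eps_c) in [-1, 1].

    ``eps_c`` is equivalent strain in microstrain; scalar or array inputs
    broadcast together.
    """
    eps = np.asarray(eps_c, dtype=float)
    fg = f_gamma(gamma_c, params.gamma_scale)
    fg = np.broadcast_to(fg, np.broadcast_shapes(eps.shape, fg.shape))
    eps = np.broadcast_to(eps, fg.shape)

    t = (eps - params.eps_du) / (params.eps_pl - params.eps_du)
    s = (eps - params.eps_pu) / (params.eps_ol - params.eps_pu)
    out = np.select(
        [
            eps < params.eps_du,
            eps < params.eps_pl,
            eps < params.eps_pu,
            eps < params.eps_ol,
        ],
        [
            -np.ones_like(eps),
            -(1.0 - t) + t * fg,
            fg,
            (1.0 - s) * fg + s,
        ],
        default=1.0,
    )
    if out.ndim == 0 or (np.isscalar(eps_c) and np.isscalar(gamma_c)):
        return float(out)
    return out


def decide(f_star, rng: Optional[np.random.Generator] = None,
           mode: Literal["stochastic", "deterministic"] = "stochastic"):
    """Turn signed probabilities into actions.

    Stochastic mode draws one uniform variate per element from ``rng`` (in
    array order, so runs are reproducible per seed): REMOVE with
    probability |f*| when f* < 0, ADD with probability f* when f* > 0.
    Deterministic mode acts iff |f*| >= 0.5.
    """
    f = np.asarray(f_star, dtype=float)
    if np.any(f < -1.0) or np.any(f > 1.0):
        raise ValueError("f_star out of [-1, 1]")
    if mode == "deterministic":
        act = np.where(np.abs(f) >= 0.5, np.sign(f), 0.0)
    else:
        if rng is None:
            raise ValueError("stochastic mode requires an rng")
        draws = rng.random(f.shape)
        act = np.where(draws < np.abs(f), np.sign(f), 0.0)
    act = act.astype(np.int8)
    if act.ndim == 0:
        return Action(int(act))
    return act
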