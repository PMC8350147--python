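"""Voxelwise mono-exponential T2* relaxometry.

The signal of a multi-echo gradient-echo acquisition is modelled per voxel as

    S(TE) = S0 * exp(-TE / T2*)

and fitted by Levenberg-Marquardt least squares with at most 50 iterations,
the amplitude initialised from the first-echo signal and T2* from the
two-point log estimate of the first two echoes (fallback 50 ms). Fitted T2*
values above a ceiling (default 300 ms) are clipped — set to the ceiling, not
discarded — to limit amniotic-fluid partial-volume contributions near the
placental boundary.

The solver is vectorised over voxels: it iterates damped 2x2 normal-equation
steps for all voxels simultaneously (internally in (S0, R2=1/T2*) coordinates,
which are regular in the no-decay limit), which makes whole-volume fitting
fast without per-voxel Python loops. Echoes with non-positive signal are
excluded from a voxel's fit when at least two usable echoes remain; otherwise
the voxel is marked invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["T2StarMap", "EmptyMaskError", "fit_voxel", "fit_volume", "masked_mean_t2s"]

DEFAULT_CLIP_CEILING = 300.0
DEFAULT_MAX_ITER = 50
_TOL = 1e-8  # convergence tolerance on the parameter update norm
_T2S_FALLBACK = 50.0  # ms, initial T2* when the two-point estimate is unusable


class EmptyMaskError(ValueError):
    """Mask does not intersect any valid voxel of the map."""


@dataclass
class T2StarMap:
    """Fitted T2* map: T2* and S0 arrays plus a validity mask.

    ``t2s`` is in ms and, on valid voxels, lies in (0, ``clip_ceiling``].
    """

    t2s: np.ndarray
    s0: np.ndarray
    valid: np.ndarray
    clip_ceiling: float = DEFAULT_CLIP_CEILING


def _check_echo_times(echo_times: np.ndarray) -> np.ndarray:
    te = np.asarray(echo_times, dtype=float)
    if te.ndim != 1 or te.size < 2:
        raise ValueError("need at least two echo times")
    if np.any(~np.isfinite(te)) or np.any(te <= 0) or np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be finite, positive and strictly increasing")
    return te


def _lm_fit(te: np.ndarray, Y: np.ndarray, max_iter: int):
    """Damped least squares of S0*exp(-R2*TE) for each row of Y.

    Returns (s0, r2, valid). Rows with fewer than two positive finite
    samples are invalid. Non-positive samples get zero weight.
    """
    Y = np.asarray(Y, dtype=float)
    V, E = Y.shape
    finite = np.isfinite(Y)
    w = (finite & (Y > 0)).astype(float)
    usable = (w.sum(axis=1) >= 2) & finite.all(axis=1)
    w[~usable] = 0.0
    Yw = np.where(w > 0, Y, 0.0)

    # --- initialisation -----------------------------------------------------
    s0 = Yw[:, 0].copy()  # first-echo signal; 0 where that echo is excluded
    bad = s0 <= 0
    s0[bad] = np.maximum(Yw.max(axis=1)[bad], 1.0)
    # two-point log estimate from the first two usable echoes
    r2 = np.full(V, 1.0 / _T2S_FALLBACK)
    first = np.argmax(w > 0, axis=1)
    tmp = np.where(w > 0, np.arange(E)[None, :], E)
    tmp[np.arange(V), first] = E
    second = tmp.min(axis=1)
    ok = usable & (second < E)
    i, j = first[ok], second[ok]
    rows = np.flatnonzero(ok)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = np.log(Y[rows, i] / Y[rows, j]) / (te[j] - te[i])
    good = np.isfinite(est) & (est > 0)
    r2[rows[good]] = est[good]

    lam = np.full(V, 1e-3)
    p = np.stack([s0, r2], axis=1)  # (V, 2)
    active = usable.copy()

    def residual_cost(p):
        # trial steps may overshoot into huge negative rates; the resulting
        # inf/nan costs are simply rejected below
        with np.errstate(over="ignore", invalid="ignore"):
            model = p[:, 0:1] * np.exp(-p[:, 1:2] * te[None, :])
            r = (model - Yw) * w
            cost = (r * r).sum(axis=1)
        return model, r, np.where(np.isfinite(cost), cost, np.inf)

    model, r, cost = residual_cost(p)
    for _ in range(max_iter):
        if not active.any():
            break
        e = np.exp(np.minimum(-p[:, 1:2] * te[None, :], 700.0))
        J0 = e * w  # d/dS0
        J1 = -p[:, 0:1] * te[None, :] * e * w  # d/dR2
        a = (J0 * J0).sum(axis=1)
        b = (J0 * J1).sum(axis=1)
        c = (J1 * J1).sum(axis=1)
        g0 = (J0 * r).sum(axis=1)
        g1 = (J1 * r).sum(axis=1)
        aa = a * (1.0 + lam)
        cc = c * (1.0 + lam)
        det = aa * cc - b * b
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d0 = -(cc * g0 - b * g1) / det
        d1 = -(aa * g1 - b * g0) / det
        cand = p.copy()
        cand[active, 0] += d0[active]
        cand[active, 1] += d1[active]
        _, r_c, cost_c = residual_cost(cand)
        accept = active & (cost_c <= cost)
        p[accept] = cand[accept]
        r[accept] = r_c[accept]
        cost[accept] = cost_c[accept]
        lam = np.where(accept, np.maximum(lam / 3.0, 1e-12), np.minimum(lam * 3.0, 1e12))
        step = np.hypot(d0, d1) / (1.0 + np.hypot(p[:, 0], p[:, 1]))
        active &= ~(accept & (step < _TOL))

    return p[:, 0], p[:, 1], usable


def _r2_to_t2s(r2: np.ndarray, clip_ceiling: float | None) -> np.ndarray:
    """Map decay rates to T2*; non-positive rates mean no measurable decay."""
    with np.errstate(divide="ignore"):
        t2s = np.where(r2 > 0, 1.0 / np.where(r2 > 0, r2, 1.0), np.inf)
    if clip_ceiling is not None:
        t2s = np.minimum(t2s, clip_ceiling)
    return t2s


def fit_voxel(
    echo_times,
    signals,
    max_iter: int = DEFAULT_MAX_ITER,
    clip_ceiling: float | None = DEFAULT_CLIP_CEILING,
) -> tuple[float, float, bool]:
    """Fit one echo series; returns ``(s0, t2s, valid)``.

    Degenerate inputs (all-zero or non-finite signals, fewer than two positive
    echoes) yield ``valid=False`` instead of raising. A series with no
    measurable decay fits to an arbitrarily long T2* and is reported at the
    clip ceiling (``valid=True``). Pass ``clip_ceiling=None`` for the raw,
    unclipped estimate.
    """
    te = _check_echo_times(echo_times)
    y = np.asarray(signals, dtype=float)
    if y.shape != te.shape:
        raise ValueError(f"signals shape {y.shape} does not match echo times {te.shape}")
    s0, r2, valid = _lm_fit(te, y[None, :], max_iter)
    t2s = _r2_to_t2s(r2, clip_ceiling)
    return float(s0[0]), float(t2s[0]), bool(valid[0])


def fit_volume(
    volume,
    max_iter: int = DEFAULT_MAX_ITER,
    clip_ceiling: float | None = DEFAULT_CLIP_CEILING,
) -> T2StarMap:
    """Voxelwise fit of a :class:`~placentaging.phantom.MultiEchoVolume`.

    Applies :func:`fit_voxel` to every voxel (vectorised) and clips the
    resulting map at ``clip_ceiling``. Deterministic.
    """
    te = _check_echo_times(volume.echo_times)
    data = np.asarray(volume.data, dtype=float)
    if data.ndim != 4 or data.shape[3] != te.size:
        raise ValueError(
            f"volume shape {data.shape} does not match {te.size} echo times"
        )
    shape = data.shape[:3]
    Y = data.reshape(-1, te.size)
    s0, r2, valid = _lm_fit(te, Y, max_iter)
    t2s = _r2_to_t2s(r2, clip_ceiling)
    t2s[~valid] = 0.0
    s0 = np.where(valid, s0, 0.0)
    return T2StarMap(
        t2s=t2s.reshape(shape),
        s0=s0.reshape(shape),
        valid=valid.reshape(shape),
        clip_ceiling=np.inf if clip_ceiling is None else clip_ceiling,
    )


def masked_mean_t2s(t2s_map: T2StarMap, mask: np.ndarray) -> float:
    """Arithmetic mean of the (clipped) T2* over ``mask`` ∩ valid voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != t2s_map.t2s.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match map {t2s_map.t2s.shape}"
        )
    sel = mask & t2s_map.valid
    if not sel.any():
        raise EmptyMaskError("mask does not overlap any valid voxel")
    return float(t2s_map.t2s[sel].mean())
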