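"""Synthetic cohorts and multi-echo phantoms.

Real placental T2* cohorts are not publicly deposited, so this module
generates the two kinds of stand-in data the rest of the package operates on:

* **cohort tables** of (gestational age, mean placental T2*) pairs in which the
  low-risk group follows a linear decline of T2* with gestational age plus
  Gaussian scatter, and the high-risk group follows the *same* law evaluated at
  a shifted ("older") age — the accelerated-aging generative model; and
* **voxel-level phantoms**: 4D multi-echo gradient-echo volumes containing a
  placental plate with smooth lobule-like T2* texture, a long-T2* amniotic
  fluid compartment, and noisy background, together with the ground-truth
  placenta mask.

The default linear law (intercept 180 ms, slope -3.5 ms/week) is an invented
but physiologically plausible choice giving ~110 ms at 20 weeks and ~40 ms at
40 weeks; it is fully configurable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "CohortSpec",
    "PhantomSpec",
    "MultiEchoVolume",
    "ConfigurationError",
    "simulate_cohort",
    "simulate_multiecho_volume",
    "write_phantom",
    "read_phantom",
]

#: Echo times (ms) of the reference multi-echo gradient-echo protocol.
DEFAULT_ECHO_TIMES = (13.8, 70.4, 127.0, 183.6)

COHORT_COLUMNS = ["subject_id", "ga_weeks", "mean_t2s", "group", "split"]


class ConfigurationError(ValueError):
    """Raised for invalid cohort or phantom specifications."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic (GA, mean T2*) cohort.

    Gestational ages are drawn from a truncated normal (mean 29.9 weeks,
    SD 4.3 weeks by default, matching a typical third-trimester scanning
    distribution) restricted to ``ga_range``; set ``ga_distribution='uniform'``
    for a flat design. High-risk subjects keep their observed GA but their T2*
    is computed at ``ga + highrisk_age_shift``, i.e. their placenta looks
    ``highrisk_age_shift`` weeks older than it is.
    """

    n_low_risk: int = 90
    n_high_risk: int = 20
    ga_range: tuple[float, float] = (18.0, 40.0)
    t2s_intercept: float = 180.0
    t2s_slope: float = -3.5
    sigma_delta_true: float = 8.7
    highrisk_age_shift: float = 6.0
    seed: int = 0
    ga_mean: float = 29.9
    ga_sd: float = 4.3
    ga_distribution: str = "truncnorm"

    def validate(self) -> None:
        if self.n_low_risk < 0 or self.n_high_risk < 0:
            raise ConfigurationError("cohort sizes must be non-negative")
        lo, hi = self.ga_range
        if not (18.0 <= lo < hi <= 41.0):
            raise ConfigurationError(
                f"ga_range must be increasing and within [18, 41], got {self.ga_range}"
            )
        if not self.sigma_delta_true >= 0:
            raise ConfigurationError("sigma_delta_true must be >= 0")
        if self.t2s_slope >= 0:
            raise ConfigurationError("t2s_slope must be negative (T2* declines with GA)")
        if self.highrisk_age_shift < 0:
            raise ConfigurationError("highrisk_age_shift must be >= 0")
        if self.ga_distribution not in ("truncnorm", "uniform"):
            raise ConfigurationError("ga_distribution must be 'truncnorm' or 'uniform'")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal model of a voxel-level multi-echo phantom.

    The placenta is a plate-like ellipsoid; amniotic fluid is a second,
    disjoint ellipsoid with a long T2* (``fluid_t2s`` > 300 ms, so downstream
    clipping is exercised); the remaining field of view is maternal tissue
    with a short T2* (``body_t2s``), as in a real acquisition where the whole
    grid contains signal-bearing anatomy. ``texture_scale`` modulates a smooth
    random field emulating lobule heterogeneity; the field is demeaned over
    the placental mask so the masked mean T2* equals the subject's latent
    value. Set ``s0_body = 0`` for an empty (noise-only) background.
    """

    grid_shape: tuple[int, int, int] = (80, 80, 6)
    voxel_size_mm: float = 3.0
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES
    snr: float = 50.0
    fluid_t2s: float = 1000.0
    texture_scale: float = 0.05
    texture_smoothing_vox: float = 3.0
    s0_placenta: float = 100.0
    s0_fluid: float = 130.0
    s0_body: float = 90.0
    body_t2s: float = 25.0
    placenta_center: tuple[float, float, float] = (0.34, 0.50, 0.50)
    placenta_semiaxes: tuple[float, float, float] = (0.18, 0.30, 0.42)
    fluid_center: tuple[float, float, float] = (0.70, 0.50, 0.50)
    fluid_semiaxes: tuple[float, float, float] = (0.20, 0.32, 0.42)

    def validate(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        if te.size < 2 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ConfigurationError("echo_times must be positive and strictly increasing")
        if not self.snr > 0:
            raise ConfigurationError("snr must be > 0 (use numpy.inf for noiseless)")
        nx, ny, nz = self.grid_shape
        if nx < 8 or ny < 8 or nz < 1:
            raise ConfigurationError(
                f"grid_shape {self.grid_shape} too small to contain the phantom geometry"
            )
        if self.fluid_t2s <= 0:
            raise ConfigurationError("fluid_t2s must be positive")


@dataclass
class MultiEchoVolume:
    """4D multi-echo signal volume: spatial grid x echoes, with echo times in ms."""

    data: np.ndarray  # (nx, ny, nz, n_echoes)
    echo_times: np.ndarray  # (n_echoes,) ms
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.data.shape[3] != self.echo_times.size:
            raise ValueError(
                f"4th axis ({self.data.shape[3]}) must match echo_times ({self.echo_times.size})"
            )


def _sample_ga(spec: CohortSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.ga_range
    if spec.ga_distribution == "uniform":
        return rng.uniform(lo, hi, size=n)
    a = (lo - spec.ga_mean) / spec.ga_sd
    b = (hi - spec.ga_mean) / spec.ga_sd
    return stats.truncnorm.rvs(
        a, b, loc=spec.ga_mean, scale=spec.ga_sd, size=n, random_state=rng
    )


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort table of (GA, mean T2*) pairs.

    Low-risk subjects: ``mean_t2s = intercept + slope * ga + N(0, sigma_delta_true^2)``.
    High-risk subjects: the same law evaluated at ``ga + highrisk_age_shift``
    (the recorded ``ga_weeks`` is unchanged), i.e. all scatter sits on the T2*
    axis and abnormality is an age shift, not an additive T2* offset.

    Returns a DataFrame with columns ``subject_id, ga_weeks, mean_t2s, group,
    split`` (split initialised to ``"none"``). Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group, n, shift in (
        ("low_risk", spec.n_low_risk, 0.0),
        ("high_risk", spec.n_high_risk, spec.highrisk_age_shift),
    ):
        ga = _sample_ga(spec, n, rng)
        noise = rng.normal(0.0, spec.sigma_delta_true, size=n) if spec.sigma_delta_true > 0 else np.zeros(n)
        t2s = spec.t2s_intercept + spec.t2s_slope * (ga + shift) + noise
        for i in range(n):
            rows.append((f"{group[:3]}{i:04d}", ga[i], t2s[i], group, "none"))
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    if (df["mean_t2s"] <= 0).any():
        # keep latent tissue values physical; extremely rare under defaults
        df["mean_t2s"] = df["mean_t2s"].clip(lower=1.0)
    return df


def _ellipsoid_mask(shape: tuple[int, int, int], center_frac, semiaxes_frac) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    r2 = np.zeros(shape, dtype=float)
    for ax in range(3):
        c = center_frac[ax] * (shape[ax] - 1)
        a = semiaxes_frac[ax] * shape[ax]
        r2 += ((idx[ax] - c) / max(a, 1e-9)) ** 2
    mask = r2 <= 1.0
    return mask


def simulate_multiecho_volume(
    subject: pd.Series | dict, spec: PhantomSpec, seed: int | None = None
) -> tuple[MultiEchoVolume, np.ndarray]:
    """Build a multi-echo phantom volume and its ground-truth placenta mask.

    Placental voxels decay mono-exponentially with a voxelwise T2* equal to the
    subject's ``mean_t2s`` modulated by a smooth, mask-demeaned lobule texture;
    fluid voxels decay with ``spec.fluid_t2s``; background voxels carry no
    signal. Gaussian noise of scale ``s0_placenta / snr`` is added to every
    echo. The returned mask marks placental voxels only and is disjoint from
    the fluid compartment by construction.

    Parameters
    ----------
    subject : mapping with at least ``mean_t2s``; ``subject_id`` (hashed) and
        ``seed`` contribute to the noise seed when ``seed`` is not given.
    """
    spec.validate()
    rec = dict(subject)
    true_mean = float(rec["mean_t2s"])
    if true_mean <= 0:
        raise ConfigurationError("subject mean_t2s must be positive")
    if seed is None:
        # stable across processes (unlike built-in hash)
        seed = zlib.crc32(str(rec.get("subject_id", "")).encode()) % (2**31)
    rng = np.random.default_rng(seed)

    shape = tuple(spec.grid_shape)
    placenta = _ellipsoid_mask(shape, spec.placenta_center, spec.placenta_semiaxes)
    if not placenta.any():
        raise ConfigurationError("grid too small: placenta geometry is empty")
    fluid = _ellipsoid_mask(shape, spec.fluid_center, spec.fluid_semiaxes) & ~placenta

    # Smooth lobule-like texture, demeaned over the mask so the masked mean
    # T2* equals the latent subject value exactly (up to the positivity floor).
    t2s_vox = np.zeros(shape, dtype=float)
    if spec.texture_scale > 0:
        tex = ndimage.gaussian_filter(
            rng.standard_normal(shape), spec.texture_smoothing_vox
        )
        tex_m = tex[placenta]
        sd = tex_m.std()
        if sd > 0:
            tex = (tex - tex_m.mean()) / sd
        t2s_vox[placenta] = true_mean * (1.0 + spec.texture_scale * tex[placenta])
    else:
        t2s_vox[placenta] = true_mean
    t2s_vox[placenta] = np.clip(t2s_vox[placenta], 1.0, None)
    t2s_vox[fluid] = spec.fluid_t2s
    body = ~placenta & ~fluid
    t2s_vox[body] = spec.body_t2s

    te = np.asarray(spec.echo_times, dtype=float)
    signal = np.zeros(shape + (te.size,), dtype=float)
    compartments = [(placenta, spec.s0_placenta), (fluid, spec.s0_fluid)]
    if spec.s0_body > 0:
        compartments.append((body, spec.s0_body))
    for compartment, s0 in compartments:
        tt = t2s_vox[compartment][:, None]
        signal[compartment] = s0 * np.exp(-te[None, :] / tt)
    if np.isfinite(spec.snr):
        signal += rng.normal(0.0, spec.s0_placenta / spec.snr, size=signal.shape)

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    vol = MultiEchoVolume(signal.astype(np.float32), te, affine)
    return vol, placenta


def ground_truth_t2s(
    subject: pd.Series | dict, spec: PhantomSpec, seed: int | None = None
) -> np.ndarray:
    """Voxelwise ground-truth T2* of the phantom (same seed convention)."""
    noiseless = replace(spec, snr=np.inf)
    vol, mask = simulate_multiecho_volume(subject, noiseless, seed=seed)
    te = vol.echo_times
    with np.errstate(divide="ignore", invalid="ignore"):
        t2s = (te[-1] - te[0]) / np.log(vol.data[..., 0] / vol.data[..., -1])
    t2s[~mask] = 0.0
    return t2s


def write_phantom(volume: MultiEchoVolume, mask: np.ndarray, path_volume, path_mask) -> None:
    """Write volume and mask as NIfTI-1, echoes on the 4th axis."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)
    img.header["descrip"] = b"multi-echo GRE phantom"
    nib.save(img, str(path_volume))
    mimg = nib.Nifti1Image(mask.astype(np.uint8), volume.affine)
    nib.save(mimg, str(path_mask))


def read_phantom(path_volume, echo_times, path_mask=None):
    """Read a 4D NIfTI volume (and optionally a mask) written by :func:`write_phantom`."""
    import nibabel as nib

    img = nib.load(str(path_volume))
    vol = MultiEchoVolume(np.asarray(img.dataobj, dtype=np.float32), echo_times, img.affine)
    if path_mask is None:
        return vol
    mask = np.asarray(nib.load(str(path_mask)).dataobj) > 0
    return vol, mask
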