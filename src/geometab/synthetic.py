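"""Synthetic georeferenced metabolite fields and synthetic NMR data.

This module generates test inputs with the statistical structure the
spatial analysis assumes:

* stationary Gaussian random fields (GRFs) with exponential covariance
  C(h) = sill · exp(−h/ℓ) plus a nugget, drawn by dense Cholesky
  factorization of the site covariance (exact at survey scale, n ≲ 1000);
* spatially clustered bimodal mixtures — a latent GRF thresholded at a
  quantile assigns each site to a low or high mode (emulating, e.g., an
  acetic-acid field with modes near −0.5 and 2.0 on the standardized
  scale, the low mode holding most samples);
* jittered quasi-grid sampling positions with GPS error (~3 m);
* synthetic free induction decays containing a full multiplet catalog
  plus a DSS reference line, so the processing/quantification chain can
  be exercised round-trip against known amplitudes.

Amplitude convention: the per-signal ``amplitudes`` passed to
:func:`synthesize_fid` are the integrated absorption-mode areas, in
ppm·intensity units, that the signals exhibit after ``transform`` — so
quantified multiplet areas can be compared to them directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import MultipletModel, SignalCatalog
from .nmr import DSS_REFERENCE_PPM, AcquisitionParams, FID

__all__ = [
    "FieldSpec",
    "BimodalSpec",
    "sample_positions",
    "positions_to_local_meters",
    "simulate_grf",
    "simulate_bimodal_field",
    "synthesize_fid",
    "make_survey",
]

#: meters per degree of latitude on the WGS84 sphere-of-reference
M_PER_DEG_LAT = 111_320.0


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of a synthetic georeferenced field survey."""

    n_sites: int = 60
    extent_m: tuple[float, float] = (500.0, 200.0)
    corr_length_m: float = 30.0
    sill: float = 1.0
    nugget: float = 0.1
    mean: float = 0.0
    origin_deg: tuple[float, float] = (40.82, 16.08)
    gps_sigma_m: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 3:
            raise ValueError("n_sites must be >= 3")
        if self.extent_m[0] <= 0 or self.extent_m[1] <= 0:
            raise ValueError("extent must be positive")
        if self.corr_length_m <= 0:
            raise ValueError("corr_length_m must be > 0")
        if self.sill < 0 or self.nugget < 0 or self.sill + self.nugget <= 0:
            raise ValueError("need sill >= 0, nugget >= 0, sill + nugget > 0")
        if self.gps_sigma_m < 0:
            raise ValueError("gps_sigma_m must be >= 0")


@dataclass(frozen=True)
class BimodalSpec:
    """Spatially clustered two-mode mixture on the standardized scale."""

    mode_lo: float = -0.5
    mode_hi: float = 2.0
    frac_hi: float = 0.3
    cluster_length_m: float = 60.0

    def __post_init__(self):
        if not self.mode_lo < self.mode_hi:
            raise ValueError("mode_lo must be < mode_hi")
        if not 0.0 < self.frac_hi < 1.0:
            raise ValueError("frac_hi must lie in (0, 1)")
        if self.cluster_length_m <= 0:
            raise ValueError("cluster_length_m must be > 0")


def _grid_layout(n: int, width: float, height: float) -> np.ndarray:
    """Cell centres of a near-square grid covering the extent, row-major."""
    nc = max(1, int(np.ceil(np.sqrt(n * width / height))))
    nr = int(np.ceil(n / nc))
    xs = (np.arange(nc) + 0.5) * width / nc
    ys = (np.arange(nr) + 0.5) * height / nr
    xy = np.array([(x, y) for y in ys for x in xs])
    return xy[:n]


def sample_positions(spec: FieldSpec) -> np.ndarray:
    """Georeferenced sampling positions, shape (n_sites, 2) = (lat, lon) deg.

    Sites sit on a jittered quasi-grid inside the extent; the jitter is
    isotropic Gaussian with standard deviation ``gps_sigma_m`` converted to
    degrees with the local metric at the origin (1° lat ≈ 111 320 m,
    longitude scaled by cos(lat)).
    """
    rng = np.random.default_rng(spec.seed)
    xy = _grid_layout(spec.n_sites, *spec.extent_m)
    xy = xy + rng.normal(0.0, spec.gps_sigma_m, size=xy.shape)
    lat0, lon0 = spec.origin_deg
    lat = lat0 + xy[:, 1] / M_PER_DEG_LAT
    lon = lon0 + xy[:, 0] / (M_PER_DEG_LAT * np.cos(np.deg2rad(lat0)))
    return np.column_stack([lat, lon])


def positions_to_local_meters(latlon: np.ndarray,
                              origin_deg: tuple[float, float]) -> np.ndarray:
    """Convert (lat, lon) degrees to local (x, y) meters at ``origin_deg``."""
    latlon = np.asarray(latlon, dtype=float)
    lat0, lon0 = origin_deg
    x = (latlon[:, 1] - lon0) * M_PER_DEG_LAT * np.cos(np.deg2rad(lat0))
    y = (latlon[:, 0] - lat0) * M_PER_DEG_LAT
    return np.column_stack([x, y])


def _exp_covariance(positions_m: np.ndarray, sill: float, nugget: float,
                    corr_length_m: float) -> np.ndarray:
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(positions_m))
    return sill * np.exp(-d / corr_length_m) + nugget * np.eye(len(positions_m))


def simulate_grf(positions_m: np.ndarray, spec: FieldSpec,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """One draw of the stationary GRF with exponential covariance.

    Covariance between sites i ≠ j is sill·exp(−d_ij/ℓ); the nugget adds
    site-level white variance on the diagonal. The draw is exact via
    Cholesky factorization of the dense site covariance.
    """
    positions_m = np.asarray(positions_m, dtype=float)
    if positions_m.ndim != 2 or len(positions_m) < 2:
        raise ValueError("need at least 2 positions with (x, y) columns")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cov = _exp_covariance(positions_m, spec.sill, spec.nugget, spec.corr_length_m)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        eigmin = float(np.linalg.eigvalsh(cov)[0])
        raise np.linalg.LinAlgError(
            f"site covariance not positive definite (min eigenvalue "
            f"{eigmin:.3e}); increase the nugget"
        ) from None
    return spec.mean + chol @ rng.standard_normal(len(positions_m))


def simulate_bimodal_field(positions_m: np.ndarray, spec: FieldSpec,
                           bspec: BimodalSpec,
                           rng: np.random.Generator | None = None,
                           return_membership: bool = False):
    """Spatially clustered bimodal field.

    A latent unit-sill GRF with correlation length ``cluster_length_m`` is
    thresholded at its empirical (1 − frac_hi) quantile: sites above the
    threshold take ``mode_hi``, the rest ``mode_lo``. Within-mode scatter
    is white noise with standard deviation sqrt(spec.nugget).

    Returns the field, plus the boolean high-mode membership when
    ``return_membership`` is set.
    """
    positions_m = np.asarray(positions_m, dtype=float)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    latent_spec = FieldSpec(
        n_sites=max(len(positions_m), 3), extent_m=spec.extent_m,
        corr_length_m=bspec.cluster_length_m, sill=1.0, nugget=1e-9,
        mean=0.0, origin_deg=spec.origin_deg, gps_sigma_m=0.0, seed=spec.seed,
    )
    latent = simulate_grf(positions_m, latent_spec, rng=rng)
    threshold = np.quantile(latent, 1.0 - bspec.frac_hi)
    hi = latent > threshold
    values = np.where(hi, bspec.mode_hi, bspec.mode_lo)
    values = values + np.sqrt(spec.nugget) * rng.standard_normal(len(values))
    if return_membership:
        return values, hi
    return values


# ---------------------------------------------------------------------------
# synthetic spectra
# ---------------------------------------------------------------------------

def synthesize_fid(catalog: SignalCatalog, amplitudes, acq: AcquisitionParams,
                   seed: int | None = None, noise_sd: float = 0.0,
                   natural_linewidth_hz: float = 0.8,
                   dss_amplitude: float = 1.0,
                   dss_offset_ppm: float = 0.0) -> FID:
    """Complex time-domain signal for a catalog plus a DSS reference line.

    Each multiplet component contributes a decaying complex exponential at
    its chemical-shift frequency; the decay rate corresponds to
    ``natural_linewidth_hz`` (the Lorentzian FWHM before apodization).
    ``amplitudes`` (one per catalog entry, ≥ 0) are absorption-line areas
    in ppm units after ``transform`` — see the module docstring. The DSS
    line is synthesized at 0.015 + ``dss_offset_ppm`` so a deliberate
    miscalibration can be planted; complex Gaussian noise of standard
    deviation ``noise_sd`` (in FID units) is added when requested.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (len(catalog),):
        raise ValueError(f"need {len(catalog)} amplitudes, got {amplitudes.shape}")
    if np.any(amplitudes < 0) or dss_amplitude < 0:
        raise ValueError("amplitudes must be >= 0")
    if acq.dwell_time_s <= 0:
        raise ValueError("inconsistent acquisition parameters: dwell time <= 0")
    if natural_linewidth_hz <= 0:
        raise ValueError("natural_linewidth_hz must be > 0")

    t = np.arange(acq.n_points) / acq.sweep_width_hz
    fid = np.zeros(acq.n_points, dtype=complex)
    decay = np.exp(-np.pi * natural_linewidth_hz * t)

    # area convention: transform() scales by the dwell time, so a complex
    # amplitude A yields an absorption line of area A/2 in Hz units, i.e.
    # A / (2 f_MHz) in ppm units.
    area_to_amp = 2.0 * acq.spectrometer_freq_mhz

    lines: list[tuple[float, float]] = []   # (shift_ppm, complex amplitude)
    for entry, area in zip(catalog, amplitudes):
        model = MultipletModel.from_entry(entry)
        for off_hz, wt in zip(model.component_offsets_hz(),
                              model.component_weights()):
            lines.append((entry.shift_ppm + off_hz / acq.spectrometer_freq_mhz,
                          area * wt * area_to_amp))
    lines.append((DSS_REFERENCE_PPM + dss_offset_ppm,
                  dss_amplitude * area_to_amp))

    for shift_ppm, amp in lines:
        f_hz = (shift_ppm - acq.center_ppm) * acq.spectrometer_freq_mhz
        fid += amp * np.exp(2j * np.pi * f_hz * t) * decay

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fid = fid + noise_sd * (rng.standard_normal(acq.n_points)
                                + 1j * rng.standard_normal(acq.n_points))
    return FID(fid, acq)


# ---------------------------------------------------------------------------
# full synthetic survey
# ---------------------------------------------------------------------------

def make_survey(field_spec: FieldSpec, catalog: SignalCatalog,
                bimodal_for: dict[str, BimodalSpec] | None = None,
                base_amplitude: float = 1.5, field_scale: float = 0.3,
                noise_sd: float = 0.0, acq: AcquisitionParams | None = None):
    """Generate a full synthetic survey: positions, true fields and FIDs.

    Every catalog metabolite receives a GRF concentration field (amplitude
    = base + scale · z, clipped to stay positive); metabolites listed in
    ``bimodal_for`` instead receive a clustered bimodal field mapped
    affinely onto positive amplitudes. Returns a dict with positions
    (lat/lon), local meters, the true amplitude matrix, high-mode
    memberships, and the per-site FIDs keyed ``site_000``, ….
    """
    import pandas as pd

    bimodal_for = bimodal_for or {}
    unknown = set(bimodal_for) - set(catalog.compounds())
    if unknown:
        raise ValueError(f"bimodal_for names not in catalog: {sorted(unknown)}")
    if acq is None:
        acq = AcquisitionParams()

    rng = np.random.default_rng(field_spec.seed)
    latlon = sample_positions(field_spec)
    xy = positions_to_local_meters(latlon, field_spec.origin_deg)

    truth = {}
    membership = {}
    for name in catalog.compounds():
        if name in bimodal_for:
            z, hi = simulate_bimodal_field(xy, field_spec, bimodal_for[name],
                                           rng=rng, return_membership=True)
            membership[name] = hi
        else:
            z = simulate_grf(xy, field_spec, rng=rng)
        amp = np.clip(base_amplitude + field_scale * z, 0.05, None)
        truth[name] = amp
    truth = pd.DataFrame(truth, index=[f"site_{i:03d}" for i in range(len(xy))])

    fids = {}
    for i, site in enumerate(truth.index):
        fids[site] = synthesize_fid(
            catalog, truth.loc[site].to_numpy(), acq,
            seed=int(rng.integers(2**31 - 1)), noise_sd=noise_sd,
        )
    return {
        "latlon": latlon,
        "xy_m": xy,
        "truth": truth,
        "membership": membership,
        "fids": fids,
        "acq": acq,
    }
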