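"""WGS84 <-> UTM coordinate projection.

Forward and inverse transverse-Mercator projection on the WGS84 ellipsoid
using the Krüger series in the third flattening n, truncated at order n**6.
At this order the series error is far below a millimetre anywhere within a
UTM zone (and several zones to either side), which is orders of magnitude
below the ~3 m GPS error of field-survey positions.

UTM conventions: scale factor k0 = 0.9996 on the central meridian, false
easting 500 000 m, false northing 0 m (northern hemisphere) or
10 000 000 m (southern).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "project_wgs84_to_utm",
    "utm_to_wgs84",
    "utm_central_meridian_deg",
]

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_K0 = 0.9996
_FALSE_EASTING = 500_000.0
_FALSE_NORTHING_SOUTH = 10_000_000.0

_E = math.sqrt(_F * (2.0 - _F))  # first eccentricity
_N3 = _F / (2.0 - _F)            # third flattening

# Rectifying radius: A = a/(1+n) * (1 + n^2/4 + n^4/64 + n^6/256)
_RECT_RADIUS = _A / (1.0 + _N3) * (
    1.0 + _N3**2 / 4.0 + _N3**4 / 64.0 + _N3**6 / 256.0
)

# Krüger alpha (forward) coefficients, order n^6.
_ALPHA = (
    _N3 / 2.0 - 2.0 / 3.0 * _N3**2 + 5.0 / 16.0 * _N3**3
    + 41.0 / 180.0 * _N3**4 - 127.0 / 288.0 * _N3**5
    + 7891.0 / 37800.0 * _N3**6,
    13.0 / 48.0 * _N3**2 - 3.0 / 5.0 * _N3**3 + 557.0 / 1440.0 * _N3**4
    + 281.0 / 630.0 * _N3**5 - 1983433.0 / 1935360.0 * _N3**6,
    61.0 / 240.0 * _N3**3 - 103.0 / 140.0 * _N3**4
    + 15061.0 / 26880.0 * _N3**5 + 167603.0 / 181440.0 * _N3**6,
    49561.0 / 161280.0 * _N3**4 - 179.0 / 168.0 * _N3**5
    + 6601661.0 / 7257600.0 * _N3**6,
    34729.0 / 80640.0 * _N3**5 - 3418889.0 / 1995840.0 * _N3**6,
    212378941.0 / 319334400.0 * _N3**6,
)

# Krüger beta (inverse) coefficients, order n^6.
_BETA = (
    _N3 / 2.0 - 2.0 / 3.0 * _N3**2 + 37.0 / 96.0 * _N3**3
    - 1.0 / 360.0 * _N3**4 - 81.0 / 512.0 * _N3**5
    + 96199.0 / 604800.0 * _N3**6,
    1.0 / 48.0 * _N3**2 + 1.0 / 15.0 * _N3**3 - 437.0 / 1440.0 * _N3**4
    + 46.0 / 105.0 * _N3**5 - 1118711.0 / 3870720.0 * _N3**6,
    17.0 / 480.0 * _N3**3 - 37.0 / 840.0 * _N3**4
    - 209.0 / 4480.0 * _N3**5 + 5569.0 / 90720.0 * _N3**6,
    4397.0 / 161280.0 * _N3**4 - 11.0 / 504.0 * _N3**5
    - 830251.0 / 7257600.0 * _N3**6,
    4583.0 / 161280.0 * _N3**5 - 108847.0 / 3991680.0 * _N3**6,
    20648693.0 / 638668800.0 * _N3**6,
)


def utm_central_meridian_deg(zone: int) -> float:
    """Central meridian of a UTM zone in degrees east (zone 34 -> 21°E)."""
    if not 1 <= zone <= 60:
        raise ValueError(f"UTM zone must be in 1..60, got {zone}")
    return -183.0 + 6.0 * zone


def project_wgs84_to_utm(lat_deg, lon_deg, zone: int = 34, hemisphere: str = "N"):
    """Project WGS84 geographic coordinates to UTM easting/northing in meters.

    Parameters
    ----------
    lat_deg, lon_deg : scalar or array_like
        Geodetic latitude and longitude in decimal degrees.
    zone : int
        UTM zone (default 34, central meridian 21°E — EPSG:32634 with the
        default northern hemisphere).
    hemisphere : {"N", "S"}
        Selects the false northing.

    Returns
    -------
    (easting_m, northing_m) : ndarray or float pair
    """
    lat = np.asarray(lat_deg, dtype=float)
    lon = np.asarray(lon_deg, dtype=float)
    if np.any(np.abs(lat) >= 84.0):
        raise ValueError("latitude out of the UTM validity range (|lat| < 84°)")
    if hemisphere not in ("N", "S"):
        raise ValueError(f"hemisphere must be 'N' or 'S', got {hemisphere!r}")

    phi = np.deg2rad(lat)
    lam = np.deg2rad(lon - utm_central_meridian_deg(zone))

    # Conformal latitude via tau' = sinh(psi), psi the isometric latitude.
    sphi = np.sin(phi)
    t = np.sinh(np.arctanh(sphi) - _E * np.arctanh(_E * sphi))

    xi_p = np.arctan2(t, np.cos(lam))
    eta_p = np.arcsinh(np.sin(lam) / np.hypot(t, np.cos(lam)))

    xi = xi_p.copy()
    eta = eta_p.copy()
    for j, a in enumerate(_ALPHA, start=1):
        xi = xi + a * np.sin(2 * j * xi_p) * np.cosh(2 * j * eta_p)
        eta = eta + a * np.cos(2 * j * xi_p) * np.sinh(2 * j * eta_p)

    easting = _FALSE_EASTING + _K0 * _RECT_RADIUS * eta
    northing = _K0 * _RECT_RADIUS * xi
    if hemisphere == "S":
        northing = northing + _FALSE_NORTHING_SOUTH
    if easting.ndim == 0:
        return float(easting), float(northing)
    return easting, northing


def utm_to_wgs84(easting_m, northing_m, zone: int = 34, hemisphere: str = "N"):
    """Inverse UTM projection back to WGS84 (lat, lon) in decimal degrees."""
    e = np.asarray(easting_m, dtype=float)
    n = np.asarray(northing_m, dtype=float)
    if hemisphere == "S":
        n = n - _FALSE_NORTHING_SOUTH
    elif hemisphere != "N":
        raise ValueError(f"hemisphere must be 'N' or 'S', got {hemisphere!r}")

    xi = n / (_K0 * _RECT_RADIUS)
    eta = (e - _FALSE_EASTING) / (_K0 * _RECT_RADIUS)

    xi_p = xi.copy()
    eta_p = eta.copy()
    for j, b in enumerate(_BETA, start=1):
        xi_p = xi_p - b * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_p = eta_p - b * np.cos(2 * j * xi) * np.sinh(2 * j * eta)

    # tau' on the conformal sphere, then Newton back to geodetic latitude.
    tau_p = np.sin(xi_p) / np.hypot(np.sinh(eta_p), np.cos(xi_p))
    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))

    tau = tau_p.copy()
    for _ in range(8):
        sig = np.sinh(_E * np.arctanh(_E * tau / np.hypot(1.0, tau)))
        f_tau = tau * np.hypot(1.0, sig) - sig * np.hypot(1.0, tau) - tau_p
        d_tau = (
            (np.hypot(1.0, sig) * np.hypot(1.0, tau) - sig * tau)
            * (1.0 - _E**2)
            * np.hypot(1.0, tau)
            / (1.0 + (1.0 - _E**2) * tau**2)
        )
        tau = tau - f_tau / d_tau

    lat = np.rad2deg(np.arctan(tau))
    lon = np.rad2deg(lam) + utm_central_meridian_deg(zone)
    if lat.ndim == 0:
        return float(lat), float(lon)
    return lat, lon
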