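"""Mixed-layer depth from the buoyancy-frequency maximum, with a quality
index.

The mixed layer is taken as the quasi-homogeneous near-surface layer; its
depth (MLD) is estimated as the depth of the maximum buoyancy frequency

    N² = (g / ρ₀) · Δρ / Δz        [s⁻²]

evaluated on interior layer midpoints of a density profile (g = 9.81 m s⁻²,
ρ₀ = 1025 kg m⁻³; density increasing downward gives positive N²).  A
quality index grades how homogeneous the layer above the candidate MLD is
relative to the layer extending to 1.5×MLD:

    QI = 1 − rms(ρ − mean ρ | surface→MLD) / rms(ρ − mean ρ | surface→1.5·MLD)

QI near 1 means the surface layer is uniform and the MLD sits at its lower
boundary; QI ≤ 0.5 means no mixed layer could be resolved.  The method uses
only homogeneity, not stratification strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidInputError

G = 9.81            # m s⁻², gravitational acceleration
RHO_0 = 1025.0      # kg m⁻³, reference density

QI_CERTAIN = 0.8    # QI above which the estimate is "certain"
QI_USABLE = 0.5     # QI above which the estimate is usable at all

# linear equation of state, for profiles supplied as (T, S) rather than
# density: rho = RHO_0 * (1 - ALPHA*(T - T_REF) + BETA*(S - S_REF))
EOS_ALPHA = 1.7e-4  # K⁻¹, thermal expansion
EOS_BETA = 7.6e-4   # PSU⁻¹, haline contraction
EOS_T_REF = 0.0     # °C
EOS_S_REF = 34.0    # PSU


@dataclass(frozen=True)
class MLDEstimate:
    """Mixed-layer depth (m), quality index and quality category."""

    mld_m: float
    qi: float
    category: str  # "certain" | "uncertain" | "undetermined"


def density_from_ts(temperature: np.ndarray, salinity: np.ndarray
                    ) -> np.ndarray:
    """In-situ density (kg m⁻³) from a linear equation of state.

    Adequate for MLD work, which depends only on the vertical *structure*
    of density, not its absolute calibration.
    """
    t = np.asarray(temperature, dtype=float)
    s = np.asarray(salinity, dtype=float)
    return RHO_0 * (1.0 - EOS_ALPHA * (t - EOS_T_REF)
                    + EOS_BETA * (s - EOS_S_REF))


def _validate_profile(depth: np.ndarray, density: np.ndarray,
                      min_levels: int = 4) -> tuple[np.ndarray, np.ndarray]:
    depth = np.asarray(depth, dtype=float)
    density = np.asarray(density, dtype=float)
    if depth.ndim != 1 or depth.shape != density.shape:
        raise InvalidInputError("depth and density must be equal-length 1-D")
    if len(depth) < min_levels:
        raise InsufficientDataError(
            f"profile needs >= {min_levels} levels, got {len(depth)}")
    if not np.all(np.isfinite(depth)) or not np.all(np.isfinite(density)):
        raise InvalidInputError("profile values must be finite")
    if np.any(np.diff(depth) <= 0):
        raise InvalidInputError("depths must be strictly increasing")
    return depth, density


def buoyancy_frequency(depth: np.ndarray, density: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """N² on interior layer midpoints.

    Returns ``(mid_depth, n2)`` with N² = (g/ρ₀)·Δρ/Δz per layer; positive
    where density increases downward (statically stable), negative across
    inversions.
    """
    depth = np.asarray(depth, dtype=float)
    density = np.asarray(density, dtype=float)
    if len(depth) < 2:
        raise InsufficientDataError("N² needs at least 2 levels")
    if np.any(np.diff(depth) <= 0):
        raise InvalidInputError("depths must be strictly increasing")
    dz = np.diff(depth)
    drho = np.diff(density)
    n2 = (G / RHO_0) * drho / dz
    mid = 0.5 * (depth[:-1] + depth[1:])
    return mid, n2


def _rms_about_mean(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def estimate_mld(depth: np.ndarray, density: np.ndarray,
                 qi_threshold: float = QI_USABLE,
                 smooth_n2: bool = False) -> MLDEstimate:
    """Estimate the mixed-layer depth of one profile.

    Parameters
    ----------
    depth, density
        Profile levels (m, positive downward, strictly increasing) and
        potential density anomaly or in-situ density (kg m⁻³); at least 4
        levels.
    qi_threshold
        QI at or below which the estimate is marked ``undetermined`` (the
        MLD value is still reported, flagged unusable).
    smooth_n2
        Apply a 3-point running mean to N² before locating its maximum.
        Default off: least processing.

    Notes
    -----
    Ties in the N² maximum are broken toward the shallowest layer — the
    mixed layer is a near-surface property.  If the profile is shallower
    than 1.5×MLD the QI denominator uses the available extent.  A perfectly
    homogeneous profile has a 0/0 quality ratio, resolved to QI = 0
    (undetermined): there is no resolvable mixed-layer base.
    """
    depth, density = _validate_profile(depth, density)
    mid, n2 = buoyancy_frequency(depth, density)
    if smooth_n2 and len(n2) >= 3:
        kernel = np.ones(3) / 3.0
        n2 = np.convolve(n2, kernel, mode="same")
        # edges of the running mean average only 2 points; rescale
        n2[0] *= 3.0 / 2.0
        n2[-1] *= 3.0 / 2.0
    # shallowest maximum, with a relative tolerance so exact ties are not
    # decided by floating-point rounding
    n2max = n2.max()
    tol = 1e-9 * max(abs(n2max), 1e-30)
    imax = int(np.flatnonzero(n2 >= n2max - tol)[0])
    mld = float(mid[imax])

    in_ml = depth <= mld
    in_ref = depth <= 1.5 * mld
    if in_ml.sum() < 2 or in_ref.sum() < 2:
        qi = 0.0  # too few levels above the candidate base to grade it
    else:
        num = _rms_about_mean(density[in_ml])
        den = _rms_about_mean(density[in_ref])
        qi = 0.0 if den == 0.0 else 1.0 - num / den
    qi = float(np.clip(qi, 0.0, 1.0))

    if qi > QI_CERTAIN:
        category = "certain"
    elif qi > qi_threshold:
        category = "uncertain"
    else:
        category = "undetermined"
    return MLDEstimate(mld, qi, category)


def estimate_mld_ts(depth: np.ndarray, temperature: np.ndarray,
                    salinity: np.ndarray,
                    qi_threshold: float = QI_USABLE,
                    smooth_n2: bool = False) -> MLDEstimate:
    """MLD from a temperature/salinity profile via the linear equation of
    state (see :func:`density_from_ts`)."""
    return estimate_mld(depth, density_from_ts(temperature, salinity),
                        qi_threshold=qi_threshold, smooth_n2=smooth_n2)
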