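"""Specular reflectivity of layered media.

The reflectivity of a slab stack is computed with the Abelès
characteristic-matrix formalism (exactly equivalent to the Parratt
recursion) with interfacial roughness included as Nevot-Croce attenuation
of the interface Fresnel coefficients, appropriate for error-function
density profiles.  Instrument resolution is a Gaussian smearing in Q whose
full width at half maximum is dQ = (dQ/Q) * Q, constant in relative terms
across the curve, as is conventional for time-of-flight reflectometers.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "abeles",
    "smear_resolution",
    "smeared_reflectivity",
    "critical_edge",
    "q_from_geometry",
    "FWHM_TO_SIGMA",
]

#: Conversion from Gaussian FWHM to standard deviation.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548

# Gauss-Legendre quadrature for the smearing kernel: 17 nodes over +/- 4
# sigma resolve the Gaussian-weighted integral of a smooth reflectivity
# curve to ~1e-7 relative; the data-array smearing uses a denser rule.
_GL_HALF_WIDTH = 4.0


def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


_GL_FAST = _leggauss(17)


def abeles(
    q: np.ndarray,
    sld: np.ndarray,
    thickness: np.ndarray,
    roughness: np.ndarray,
    scale: float = 1.0,
    background: float = 0.0,
) -> np.ndarray:
    """Specular reflectivity R(Q) of a slab stack.

    Parameters
    ----------
    q :
        Momentum transfer, Å^-1 (positive).
    sld, thickness, roughness :
        Per-slab arrays ordered from the incident medium (first, semi-
        infinite) to the backing medium (last, semi-infinite); SLD in Å^-2,
        thickness in Å (ignored for the half-spaces), and ``roughness[j]``
        the error-function width of the interface between slabs j-1 and j
        (``roughness[0]`` unused).
    scale, background :
        Returned reflectivity is ``scale * R + background``.

    The wavevector in slab j is k_j = sqrt(k_0^2 - 4 pi (rho_j - rho_0));
    below the critical edge k_j is imaginary and total reflection emerges
    naturally from the matrix algebra.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    sld = np.asarray(sld, dtype=complex)
    thickness = np.asarray(thickness, dtype=float)
    roughness = np.asarray(roughness, dtype=float)
    n = len(sld)
    if n < 2:
        raise ValueError("need at least incident and backing half-spaces")

    k0 = q[:, None] / 2.0
    # wavevector in each slab relative to the incident medium
    k = np.sqrt(k0**2 - 4.0 * np.pi * (sld[None, :] - sld[0]) + 0j)

    # resultant matrix elements, accumulated across interfaces
    m00 = np.ones(len(q), dtype=complex)
    m01 = np.zeros(len(q), dtype=complex)
    m10 = np.zeros(len(q), dtype=complex)
    m11 = np.ones(len(q), dtype=complex)
    for j in range(n - 1):
        kj, kj1 = k[:, j], k[:, j + 1]
        r = (kj - kj1) / (kj + kj1) * np.exp(-2.0 * kj * kj1 * roughness[j + 1] ** 2)
        if j > 0:
            e_plus = np.exp(1j * (kj * thickness[j]))
            e_minus = 1.0 / e_plus
        else:
            e_plus = np.ones_like(kj)
            e_minus = e_plus
        a00 = e_plus
        a01 = r * e_plus
        a10 = r * e_minus
        a11 = e_minus
        m00, m01, m10, m11 = (
            m00 * a00 + m01 * a10,
            m00 * a01 + m01 * a11,
            m10 * a00 + m11 * a10,
            m10 * a01 + m11 * a11,
        )
    refl = np.abs(m10 / m00) ** 2
    return scale * np.real(refl) + background


def critical_edge(rho_in: float, rho_out: float) -> float:
    """Critical momentum transfer Qc = sqrt(16 pi (rho_out - rho_in)).

    Total external reflection occurs below Qc when the backing medium is
    optically denser (rho_out > rho_in); otherwise there is no edge and 0 is
    returned.
    """
    delta = rho_out - rho_in
    if delta <= 0:
        return 0.0
    return float(np.sqrt(16.0 * np.pi * delta))


def q_from_geometry(theta_deg: np.ndarray, wavelength: np.ndarray) -> np.ndarray:
    """Q = 4 pi sin(theta) / lambda for glancing angle theta (degrees)."""
    return 4.0 * np.pi * np.sin(np.radians(theta_deg)) / np.asarray(wavelength)


# ---------------------------------------------------------------------------
# Resolution smearing
# ---------------------------------------------------------------------------

def _kernel_nodes(
    q: np.ndarray, sigma: np.ndarray, rule: tuple[np.ndarray, np.ndarray] = _GL_FAST
) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes (nq, nodes) and normalized Gaussian weights."""
    gl_x, gl_w = rule
    u = gl_x * _GL_HALF_WIDTH  # in units of sigma
    w = gl_w * _GL_HALF_WIDTH
    gauss = np.exp(-0.5 * u**2) / np.sqrt(2.0 * np.pi)
    weights = w * gauss
    weights = weights / weights.sum()  # renormalize the truncated kernel
    nodes = q[:, None] + sigma[:, None] * u[None, :]
    return nodes, weights


def _sigma_from(q: np.ndarray, dq_over_q: float, dq: np.ndarray | None) -> np.ndarray:
    if dq is not None:
        return np.asarray(dq, dtype=float) * FWHM_TO_SIGMA
    if dq_over_q < 0:
        raise ValueError("dq_over_q must be non-negative")
    return dq_over_q * q * FWHM_TO_SIGMA


def smear_resolution(
    r: np.ndarray,
    q: np.ndarray,
    dq_over_q: float = 0.04,
    dq: np.ndarray | None = None,
) -> np.ndarray:
    """Convolve a sampled R(Q) with the Gaussian resolution kernel.

    ``dq_over_q`` (or a per-point ``dq`` column, which takes precedence) is
    interpreted as the kernel FWHM.  The integral is a dense trapezoidal
    quadrature over +/- 4 sigma with the curve linearly interpolated
    between samples; nodes falling outside the sampled range are dropped
    and the kernel renormalized, which reduces to the identity at the
    endpoints of a sharply truncated kernel.
    """
    q = np.asarray(q, dtype=float)
    r = np.asarray(r, dtype=float)
    sigma = _sigma_from(q, dq_over_q, dq)
    if np.all(sigma == 0):
        return r.copy()
    u = np.linspace(-_GL_HALF_WIDTH, _GL_HALF_WIDTH, 801)
    kernel = np.exp(-0.5 * u**2)
    du = u[1] - u[0]
    simpson = np.ones_like(u)
    simpson[1:-1:2] = 4.0
    simpson[2:-1:2] = 2.0
    weights = kernel * simpson * du / 3.0
    nodes = q[:, None] + sigma[:, None] * u[None, :]
    inside = (nodes >= q[0]) & (nodes <= q[-1])
    rv = np.interp(nodes, q, r)
    wsum = (weights[None, :] * inside).sum(axis=1)
    smeared = (rv * weights[None, :] * inside).sum(axis=1) / wsum
    # zero-sigma points pass through untouched
    return np.where(sigma > 0, smeared, r)


def smeared_reflectivity(
    q: np.ndarray,
    sld: np.ndarray,
    thickness: np.ndarray,
    roughness: np.ndarray,
    scale: float = 1.0,
    background: float = 0.0,
    dq_over_q: float = 0.04,
    dq: np.ndarray | None = None,
) -> np.ndarray:
    """Resolution-smeared slab reflectivity, evaluated exactly at the nodes.

    Unlike :func:`smear_resolution` this does not interpolate: the model is
    evaluated at every quadrature node, which is the form used by the
    forward model during fitting and synthetic-data generation.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    sigma = _sigma_from(q, dq_over_q, dq)
    if np.all(sigma == 0):
        return abeles(q, sld, thickness, roughness, scale, background)
    nodes, weights = _kernel_nodes(q, sigma)
    flat = np.clip(nodes.ravel(), 1e-8, None)
    r = abeles(flat, sld, thickness, roughness).reshape(nodes.shape)
    return scale * (r * weights[None, :]).sum(axis=1) + background
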