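"""Optical constants and the modified Beer–Lambert law (MBLL).

Near-infrared light attenuation through cortical tissue is modelled as

    OD_lambda(t) = [eps_lambda,HbO * dHbO(t) + eps_lambda,HbR * dHbR(t)] * d * DPF_lambda

where OD is optical density (dimensionless), eps are molar extinction
coefficients (cm^-1 / (mol/L)), d is the source-detector separation (cm), DPF
is the differential pathlength factor, and dHbO/dHbR are concentration changes
(mol/L).  With measurements at two wavelengths the 2x2 system is inverted per
time point to recover the two chromophore changes.

Extinction coefficients are the compiled Gratzer/Cope values in widespread use
in fNIRS software (units cm^-1/M); the DPF default follows the general
wavelength- and age-dependent polynomial fit of Scholkmann & Wolf (2013).
"""

from __future__ import annotations

import numpy as np

# cm^-1 / (mol/L), rows: wavelength, columns: (HbO, HbR)
EXTINCTION = {
    760.0: (1486.5865, 3843.707),
    850.0: (2526.391, 1798.643),
}

DEFAULT_WAVELENGTHS = (760.0, 850.0)

# Scholkmann & Wolf (2013) general DPF fit: DPF(age, lambda)
_DPF_COEF = dict(alpha=223.3, beta=0.05624, gamma=0.8493,
                 delta=-5.723e-7, eps=0.001245, zeta=-0.9025)


def dpf(wavelength_nm: float, age_years: float) -> float:
    """Differential pathlength factor for a given wavelength and age."""
    c = _DPF_COEF
    lam = float(wavelength_nm)
    return (c["alpha"] + c["beta"] * age_years ** c["gamma"]
            + c["delta"] * lam ** 3 + c["eps"] * lam ** 2 + c["zeta"] * lam)


def extinction_matrix(wavelengths=DEFAULT_WAVELENGTHS) -> np.ndarray:
    """2x2 matrix of extinction coefficients, rows per wavelength, cols (HbO, HbR)."""
    try:
        rows = [EXTINCTION[float(w)] for w in wavelengths]
    except KeyError as exc:  # pragma: no cover - configuration error path
        raise ValueError(f"no extinction coefficients tabulated for {exc} nm") from exc
    e = np.asarray(rows, dtype=float)
    if abs(np.linalg.det(e)) < 1e-9:
        raise ValueError("extinction matrix is singular; wavelengths must differ")
    return e


def pathlengths(distance_cm: float, age_years: float,
                wavelengths=DEFAULT_WAVELENGTHS) -> np.ndarray:
    """Effective photon pathlength L_lambda = distance * DPF_lambda, in cm."""
    if distance_cm <= 0:
        raise ValueError("source-detector distance must be positive")
    return np.array([distance_cm * dpf(w, age_years) for w in wavelengths])


def mbll_forward(hbo_uM: np.ndarray, hbr_uM: np.ndarray, distance_cm: float,
                 age_years: float, wavelengths=DEFAULT_WAVELENGTHS) -> np.ndarray:
    """Forward MBLL: concentration changes (µM) -> optical density per wavelength.

    Returns an array of shape (n_wavelengths,) + hbo.shape.
    """
    e = extinction_matrix(wavelengths)
    ell = pathlengths(distance_cm, age_years, wavelengths)
    conc_M = np.stack([np.asarray(hbo_uM), np.asarray(hbr_uM)]) * 1e-6
    # od[w] = (e[w,0]*hbo + e[w,1]*hbr) * L[w]
    return np.einsum("wc,c...->w...", e, conc_M) * ell.reshape((-1,) + (1,) * conc_M[0].ndim)


def mbll_inverse(od: np.ndarray, distance_cm: float, age_years: float,
                 wavelengths=DEFAULT_WAVELENGTHS) -> tuple[np.ndarray, np.ndarray]:
    """Invert the MBLL: optical density per wavelength -> (dHbO, dHbR) in µM.

    `od` has shape (n_wavelengths,) + signal shape.
    """
    e = extinction_matrix(wavelengths)
    ell = pathlengths(distance_cm, age_years, wavelengths)
    a = e * ell[:, None]          # 2x2 system matrix
    inv = np.linalg.inv(a)
    conc_M = np.einsum("cw,w...->c...", inv, np.asarray(od, dtype=float))
    hbo, hbr = conc_M * 1e6
    return hbo, hbr
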