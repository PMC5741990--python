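"""Layer sensitivity factors and the conversion to hemoglobin concentrations.

The sensitivity factor of layer k is SF_k = -d<t>/dmua_k, the (positive)
picosecond shift of the mean time of flight per unit absorption increase in
that layer.  Layer SFs come from the layered Monte Carlo by finite
differences on shared photon paths (correlated estimator); the
intracerebral SF is the sum over layers 5-10 (depths 0.8-2.0 cm of the
default stack).  Two-wavelength absorption changes recovered from d<t> are
then inverted through the extinction-coefficient matrix to oxy- and
deoxyhemoglobin concentration changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transport import (
    DetectionGeometry,
    OpticalLayerStack,
    PhotonBank,
    run_transport,
)

__all__ = [
    "SensitivityProfile",
    "ExtinctionTable",
    "run_sensitivity_mc",
    "sensitivity_from_bank",
    "intracerebral_sf",
    "delta_mua_from_dtof",
    "hemoglobin_from_mua",
]


class SensitivityError(ValueError):
    pass


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction coefficients of HbO2 and HbR at the two wavelengths.

    ``coefficients[wl] = (eps_HbO, eps_HbR)`` in 1/(M cm), decadic, from the
    standard compiled hemoglobin spectra (Prahl / OMLC compilation).
    ``row`` converts to natural-log absorption per uM so that
    dmua(wl) [1/cm] = row(wl) . (dHbO, dHbR) [uM].
    """

    coefficients: dict[float, tuple[float, float]] = field(
        default_factory=lambda: {760.0: (586.0, 1548.52),
                                 830.0: (974.0, 693.04)}
    )
    source: str = "OMLC compiled hemoglobin spectra"

    def row(self, wavelength_nm: float) -> np.ndarray:
        eps = self.coefficients[float(wavelength_nm)]
        return np.log(10.0) * 1e-6 * np.asarray(eps)  # 1/(uM cm), natural log

    def matrix(self, wavelengths_nm: tuple[float, float]) -> np.ndarray:
        E = np.vstack([self.row(wl) for wl in wavelengths_nm])
        cond = np.linalg.cond(E)
        if not np.isfinite(cond) or cond > 1e9:
            raise SensitivityError(
                f"extinction matrix singular or ill-conditioned (cond={cond:.3g})")
        return E

    def condition_number(self, wavelengths_nm: tuple[float, float]) -> float:
        return float(np.linalg.cond(self.matrix(wavelengths_nm)))


@dataclass(frozen=True)
class SensitivityProfile:
    """Per-layer sensitivity factors of <t> to absorption, per wavelength.

    ``sf_ps_cm[wl]`` is an array of SF_k (ps cm) ordered surface-first;
    ``se_ps_cm[wl]`` the Monte Carlo standard error of each entry.
    ``substrate_sf_ps_cm[wl]`` is the factor of the semi-infinite substrate
    below the nominal stack (outside the layer model, reported for
    bookkeeping and conservation checks).
    """

    sf_ps_cm: dict[float, np.ndarray]
    se_ps_cm: dict[float, np.ndarray]
    mc_photons: int
    stack: OpticalLayerStack
    seed: int
    substrate_sf_ps_cm: dict[float, float] = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return next(iter(self.sf_ps_cm.values())).size


def sensitivity_from_bank(
    bank: PhotonBank,
    delta_mua: float = 0.005,
) -> tuple[np.ndarray, np.ndarray]:
    """Region SFs from one photon bank by central finite differences.

    SF_k = -(<t>(mua_k + d) - <t>(mua_k - d)) / (2 d) on shared photon
    paths (correlated estimator).  The Monte Carlo standard error is the
    delta-method error of the paired ratio estimator, from the per-photon
    influence values.  Returns one entry per region: the model layers
    surface-first, then the semi-infinite substrate below the stack.
    """
    n_regions = bank.path_cm.shape[1]
    t = bank.tof_ps
    path = bank.path_cm
    w0 = bank.weights()
    sf = np.empty(n_regions)
    se = np.empty(n_regions)
    for k in range(n_regions):
        # reweight relative to baseline: only region k changes
        dw = np.exp(-delta_mua * path[:, k])
        up = w0 / dw      # mua_k - d
        dn = w0 * dw      # mua_k + d
        W_up, W_dn = up.sum(), dn.sum()
        m_up = (up * t).sum() / W_up
        m_dn = (dn * t).sum() / W_dn
        sf[k] = -(m_dn - m_up) / (2.0 * delta_mua)
        # influence of photon i on (m_dn - m_up); photons are shared, so
        # the difference's variance comes from the paired influences
        phi = dn * (t - m_dn) / W_dn - up * (t - m_up) / W_up
        se[k] = np.sqrt((phi**2).sum()) / (2.0 * delta_mua)
    return sf, se


def run_sensitivity_mc(
    stack: OpticalLayerStack | dict[float, OpticalLayerStack],
    geometry: DetectionGeometry | None = None,
    mc_photons: int = 1_000_000,
    seed: int = 0,
    wavelengths_nm: tuple[float, ...] = (760.0, 830.0),
    delta_mua: float = 0.005,
    banks: dict[float, PhotonBank] | None = None,
) -> SensitivityProfile:
    """Monte Carlo sensitivity profile at each wavelength.

    ``stack`` may be a single stack (shared optical properties at both
    wavelengths) or a per-wavelength mapping.  Pre-computed photon banks
    can be supplied to reuse transport runs.
    """
    if mc_photons < 1e5:
        raise SensitivityError("mc_photons must be >= 1e5 for stable factors")
    geometry = geometry or DetectionGeometry()
    stacks = stack if isinstance(stack, dict) else {wl: stack for wl in wavelengths_nm}
    sf: dict[float, np.ndarray] = {}
    se: dict[float, np.ndarray] = {}
    sub: dict[float, float] = {}
    ref_stack = None
    for i, wl in enumerate(wavelengths_nm):
        st = stacks[wl]
        ref_stack = ref_stack or st
        if banks is not None and wl in banks:
            bank = banks[wl]
        else:
            bank = run_transport(st, geometry, mc_photons, seed=seed + 7919 * (i + 1))
        full, full_se = sensitivity_from_bank(bank, delta_mua=delta_mua)
        n = st.n_layers
        sf[wl], se[wl], sub[wl] = full[:n], full_se[:n], float(full[n])
    return SensitivityProfile(sf_ps_cm=sf, se_ps_cm=se, mc_photons=int(mc_photons),
                              stack=ref_stack, seed=int(seed),
                              substrate_sf_ps_cm=sub)


def intracerebral_sf(profile: SensitivityProfile,
                     first_layer: int = 5) -> dict[float, float]:
    """Intracerebral sensitivity factor: sum of layer SFs from ``first_layer``
    (1-based, surface = layer 1) to the deepest layer, per wavelength."""
    if profile.n_layers < 10:
        raise SensitivityError(
            f"profile has {profile.n_layers} layers; >= 10 required")
    return {wl: float(sf[first_layer - 1:].sum())
            for wl, sf in profile.sf_ps_cm.items()}


def delta_mua_from_dtof(
    delta_mean_tof_ps: dict[float, np.ndarray],
    sf_ps_cm: dict[float, float],
) -> dict[float, np.ndarray]:
    """Convert d<t> series to intracerebral absorption changes.

    dmua(wl, t) = -d<t>(wl, t) / SF(wl): an absorption increase removes
    late photons preferentially and therefore shortens <t>.
    """
    out = {}
    for wl, series in delta_mean_tof_ps.items():
        sf = sf_ps_cm[wl]
        if not sf > 0:
            raise SensitivityError(f"sensitivity factor at {wl} nm must be > 0")
        out[wl] = -np.asarray(series, dtype=float) / sf
    return out


def hemoglobin_from_mua(
    dmua: dict[float, np.ndarray],
    extinction: ExtinctionTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert two-wavelength dmua series to (dHbO, dHbR) in uM."""
    ext = extinction or ExtinctionTable()
    wavelengths = tuple(sorted(dmua))
    if len(wavelengths) != 2:
        raise SensitivityError("exactly two wavelengths required")
    E = ext.matrix(wavelengths)
    stacked = np.vstack([dmua[wl] for wl in wavelengths])
    hb = np.linalg.solve(E, stacked)
    return hb[0], hb[1]
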