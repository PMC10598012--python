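"""Equilibrium chemical-denaturation analysis.

Unfolding monitored by intrinsic fluorescence is summarized by the
average emission wavelength (AEW), the intensity-weighted mean of the
emission spectrum:

    AEW = Σ F_i λ_i / Σ F_i

Denaturation curves (AEW or far-UV CD ellipticity vs denaturant) are fit
to linear-extrapolation two-state (N ⇌ D) or three-state (N ⇌ I ⇌ D)
models.  Each equilibrium constant follows

    K = exp(m ([den] - [den]_50%) / RT)

so the observed signal is a Boltzmann population average over states with
linear baselines for N and D and a constant intermediate signal (the
intermediate baseline carries no slope term).  The water free energy of
each transition is the identity ΔG(H2O) = m · [den]_50%.

Defaults: R = 1.987e-3 kcal/(mol·K), T = 298.15 K (25 °C).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "R_KCAL",
    "T_DEFAULT",
    "EquilibriumError",
    "TwoStateParams",
    "ThreeStateParams",
    "EquilibriumFit",
    "average_emission_wavelength",
    "two_state_signal",
    "three_state_signal",
    "three_state_populations",
    "fit_equilibrium",
    "simulate_denaturation",
]

R_KCAL = 1.987e-3  # kcal / (mol K)
T_DEFAULT = 298.15  # K


class EquilibriumError(ValueError):
    pass


def average_emission_wavelength(wavelengths, intensities) -> float:
    """Intensity-weighted mean emission wavelength (nm)."""
    lam = np.asarray(wavelengths, dtype=float)
    F = np.asarray(intensities, dtype=float)
    if lam.shape != F.shape or lam.ndim != 1:
        raise EquilibriumError("wavelengths and intensities must be equal-length 1-D")
    if (F < 0).any():
        raise EquilibriumError("negative fluorescence intensity")
    total = F.sum()
    if total <= 0:
        raise EquilibriumError("total fluorescence intensity is zero")
    return float((F * lam).sum() / total)


@dataclass(frozen=True)
class TwoStateParams:
    """Two-state (N ⇌ D) linear-extrapolation model parameters."""

    alpha_n: float  # native baseline intercept (signal units)
    beta_n: float  # native baseline slope (signal / M)
    alpha_d: float  # denatured baseline intercept
    beta_d: float  # denatured baseline slope
    m: float  # kcal / (mol M)
    d50: float  # M
    temperature: float = T_DEFAULT

    @property
    def dG_water(self) -> float:
        """ΔG_D-N(H2O) = m · [den]_50% (kcal/mol)."""
        return self.m * self.d50


@dataclass(frozen=True)
class ThreeStateParams:
    """Three-state (N ⇌ I ⇌ D) model parameters.

    The intermediate has a constant signal ``alpha_i`` (no baseline slope).
    """

    alpha_n: float
    beta_n: float
    alpha_i: float
    alpha_d: float
    beta_d: float
    m_in: float  # I-N transition m-value
    d50_in: float
    m_di: float  # D-I transition m-value
    d50_di: float
    temperature: float = T_DEFAULT

    @property
    def dG_in_water(self) -> float:
        return self.m_in * self.d50_in

    @property
    def dG_di_water(self) -> float:
        return self.m_di * self.d50_di

    @property
    def dG_dn_water(self) -> float:
        """Total ΔG_D-N(H2O), sum of the two transitions."""
        return self.dG_in_water + self.dG_di_water


def _softmax_fractions(*log_weights):
    """Numerically stable Boltzmann fractions from log statistical weights."""
    logits = np.stack(np.broadcast_arrays(*log_weights))
    m = logits.max(axis=0)
    w = np.exp(logits - m)
    return tuple(w[i] / w.sum(axis=0) for i in range(logits.shape[0]))


def two_state_signal(den, params: TwoStateParams):
    """Two-state observed signal at denaturant concentration(s) ``den``."""
    den = np.asarray(den, dtype=float)
    RT = R_KCAL * params.temperature
    a = params.m * (den - params.d50) / RT  # ln K_D-N
    f_n, f_d = _softmax_fractions(np.zeros_like(a), a)
    return ((params.alpha_n + params.beta_n * den) * f_n
            + (params.alpha_d + params.beta_d * den) * f_d)


def three_state_populations(den, params: ThreeStateParams):
    """Fractional populations (f_N, f_I, f_D); they sum to one."""
    den = np.asarray(den, dtype=float)
    RT = R_KCAL * params.temperature
    a1 = params.m_in * (den - params.d50_in) / RT  # ln K_I-N
    a2 = params.m_di * (den - params.d50_di) / RT  # ln K_D-I
    return _softmax_fractions(np.zeros_like(a1), a1, a1 + a2)


def three_state_signal(den, params: ThreeStateParams):
    """Population-weighted three-state signal with N/D baselines."""
    den = np.asarray(den, dtype=float)
    f_n, f_i, f_d = three_state_populations(den, params)
    return ((params.alpha_n + params.beta_n * den) * f_n
            + params.alpha_i * f_i
            + (params.alpha_d + params.beta_d * den) * f_d)


@dataclass(frozen=True)
class EquilibriumFit:
    """Result of a denaturation-curve fit."""

    model: str
    params: TwoStateParams | ThreeStateParams
    stderr: dict[str, float]
    residuals: np.ndarray
    rss: float
    aic: float

    @property
    def dG_water(self) -> float:
        if isinstance(self.params, TwoStateParams):
            return self.params.dG_water
        return self.params.dG_dn_water


_TWO_NAMES = ["alpha_n", "beta_n", "alpha_d", "beta_d", "m", "d50"]
_THREE_NAMES = ["alpha_n", "beta_n", "alpha_i", "alpha_d", "beta_d",
                "m_in", "d50_in", "m_di", "d50_di"]


def _aic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def fit_equilibrium(den, signal, model: str = "two_state",
                    temperature: float = T_DEFAULT, multistart_seed: int = 0,
                    n_starts: int = 12) -> EquilibriumFit:
    """Nonlinear least-squares fit of a denaturation curve.

    Seeded multi-start initialization: baselines are estimated from the
    curve ends, transition midpoints drawn from the sampled concentration
    range and m-values from a physically plausible band; the best
    converged start (lowest residual sum of squares) is returned with
    asymptotic standard errors from the Jacobian.
    """
    den = np.asarray(den, dtype=float)
    y = np.asarray(signal, dtype=float)
    if den.shape != y.shape or den.ndim != 1:
        raise EquilibriumError("den and signal must be equal-length 1-D arrays")
    if den.size < 8:
        raise EquilibriumError("need at least 8 points spanning both baselines")
    rng = np.random.default_rng(multistart_seed)
    span = max(y.max() - y.min(), 1e-12)
    d_lo, d_hi = den.min(), den.max()

    if model == "two_state":
        names = _TWO_NAMES

        def predict(theta, d):
            return two_state_signal(d, TwoStateParams(*theta, temperature))

        def starts():
            for _ in range(n_starts):
                yield np.array([
                    y[np.argmin(den)], 0.0, y[np.argmax(den)], 0.0,
                    rng.uniform(1.0, 8.0),
                    rng.uniform(d_lo + 0.1 * (d_hi - d_lo), d_hi - 0.1 * (d_hi - d_lo)),
                ])

        lower = [-np.inf, -np.inf, -np.inf, -np.inf, 1e-6, 0.0]
        upper = [np.inf] * 4 + [np.inf, np.inf]
    elif model == "three_state":
        names = _THREE_NAMES

        def predict(theta, d):
            return three_state_signal(d, ThreeStateParams(*theta, temperature))

        def starts():
            for _ in range(n_starts):
                mid1 = rng.uniform(d_lo + 0.15 * (d_hi - d_lo), d_lo + 0.65 * (d_hi - d_lo))
                mid2 = rng.uniform(mid1 + 0.05 * (d_hi - d_lo), d_hi)
                yield np.array([
                    y[np.argmin(den)], 0.0,
                    0.5 * (y.min() + y.max()) + rng.normal(0, 0.15 * span),
                    y[np.argmax(den)], 0.0,
                    rng.uniform(2.0, 10.0), mid1,
                    rng.uniform(2.0, 10.0), mid2,
                ])

        lower = [-np.inf] * 5 + [1e-6, 0.0, 1e-6, 0.0]
        upper = [np.inf] * 9
    else:
        raise EquilibriumError(f"unknown model {model!r}")

    best = None
    for theta0 in starts():
        try:
            res = least_squares(
                lambda th: predict(th, den) - y, theta0,
                bounds=(lower, upper), method="trf", x_scale="jac",
            )
        except Exception:
            continue
        if not res.success and not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise EquilibriumError("equilibrium fit failed to converge from any start")
    theta = best.x
    resid = predict(theta, den) - y
    rss = float((resid**2).sum())
    dof = max(den.size - len(theta), 1)
    s2 = rss / dof
    J = best.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(theta), np.nan)
    stderr = dict(zip(names, se))
    if model == "two_state":
        params = TwoStateParams(*theta, temperature)
    else:
        params = ThreeStateParams(*theta, temperature)
        # Report with ordered midpoints (swap transitions if inverted).
        if params.d50_in > params.d50_di:
            params = ThreeStateParams(
                params.alpha_n, params.beta_n, params.alpha_i, params.alpha_d,
                params.beta_d, params.m_di, params.d50_di, params.m_in,
                params.d50_in, temperature,
            )
    return EquilibriumFit(model, params, stderr, resid, rss,
                          _aic(rss, den.size, len(theta)))


def simulate_denaturation(params, den_grid, noise_sd: float = 0.0,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic denaturation curve: model signal plus Gaussian noise.

    Returns ``(den, signal)``; reproducible for a given seed.
    """
    den = np.asarray(den_grid, dtype=float)
    if isinstance(params, TwoStateParams):
        y = two_state_signal(den, params)
    elif isinstance(params, ThreeStateParams):
        y = three_state_signal(den, params)
    else:
        raise EquilibriumError("params must be TwoStateParams or ThreeStateParams")
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, den.shape)
    return den, np.asarray(y, dtype=float)
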