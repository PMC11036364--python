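"""Crystal growth interface kinetics: serial mass-transfer + surface
integration resistances.

The facet growth rate is modelled as a driving force over two serial
resistances,

    G(sigma) = sigma / (R_MT(sigma) + R_SI(sigma)),

where sigma is the relative supersaturation.  The surface-integration
resistance is ``R_SI = sigma / G_SI`` with the interface rate ``G_SI`` given
by one of three mechanisms:

* power law:        G_SI = k_G * sigma**r           (r = 1: rough interface)
* Birth & Spread:   G_SI = A1 * sigma**(5/6) * exp(-A2 / sigma)
* BCF (screw
  dislocation):     G_SI = A1 * sigma**2 * tanh(A2 / sigma)

The mass-transfer resistance follows from a stagnant-film balance: the molar
flux to the face is ``k_mt * (C - C_e) = k_mt * C_e * sigma`` and the face
advances at ``G = flux * MW_s / rho_s``, hence

    R_MT = rho_s / (k_mt * MW_s * C_e(sigma)),   C_e = C0 / (1 + sigma),

which grows with sigma as the solubility reference C_e falls.  Units:
k_mt in m s^-1, C in mol m^-3, MW_s in g mol^-1, rho_s converted to g m^-3;
G comes out in m s^-1.

Fitting uses damped Gauss-Newton (Levenberg-Marquardt) over log-positive
parameters with a deterministic multi-start grid, ranked by R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MODELS",
    "SoluteProperties",
    "KineticFit",
    "ResistancePair",
    "equilibrium_concentration",
    "mass_transfer_resistance",
    "interface_rate",
    "model_growth_rate",
    "fit_kinetics",
    "select_model",
    "critical_supersaturation",
    "resistance_decomposition",
]

MODELS = ("power_law", "birth_spread", "bcf")


@dataclass(frozen=True)
class SoluteProperties:
    """Solute constants; defaults are those of L-glutamic acid in water
    with a 35 g/L starting solution."""

    MW_s: float = 147.13   # g mol^-1
    rho_s: float = 1.54    # g cm^-3
    C0: float = 237.88     # mol m^-3

    def __post_init__(self) -> None:
        if min(self.MW_s, self.rho_s, self.C0) <= 0:
            raise ValueError("solute properties must be positive")

    @property
    def rho_gm3(self) -> float:
        return self.rho_s * 1e6


@dataclass
class KineticFit:
    """A fitted combined MT+GSI model for one face."""

    model: str
    params: dict
    k_mt: float
    r2: float
    sigma_c: float
    plausible: bool
    sse: float = np.nan
    sigma_max: float = np.nan
    g_max: float = np.nan
    sigma_c_flagged: bool = False
    props: SoluteProperties = field(default_factory=SoluteProperties)

    def predict(self, sigma) -> np.ndarray:
        return model_growth_rate(
            self.model, self.params, self.k_mt, self.props, sigma
        )


@dataclass
class ResistancePair:
    """MT and GSI resistances at one supersaturation."""

    sigma: float
    R_mt: float
    R_si: float

    @property
    def limiting(self) -> str:
        return "MT" if self.R_mt > self.R_si else "GSI"


def equilibrium_concentration(props: SoluteProperties, sigma) -> np.ndarray:
    """Solubility C_e = C0 / (1 + sigma) from sigma = (C0 - C_e) / C_e."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= -1):
        raise ValueError("sigma must exceed -1")
    return props.C0 / (1.0 + sigma)


def mass_transfer_resistance(
    k_mt: float, props: SoluteProperties, sigma
) -> np.ndarray:
    """R_MT = rho_s / (k_mt * MW_s * C_e(sigma)), s m^-1.

    This single function holds the algebraic form of the MT resistance;
    change it here if a different film-model convention is needed.
    """
    with np.errstate(divide="ignore", over="ignore"):
        return props.rho_gm3 / (
            k_mt * props.MW_s * equilibrium_concentration(props, sigma)
        )


def interface_rate(model: str, params: dict, sigma) -> np.ndarray:
    """Pure surface-integration rate G_SI(sigma) for one mechanism."""
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if model == "power_law":
            g = params["k_G"] * sigma ** params["r"]
        elif model == "birth_spread":
            g = params["A1"] * sigma ** (5.0 / 6.0) * np.exp(
                -params["A2"] / sigma
            )
        elif model == "bcf":
            g = params["A1"] * sigma**2 * np.tanh(params["A2"] / sigma)
        else:
            raise ValueError(f"unknown model {model!r}")
    return np.where(sigma == 0.0, 0.0, g)


def surface_integration_resistance(
    model: str, params: dict, sigma
) -> np.ndarray:
    """R_SI = sigma / G_SI; +inf where the interface rate vanishes."""
    sigma = np.asarray(sigma, dtype=float)
    g = interface_rate(model, params, sigma)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        return np.where(g > 0, sigma / g, np.inf)


def model_growth_rate(
    model: str, params: dict, k_mt: float, props: SoluteProperties, sigma
) -> np.ndarray:
    """Combined growth rate G = sigma / (R_MT + R_SI); G(0) = 0."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")
    vals = [k_mt, *params.values()]
    if not np.all(np.isfinite(vals)):
        raise ValueError("model parameters must be finite")
    r_tot = mass_transfer_resistance(k_mt, props, sigma) + (
        surface_integration_resistance(model, params, sigma)
    )
    with np.errstate(invalid="ignore"):
        g = np.where(sigma > 0, sigma / r_tot, 0.0)
    out = np.nan_to_num(g, nan=0.0, posinf=0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fitting

_PARAM_NAMES = {
    "power_law": ("k_G", "r"),
    "birth_spread": ("A1", "A2"),
    "bcf": ("A1", "A2"),
}

#: sanity bounds used for the plausibility flag.  The power-law exponent is
#: bounded by the mechanistic range of interface growth orders: r = 1 is a
#: rough interface and r = 2 the low-supersaturation parabolic (spiral)
#: limit, so exponents collapsing to ~0 or exceeding 2 mark a degenerate
#: fit rather than a mechanism.
_PLAUSIBLE = {
    "r": (1e-3, 2.0),
    "A2": (1e-4, 1e3),
}


def _start_grid(model: str, sigma: np.ndarray, g: np.ndarray,
                props: SoluteProperties) -> list[np.ndarray]:
    """Deterministic multi-start grid in log-parameter space."""
    gmax = g.max()
    smax = sigma.max()
    # k_mt scale at which R_MT alone would explain the largest rate
    ce = float(equilibrium_concentration(props, smax))
    k0 = props.rho_gm3 * gmax / (props.MW_s * ce * smax)
    kmt_grid = k0 * np.array([0.3, 1.0, 3.0, 30.0, 1e3, 1e6])
    starts = []
    if model == "power_law":
        for r in (0.5, 1.0, 2.0):
            for fac in (0.5, 1.0, 2.0, 10.0):
                kg = fac * gmax / smax**r
                for kmt in kmt_grid:
                    starts.append(np.log([kg, r, kmt]))
    else:
        a2_grid = (0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 5.0)
        for a2 in a2_grid:
            base = interface_rate(model, {"A1": 1.0, "A2": a2}, smax)
            for fac in (1.0, 3.0, 10.0, 100.0, 1e3, 1e4):
                a1 = fac * gmax / base
                for kmt in kmt_grid:
                    starts.append(np.log([a1, a2, kmt]))
    return starts


def _unpack_x(model: str, x: np.ndarray) -> tuple[dict, float]:
    names = _PARAM_NAMES[model]
    vals = np.exp(np.clip(x, -700.0, 700.0))
    return dict(zip(names, vals[:-1])), float(vals[-1])


def fit_kinetics(
    sigma: Sequence[float],
    G: Sequence[float],
    model: str,
    props: SoluteProperties | None = None,
    spread: Sequence[float] | None = None,
    n_refine: int = 8,
    sigma_c_threshold_frac: float = 0.01,
) -> KineticFit:
    """Levenberg-Marquardt fit of one combined model to (sigma, G) data.

    Parameters are fitted in log space (all positive); a fixed multi-start
    grid is prescreened by sum of squares and the best ``n_refine`` starts
    are refined with damped Gauss-Newton, keeping the overall best.  R^2 is
    computed on G about its mean.  The plausibility flag goes false when a
    fitted exponent or barrier parameter leaves its configured sanity range
    (e.g. a power-law exponent collapsing toward zero).
    """
    props = props or SoluteProperties()
    sigma = np.asarray(sigma, dtype=float)
    g = np.asarray(G, dtype=float)
    if sigma.size < 4:
        raise ValueError("need at least 4 (sigma, G) points")
    if np.any(sigma < 0) or np.any(g < 0):
        raise ValueError("sigma and G must be >= 0")
    if np.all(g == 0):
        raise ValueError("all growth rates are zero; nothing to fit")
    w = None if spread is None else 1.0 / np.asarray(spread, dtype=float)

    def residuals(x: np.ndarray) -> np.ndarray:
        params, kmt = _unpack_x(model, x)
        pred = model_growth_rate(model, params, kmt, props, sigma)
        res = pred - g
        return res if w is None else res * w

    starts = _start_grid(model, sigma, g, props)
    sses = np.array([float(np.sum(residuals(x) ** 2)) for x in starts])
    order = np.argsort(sses, kind="stable")[:n_refine]
    best_x, best_sse = None, np.inf
    for idx in order:
        try:
            sol = least_squares(
                residuals, starts[idx], method="lm", xtol=1e-14, ftol=1e-14,
                max_nfev=2000,
            )
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if sse < best_sse - 1e-30:
            best_sse, best_x = sse, sol.x
    if best_x is None:  # pragma: no cover - grid always yields a candidate
        raise RuntimeError("all fits failed")
    params, kmt = _unpack_x(model, best_x)
    pred = model_growth_rate(model, params, kmt, props, sigma)
    ss_res = float(np.sum((pred - g) ** 2))
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    plausible = all(
        lo <= params[k] <= hi
        for k, (lo, hi) in _PLAUSIBLE.items()
        if k in params
    )
    fit = KineticFit(
        model=model, params=params, k_mt=kmt, r2=r2, sigma_c=np.nan,
        plausible=bool(plausible), sse=ss_res,
        sigma_max=float(sigma.max()), g_max=float(g.max()), props=props,
    )
    fit.sigma_c, fit.sigma_c_flagged = critical_supersaturation(
        fit, G_detect=sigma_c_threshold_frac * fit.g_max
    )
    return fit


def select_model(
    sigma: Sequence[float],
    G: Sequence[float],
    props: SoluteProperties | None = None,
    models: Sequence[str] = MODELS,
    **kwargs,
) -> list[KineticFit]:
    """Fit every mechanism and rank by R^2, plausible fits first."""
    fits = [fit_kinetics(sigma, G, m, props, **kwargs) for m in models]
    return sorted(fits, key=lambda f: (not f.plausible, -f.r2))


def critical_supersaturation(
    fit: KineticFit, G_detect: float | None = None
) -> tuple[float, bool]:
    """Dead-zone edge: smallest sigma where the fitted curve reaches a
    detectability threshold.

    The combined models are strictly positive for sigma > 0, so a literal
    G = 0 crossing sits at sigma = 0; operationally the dead zone ends
    where growth first becomes measurable.  ``G_detect`` defaults to 1% of
    the largest observed rate.  Found by bisection on [0, sigma_max];
    if the curve never reaches the threshold the result is flagged and
    sigma_max returned.
    """
    if G_detect is None:
        G_detect = 0.01 * fit.g_max
    if G_detect < 0:
        raise ValueError("G_detect must be >= 0")
    if G_detect == 0.0:
        return 0.0, False
    hi = fit.sigma_max
    if fit.predict(hi) < G_detect:
        return hi, True
    lo = 0.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if fit.predict(mid) >= G_detect:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi), False


def resistance_decomposition(
    fit: KineticFit,
    props: SoluteProperties | None = None,
    sigmas: Sequence[float] | None = None,
) -> list[ResistancePair]:
    """Per-sigma MT and GSI resistances with the limiting (larger) step."""
    props = props or fit.props
    sig = np.atleast_1d(
        np.asarray(fit.sigma_max if sigmas is None else sigmas, float)
    )
    out = []
    for s in sig:
        r_mt = float(mass_transfer_resistance(fit.k_mt, props, s))
        r_si = float(
            surface_integration_resistance(fit.model, fit.params, s)
        )
        out.append(ResistancePair(sigma=float(s), R_mt=r_mt, R_si=r_si))
    return out
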