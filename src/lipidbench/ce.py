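"""Collision-energy → relative-intensity models for lipid fragments.

Fragment dissociation profiles (scan-relative intensity as a function of
collision energy) are fitted with a shifted, rescaled log-normal kernel:

    f(x | mu, sigma) = 1/x * 1/(sigma*sqrt(2*pi)) * exp(-(ln x - mu)^2 / (2 sigma^2))
    g(x | mu, sigma, s, delta) = s * f(x + delta | mu, sigma)

where ``delta`` positions the density in collision-energy coordinates and
``s`` rescales its height to the profile height.  Fitting is bounded
multi-start Levenberg–Marquardt least squares (a grid of start values over
the parameter box); among converged candidates the one with the lowest AIC
is selected.  Fit diagnostics include the per-CE residuals, a Shapiro–Wilk
normality test on the standardized residuals, and a degrees-of-freedom
corrected mean squared error.

The *optimal* collision energy for a lipid is the mode of the product of
the selected fragments' densities — the CE with the highest simultaneous
overlap of all fragment profiles — clipped to the instrument's minimum
reporting CE.  Evaluating all models at a chosen CE and max-normalizing
yields an in silico spectrum.
"""

from __future__ import annotations

import csv
import itertools
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from lmfit import Parameters, minimize as lmfit_minimize
from scipy import stats

__all__ = [
    "CEModelParams",
    "CEProfile",
    "FitResult",
    "InstrumentConfig",
    "load_instruments",
    "lognormal_density",
    "ce_response",
    "response_mode",
    "fit_ce_profile",
    "model_mse",
    "model_aic",
    "optimal_collision_energy",
    "predict_spectrum",
]


def lognormal_density(x, mu: float, sigma: float):
    """Log-normal probability density; integrates to 1 over (0, inf).

    Vectorized over ``x``; every element must be strictly positive and
    ``sigma`` > 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("log-normal density requires x > 0")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = (
        1.0
        / x
        / (sigma * math.sqrt(2.0 * math.pi))
        * np.exp(-((np.log(x) - mu) ** 2) / (2.0 * sigma**2))
    )
    return out if out.shape else float(out)


@dataclass(frozen=True)
class CEModelParams:
    """Shifted/rescaled log-normal parameters (mu, sigma, s, delta)."""

    mu: float
    sigma: float
    s: float
    delta: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.s <= 0:
            raise ValueError("height rescale s must be positive")

    @property
    def mode(self) -> float:
        """CE at which the response peaks: exp(mu - sigma^2) - delta."""
        return math.exp(self.mu - self.sigma**2) - self.delta


def ce_response(x, p: CEModelParams):
    """Predicted scan-relative intensity  g(x) = s * f(x + delta).

    Left of the profile front (x + delta <= 0) the response is defined as 0
    with a warning — the kernel has no support there.
    """
    x = np.asarray(x, dtype=float)
    shifted = x + p.delta
    out = np.zeros_like(shifted)
    ok = shifted > 0
    if not np.all(ok):
        warnings.warn(
            "ce_response evaluated left of the profile front (x + delta <= 0); "
            "returning 0 there",
            stacklevel=2,
        )
    if np.any(ok):
        out[ok] = p.s * lognormal_density(shifted[ok], p.mu, p.sigma)
    return out if out.shape else float(out)


def response_mode(p: CEModelParams) -> float:
    return p.mode


@dataclass
class CEProfile:
    """Observed (CE, scan-relative intensity) pairs for one fragment."""

    lipid: str
    fragment: str
    observations: list[tuple[float, float]]
    instrument: str = "hcd-orbitrap-nce"

    def __post_init__(self) -> None:
        for ce, y in self.observations:
            if not -1e-9 <= y <= 1 + 1e-9:
                raise ValueError(
                    f"scan-relative intensity {y} outside [0, 1] at CE {ce}"
                )

    @property
    def x(self) -> np.ndarray:
        return np.array([ce for ce, _ in self.observations])

    @property
    def y(self) -> np.ndarray:
        return np.array([y for _, y in self.observations])

    def n_distinct_ce(self) -> int:
        return len({ce for ce, _ in self.observations})


@dataclass
class FitResult:
    """Best-AIC fit of one CE profile with diagnostics."""

    lipid: str
    fragment: str
    params: CEModelParams
    aic: float
    mse: float
    ssr: float
    n_points: int
    residuals: np.ndarray = field(repr=False)
    shapiro_wilk_p: float = float("nan")
    n_starts_converged: int = 0
    fragment_mz: float | None = None

    def predict(self, x):
        return ce_response(x, self.params)


@dataclass(frozen=True)
class InstrumentConfig:
    """CE acquisition range and reporting floor of one MS platform."""

    name: str
    ce_unit: str
    ce_range: tuple[float, float]
    step: float
    min_reporting_ce: float

    def __post_init__(self) -> None:
        lo, hi = self.ce_range
        if not lo <= self.min_reporting_ce <= hi:
            raise ValueError("min_reporting_ce outside the CE range")

    def grid(self, refine: int = 10) -> np.ndarray:
        """Evaluation grid at step/refine resolution across the CE range."""
        lo, hi = self.ce_range
        n = int(round((hi - lo) / (self.step / refine))) + 1
        return np.linspace(lo, hi, n)


def load_instruments(path=None) -> dict[str, InstrumentConfig]:
    """Load instrument profiles (packaged ``instruments.csv`` by default)."""
    if path is None:
        text = resources.files("lipidbench.data").joinpath("instruments.csv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    out = {}
    for row in csv.DictReader(
        ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
    ):
        cfg = InstrumentConfig(
            name=row["name"],
            ce_unit=row["ce_unit"],
            ce_range=(float(row["ce_min"]), float(row["ce_max"])),
            step=float(row["step"]),
            min_reporting_ce=float(row["min_reporting_ce"]),
        )
        out[cfg.name] = cfg
    return out


# ----------------------------------------------------------------------
# fitting

#: Default parameter box for the bounded grid-search multi-start.  delta's
#: lower bound is tightened per profile to keep x + delta > 0 on the data.
DEFAULT_BOUNDS = {
    "mu": (0.0, 6.0),
    "sigma": (0.05, 3.0),
    "s": (1e-3, 1e3),
    "delta": (None, 100.0),  # lower bound set from min(CE) at fit time
}

_N_FIT_PARAMS = 4
#: AIC parameter count: 4 model parameters + the residual variance.
_AIC_K = 5


def model_aic(ssr: float, n: int, k: int = _AIC_K) -> float:
    """Least-squares AIC: n*ln(SSR/n) + 2k (k counts the variance term)."""
    ssr = max(ssr, 1e-300)
    return n * math.log(ssr / n) + 2 * k


def model_mse(
    ssr: float, n_points: int, n_params: int = _N_FIT_PARAMS, convention: str = "literal"
) -> float:
    """Degrees-of-freedom corrected mean squared error of a fit.

    ``literal`` divides SSR by (n − n_params − 1); the alternative
    ``per-parameter`` convention divides by (n − n_params).  Both are
    exposed because reported MSE values in the field vary by this choice.
    """
    if convention == "literal":
        denom = n_points - n_params - 1
    elif convention == "per-parameter":
        denom = n_points - n_params
    else:
        raise ValueError(f"unknown MSE convention {convention!r}")
    if denom <= 0:
        raise ValueError(
            f"too few points ({n_points}) for {n_params}-parameter MSE"
        )
    return ssr / denom


def _start_grid(bounds: dict, n_per_param: int = 5) -> list[tuple[float, ...]]:
    axes = []
    for name in ("mu", "sigma", "s", "delta"):
        lo, hi = bounds[name]
        if name == "s":  # spans decades; space geometrically
            axes.append(np.geomspace(max(lo, 1e-3), hi, n_per_param))
        else:
            axes.append(np.linspace(lo, hi, n_per_param))
    return list(itertools.product(*axes))


def _heuristic_start(x: np.ndarray, y: np.ndarray, bounds: dict) -> tuple[float, ...]:
    """Moment-style start: place the mode at the empirical peak."""
    peak_ce = float(x[np.argmax(y)])
    peak_y = float(np.max(y))
    sigma0 = 0.3
    delta0 = 0.0
    mu0 = math.log(max(peak_ce + delta0, 1e-3)) + sigma0**2
    f_mode = lognormal_density(max(peak_ce + delta0, 1e-3), mu0, sigma0)
    s0 = max(peak_y / max(f_mode, 1e-12), bounds["s"][0])

    def clip(v, lo, hi):
        return min(max(v, lo), hi)

    return (
        clip(mu0, *bounds["mu"]),
        clip(sigma0, *bounds["sigma"]),
        clip(s0, *bounds["s"]),
        clip(delta0, *bounds["delta"]),
    )


def fit_ce_profile(
    profile: CEProfile,
    bounds: dict | None = None,
    n_starts: int = 60,
    seed: int = 0,
) -> FitResult:
    """Bounded multi-start least-squares fit of the shifted log-normal.

    Start values are drawn from a 5-per-parameter grid over the bounds
    (625 candidates), subsampled to ``n_starts`` with the given seed (the
    moment-based heuristic start is always included).  Each start runs
    bounded Levenberg–Marquardt; the converged candidate with the lowest
    AIC wins.  Deterministic for fixed inputs and seed.

    Requires observations at ≥ 8 distinct CE values (the model has 4
    parameters).
    """
    if profile.n_distinct_ce() < 8:
        raise ValueError(
            f"profile {profile.lipid}/{profile.fragment} has only "
            f"{profile.n_distinct_ce()} distinct CE values; >= 8 required "
            f"for a 4-parameter model"
        )
    x, y = profile.x, profile.y
    n = len(y)

    b = dict(DEFAULT_BOUNDS, **(bounds or {}))
    if b["delta"][0] is None:
        b = dict(b, delta=(-float(x.min()) + 1e-6, b["delta"][1]))

    starts = _start_grid(b)
    rng = np.random.default_rng(seed)
    if n_starts < len(starts) + 1:
        idx = rng.choice(len(starts), size=max(n_starts - 1, 1), replace=False)
        starts = [starts[i] for i in sorted(idx)]
    starts.insert(0, _heuristic_start(x, y, b))

    def residual(pars):
        shifted = x + pars["delta"].value
        model = np.zeros_like(x)
        ok = shifted > 0
        model[ok] = pars["s"].value * (
            1.0
            / shifted[ok]
            / (pars["sigma"].value * math.sqrt(2 * math.pi))
            * np.exp(
                -((np.log(shifted[ok]) - pars["mu"].value) ** 2)
                / (2 * pars["sigma"].value ** 2)
            )
        )
        return model - y

    best = None
    diagnostics = []
    n_converged = 0
    for start in starts:
        pars = Parameters()
        for name, value in zip(("mu", "sigma", "s", "delta"), start):
            lo, hi = b[name]
            pars.add(name, value=value, min=lo, max=hi)
        try:
            res = lmfit_minimize(residual, pars, method="leastsq")
        except Exception as exc:  # singular Jacobian etc.
            diagnostics.append((start, f"error: {exc}"))
            continue
        if not res.success:
            diagnostics.append((start, f"no convergence: {res.message}"))
            continue
        n_converged += 1
        ssr = float(np.sum(res.residual**2))
        aic = model_aic(ssr, n)
        if best is None or aic < best[0]:
            best = (aic, ssr, res)

    if best is None:
        lines = "; ".join(f"start {s} -> {msg}" for s, msg in diagnostics[:5])
        raise RuntimeError(
            f"all {len(starts)} starts failed for "
            f"{profile.lipid}/{profile.fragment}: {lines}"
        )

    aic, ssr, res = best
    p = CEModelParams(
        mu=res.params["mu"].value,
        sigma=res.params["sigma"].value,
        s=res.params["s"].value,
        delta=res.params["delta"].value,
    )
    residuals = ce_response(x, p) - y
    std = residuals.std(ddof=1)
    if std > 0 and n >= 3:
        sw_p = float(stats.shapiro((residuals - residuals.mean()) / std).pvalue)
    else:
        sw_p = float("nan")
    return FitResult(
        lipid=profile.lipid,
        fragment=profile.fragment,
        params=p,
        aic=aic,
        mse=model_mse(ssr, n),
        ssr=ssr,
        n_points=n,
        residuals=residuals,
        shapiro_wilk_p=sw_p,
        n_starts_converged=n_converged,
    )


# ----------------------------------------------------------------------
# CE selection and in silico spectra

def optimal_collision_energy(
    models: list[FitResult],
    instrument: InstrumentConfig,
    selected: list[str] | None = None,
    refine: int = 10,
) -> float:
    """CE maximizing the product of the selected fragments' densities.

    The product density's mode is found on a grid at step/``refine``
    resolution over the instrument CE range and clipped up to the
    instrument's minimum reporting CE.  Changing ``selected`` (fragment
    names) updates the mode accordingly.
    """
    if selected is not None:
        models = [m for m in models if m.fragment in selected]
    if not models:
        raise ValueError("no fragment models selected for CE optimization")
    grid = instrument.grid(refine)
    log_prod = np.zeros_like(grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for m in models:
            g = np.asarray(ce_response(grid, m.params))
            log_prod += np.log(np.maximum(g, 1e-300))
    ce = float(grid[int(np.argmax(log_prod))])
    return max(ce, instrument.min_reporting_ce)


def predict_spectrum(
    models: list[FitResult],
    ce: float,
    instrument: InstrumentConfig,
) -> list[tuple[str, float | None, float]]:
    """In silico spectrum at ``ce``: (fragment, m/z, relative intensity).

    Intensities are the model responses max-normalized to 1.  A CE below
    the instrument's minimum reporting CE is rejected: there the profiles
    are nearly flat and the models are not informative.
    """
    lo, hi = instrument.ce_range
    if not lo <= ce <= hi:
        raise ValueError(f"CE {ce} outside instrument range [{lo}, {hi}]")
    if ce < instrument.min_reporting_ce:
        raise ValueError(
            f"CE {ce} is below the minimum reporting CE "
            f"({instrument.min_reporting_ce} {instrument.ce_unit}); model "
            f"predictions are unreliable in the flat low-CE regime"
        )
    if not models:
        raise ValueError("no fragment models given")
    raw = np.array([float(ce_response(ce, m.params)) for m in models])
    top = raw.max()
    if top <= 0:
        raise ValueError(f"all model responses vanish at CE {ce}")
    rel = raw / top
    return [
        (m.fragment, m.fragment_mz, float(r)) for m, r in zip(models, rel)
    ]
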