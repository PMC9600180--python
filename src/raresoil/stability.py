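"""Stability-landscape impulse-response model of diversity recovery.

A disturbed community is treated as a ball displaced inside a basin of a
stability landscape: an impulse perturbation of strength ``D`` knocks the
diversity away from its pre-disturbance equilibrium, a restoring force pulls
it back, and the system may settle at a *new* equilibrium displaced by ``A``
from the original one.  The displacement of (Shannon) diversity from the
initial baseline is modelled as

    x(t) = D * t * exp(phi1 * t) + A * (1 - exp(-phi2 * t))

the critically-damped impulse response of a second-order system plus a
relaxation towards the shifted equilibrium.  ``phi1`` (expected negative)
sets how fast the impulse decays, ``phi2`` (expected positive) how fast the
new equilibrium is approached; the damping ``b`` and restoring-force
strength ``k`` of the underlying oscillator are ``b = -2*phi1`` and
``k = phi1**2`` in this parameterisation and are reported for reference
only.  An overdamped two-exponential variant is available through
``form="overdamped"``.

The model is fitted in a Bayesian framework: uniform box priors on
``(D, A, phi1, phi2)``, a half-normal prior on the Gaussian observation
noise ``sigma``, and an affine-invariant ensemble sampler
(differential-evolution moves) for the posterior.  Summaries are the
percentile-based median and 95% credible interval per parameter; the
skewness of the asymptote posterior is the package's diagnostic for whether
a community is drifting to an alternative state (positive skew) or
recovering towards the original one (negative skew).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import InvalidConfigError

PARAM_NAMES = ("D", "A", "phi1", "phi2", "sigma")

#: Default uniform prior box.  Chosen wide enough to contain every credible
#: interval the model is expected to produce on displacement data measured
#: in Shannon units (natural log), where |x| rarely exceeds 2.
DEFAULT_BOUNDS = {
    "D": (0.0, 10.0),
    "A": (-2.0, 2.0),
    "phi1": (-2.0, 2.0),
    "phi2": (-2.0, 2.0),
    "sigma": (1e-4, 5.0),
}

#: Default mapping from timepoint label to model time (ordinal scale).
ORDINAL_TIME = {"initial": 0.0, "R0": 1.0, "R2": 2.0, "R40": 3.0, "R170": 4.0}
#: Calendar-day alternative (days since start of the disturbance).
CALENDAR_TIME = {"initial": 0.0, "R0": 80.0, "R2": 82.0, "R40": 120.0, "R170": 250.0}


@dataclass
class StabilityParams:
    """Parameters of the impulse-response recovery curve.

    ``D`` perturbation strength (diversity units x rate), ``A`` the new
    equilibrium displacement (diversity units), ``phi1`` the impulse
    decay rate and ``phi2`` the asymptote approach rate (both per model
    time unit).
    """

    D: float
    A: float
    phi1: float
    phi2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.D, self.A, self.phi1, self.phi2], dtype=float)

    @property
    def damping(self) -> float:
        """Damping coefficient b of the underlying second-order system."""
        return -2.0 * self.phi1

    @property
    def restoring_force(self) -> float:
        """Restoring-force strength k of the underlying second-order system."""
        return self.phi1 ** 2


def impulse_response(t, params: StabilityParams, form: str = "critical") -> np.ndarray:
    """Analytic displacement curve x(t) of the stability-landscape model.

    Parameters
    ----------
    t : array-like
        Non-negative model times.
    params : StabilityParams
    form : {"critical", "overdamped"}
        ``"critical"`` (default) is ``D*t*exp(phi1*t) + A*(1-exp(-phi2*t))``.
        ``"overdamped"`` uses the two-exponential response
        ``D*(e^{phi1 t} - e^{phi2 t})/(phi1-phi2)
        + A*[1 + (phi2 e^{phi1 t} - phi1 e^{phi2 t})/(phi1-phi2)]``
        and falls back to the critical form when ``phi1 == phi2``.

    Both forms satisfy x(0) = 0 and, for decaying rate parameters,
    x(t) -> A as t -> infinity.
    """
    t = np.asarray(t, dtype=float)
    D, A, p1, p2 = params.D, params.A, params.phi1, params.phi2
    if form == "critical":
        return D * t * np.exp(p1 * t) + A * (1.0 - np.exp(-p2 * t))
    if form == "overdamped":
        if np.isclose(p1, p2):
            return D * t * np.exp(p1 * t) + A * (1.0 - np.exp(-p2 * t))
        d = p1 - p2
        e1, e2 = np.exp(p1 * t), np.exp(p2 * t)
        return D * (e1 - e2) / d + A * (1.0 + (p2 * e1 - p1 * e2) / d)
    raise InvalidConfigError(f"unknown model form {form!r}")


@dataclass
class FitConfig:
    """Sampler and prior settings for :func:`fit_stability_model`."""

    form: str = "critical"
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    sigma_scale: float = 1.0
    n_walkers: int = 32
    n_steps: int = 20_000
    n_burn: int = 8_000
    thin: int = 4
    seed: int = 0
    time_mapping: dict = field(default_factory=lambda: dict(ORDINAL_TIME))

    def __post_init__(self) -> None:
        if self.n_steps <= self.n_burn:
            raise InvalidConfigError("n_steps must exceed n_burn")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise InvalidConfigError(f"invalid prior bounds for {name}")


class StabilityLandscapeModel(BaseEstimator):
    """Bayesian fit of the impulse-response recovery curve.

    scikit-learn style estimator: ``fit(t, y)`` samples the posterior over
    ``(D, A, phi1, phi2, sigma)``; ``predict(t)`` evaluates the posterior
    median curve.

    Parameters
    ----------
    form : {"critical", "overdamped"}
        Analytic form of the response curve.
    bounds : dict or None
        Uniform prior box per parameter; ``None`` uses :data:`DEFAULT_BOUNDS`.
    sigma_scale : float
        Scale of the half-normal prior on the observation noise sd.
    n_walkers, n_steps, n_burn, thin : int
        Ensemble-sampler settings.  Differential-evolution moves are used;
        on this posterior they mix an order of magnitude faster than the
        default stretch move (integrated autocorrelation ~150-350 steps).
    seed : int
        Seed for walker initialisation and the sampler; fits are
        reproducible bit-for-bit given identical settings.

    Attributes
    ----------
    samples_ : pandas.DataFrame
        Post-burn-in, thinned posterior draws (columns = parameters).
    rhat_ : pandas.Series
        Split-chain potential-scale-reduction statistic per parameter,
        treating each walker as a chain.
    ess_ : pandas.Series
        Effective sample size per parameter (autocorrelation-time based).
    converged_ : bool
        True when max(rhat_) <= 1.05.
    """

    def __init__(
        self,
        form: str = "critical",
        bounds: dict | None = None,
        sigma_scale: float = 1.0,
        n_walkers: int = 32,
        n_steps: int = 20_000,
        n_burn: int = 8_000,
        thin: int = 4,
        seed: int = 0,
    ):
        self.form = form
        self.bounds = bounds
        self.sigma_scale = sigma_scale
        self.n_walkers = n_walkers
        self.n_steps = n_steps
        self.n_burn = n_burn
        self.thin = thin
        self.seed = seed

    # ------------------------------------------------------------------
    def _log_prob(self, theta, t, y, lo, hi):
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        D, A, p1, p2, s = theta
        resid = y - impulse_response(t, StabilityParams(D, A, p1, p2), self.form)
        n = y.size
        return (
            -0.5 * np.dot(resid, resid) / s ** 2
            - n * np.log(s)
            - 0.5 * (s / self.sigma_scale) ** 2
        )

    def fit(self, t, y):
        """Sample the posterior given times ``t`` and displacements ``y``.

        ``y`` may be a flat vector aligned with ``t`` or a
        (replicates x times) matrix; replicate rows share the time grid.
        """
        if self.n_steps <= self.n_burn:
            raise InvalidConfigError("n_steps must exceed n_burn")
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float)
        if t.size == 0:
            raise InvalidConfigError("empty time vector")
        if y.ndim == 2:
            if y.shape[1] != t.size:
                raise InvalidConfigError("displacement matrix does not match times")
            tt = np.tile(t, y.shape[0])
            yy = y.ravel()
        else:
            if y.size != t.size:
                raise InvalidConfigError("displacements do not match times")
            tt, yy = t, y
        if np.unique(tt).size < 3:
            raise InvalidConfigError("need at least 3 distinct time points")
        if np.ptp(yy) == 0:
            warnings.warn(
                "degenerate trajectory: all displacements identical; "
                "sigma posterior is held off zero by its prior floor",
                stacklevel=2,
            )

        bounds = dict(DEFAULT_BOUNDS) if self.bounds is None else dict(self.bounds)
        lo = np.array([bounds[p][0] for p in PARAM_NAMES])
        hi = np.array([bounds[p][1] for p in PARAM_NAMES])

        rng = np.random.default_rng(self.seed)
        # walkers start spread over the interior of the prior box
        span = hi - lo
        start_lo = lo + 0.02 * span
        start_hi = hi - 0.02 * span
        start_hi[4] = min(start_hi[4], 0.5)  # modest initial noise guesses
        p0 = rng.uniform(start_lo, start_hi, size=(self.n_walkers, len(PARAM_NAMES)))

        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(
            self.n_walkers,
            len(PARAM_NAMES),
            self._log_prob,
            args=(tt, yy, lo, hi),
            moves=moves,
        )
        state = emcee.State(
            p0, random_state=np.random.RandomState(self.seed % (2 ** 31)).get_state()
        )
        sampler.run_mcmc(state, self.n_steps, progress=False)

        chain = sampler.get_chain(discard=self.n_burn, thin=self.thin)
        flat = chain.reshape(-1, len(PARAM_NAMES))
        self.samples_ = pd.DataFrame(flat, columns=PARAM_NAMES)
        self.rhat_ = pd.Series(
            _split_rhat(chain), index=list(PARAM_NAMES), name="rhat"
        )
        tau = sampler.get_autocorr_time(discard=self.n_burn, quiet=True)
        n_total = (self.n_steps - self.n_burn) * self.n_walkers
        with np.errstate(divide="ignore"):
            self.ess_ = pd.Series(n_total / tau, index=list(PARAM_NAMES), name="ess")
        self.converged_ = bool(self.rhat_.max() <= 1.05)
        if not self.converged_:
            warnings.warn(
                f"fit flagged: split-chain R-hat max {self.rhat_.max():.3f} > 1.05",
                stacklevel=2,
            )
        self.acceptance_fraction_ = float(np.mean(sampler.acceptance_fraction))
        self.lower_ = lo
        self.upper_ = hi
        return self

    def predict(self, t) -> np.ndarray:
        """Posterior-median displacement curve evaluated at ``t``."""
        med = self.samples_.median()
        params = StabilityParams(med["D"], med["A"], med["phi1"], med["phi2"])
        return impulse_response(np.asarray(t, dtype=float), params, self.form)

    def posterior_summary(self) -> pd.DataFrame:
        """Median and 95% credible interval per parameter."""
        if len(self.samples_) == 0:
            raise InvalidConfigError("empty posterior")
        q = self.samples_.quantile([0.5, 0.025, 0.975]).T
        q.columns = ["median", "ci_lower", "ci_upper"]
        return q[["median", "ci_lower", "ci_upper"]]

    def posterior_skewness(self, param: str = "A") -> float:
        """Moment-based sample skewness of one marginal posterior.

        Returns NaN for a zero-variance posterior (skewness undefined).
        """
        x = self.samples_[param].to_numpy()
        if np.ptp(x) == 0 or np.std(x) == 0:
            return float("nan")
        return float(stats.skew(x, bias=False))


def _split_rhat(chain: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction (walkers treated as chains).

    ``chain`` has shape (draws, chains, params).  Each chain is split in
    half, then the classic between/within variance ratio is formed.
    """
    n, m, k = chain.shape
    half = n // 2
    segs = np.concatenate([chain[:half], chain[half : 2 * half]], axis=1)
    means = segs.mean(axis=0)  # (2m, k)
    var_within = segs.var(axis=0, ddof=1).mean(axis=0)
    var_between = half * means.var(axis=0, ddof=1)
    var_hat = (half - 1) / half * var_within + var_between / half
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_hat / var_within)


# ------------------------------------------------------------- functional API
def fit_stability_model(traj, config: FitConfig | None = None, **overrides):
    """Fit the stability-landscape model to a trajectory.

    ``traj`` is either a :class:`~raresoil.synth.TrajectoryData` (or any
    object exposing ``times`` and ``displacements``) or a ``(t, y)`` tuple.
    Returns the fitted :class:`StabilityLandscapeModel`.
    """
    cfg = config or FitConfig()
    if hasattr(traj, "times") and hasattr(traj, "displacements"):
        t, y = traj.times, traj.displacements
    else:
        t, y = traj
    kwargs = dict(
        form=cfg.form,
        bounds=cfg.bounds,
        sigma_scale=cfg.sigma_scale,
        n_walkers=cfg.n_walkers,
        n_steps=cfg.n_steps,
        n_burn=cfg.n_burn,
        thin=cfg.thin,
        seed=cfg.seed,
    )
    kwargs.update(overrides)
    return StabilityLandscapeModel(**kwargs).fit(t, y)


def posterior_summary(fit: StabilityLandscapeModel) -> pd.DataFrame:
    return fit.posterior_summary()


def posterior_skewness(fit: StabilityLandscapeModel, param: str = "A") -> float:
    return fit.posterior_skewness(param)
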