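"""Phenomenological Hill AND-gate ODE models of dusk-cluster expression.

Each of the three major dusk-gene clusters (Early, Middle, Late) is
coarse-grained to one effective gene X whose 0-1-scaled mean expression
obeys

    dX/dt = B + beta * prod_i f_i(u_i(t)) - alpha * X

where the product runs over the regulatory inputs present in the model
variant: activation by RpaA~P, activation by RpaB~P, and optionally
activation or repression by another cluster's measured expression Y
("feedback"). Each input enters through a Hill term

    activation:  f(u) = (u/K)^H / (1 + (u/K)^H)
    repression:  f(u) = 1 / (1 + (u/K)^H)

with coefficient of activation/repression K and Hill coefficient H.
All driving inputs are *measured* series normalized to [0, 1] across
the four light conditions and interpolated piecewise-linearly; they are
exogenous, never co-simulated.

Parameters are fitted by bounded nonlinear least squares (trust-region
reflective) from multiple Latin-hypercube starts inside the bounding
box (:data:`clocklight.params.BOUNDS`), minimizing the concatenated
residuals of the Clear Day and Shade pulse conditions simultaneously.
The reported error is the square root of the summed squared deviations
between simulation and data. Model variants of different complexity are
compared by AIC = n*ln(RSS/n) + 2k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal
from scipy.integrate import solve_ivp
from scipy.special import expit
from scipy.stats import qmc

from .params import BOUNDS, REFERENCE_FITS
from .regulators import RegulatorTrajectory

__all__ = [
    "HillTerm",
    "ClusterModelSpec",
    "ClusterModelParams",
    "FitResult",
    "ModelComparison",
    "hill_activation",
    "hill_repression",
    "cluster_rhs",
    "simulate_cluster",
    "model_error",
    "fit_model",
    "compare_models_aic",
    "spec_from_variant",
    "params_from_reference",
]

logger = logging.getLogger(__name__)

CLUSTERS = ("Early", "Middle", "Late")

#: Default conditions used for fitting (joint fit; shared parameters).
FIT_CONDITIONS = ("ClearDay", "ShadePulse")


# ---------------------------------------------------------------------------
# Hill terms


def _hill_core(u, K: float, H: float) -> np.ndarray:
    """Activating Hill term with continuous degenerate conventions.

    H = 0 -> 1/2 everywhere (the (u/K)^0 = 1 limit, 0^0 = 1 included);
    K = 0, u > 0 -> 1; u = K = 0 -> 1/2; u = 0, K > 0, H > 0 -> 0.
    These are the limits of (u/K)^H / (1 + (u/K)^H) and keep the fitting
    objective continuous on the closed bounding box.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("regulator level u must be nonnegative")
    if H == 0:
        return np.full(u.shape, 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_u = np.log(u)
        log_k = np.log(K) if K > 0 else -np.inf
        arg = H * (log_u - log_k)
    # u == K == 0 (or u == K generally): -inf - -inf is nan -> symmetry point 1/2
    arg = np.where(np.isnan(arg), 0.0, arg)
    return expit(arg)


def hill_activation(u, K: float, H: float):
    """f = (u/K)^H / (1 + (u/K)^H), equal to 1/2 at u = K."""
    out = _hill_core(u, K, H)
    return float(out) if np.isscalar(u) else out


def hill_repression(u, K: float, H: float):
    """f = 1 / (1 + (u/K)^H); complements :func:`hill_activation` to 1."""
    out = 1.0 - _hill_core(u, K, H)
    return float(out) if np.isscalar(u) else out


# ---------------------------------------------------------------------------
# Model structure


@dataclass(frozen=True)
class HillTerm:
    """One regulatory input: K in [0, 1], H in [0, 7], activating or repressing."""

    K: float
    H: float
    mode: str = "activation"  # "activation" | "repression"

    def __post_init__(self) -> None:
        if self.mode not in ("activation", "repression"):
            raise ValueError(f"mode must be activation or repression, got {self.mode!r}")

    def __call__(self, u):
        if self.mode == "activation":
            return hill_activation(u, self.K, self.H)
        return hill_repression(u, self.K, self.H)


@dataclass(frozen=True)
class ClusterModelSpec:
    """Which inputs drive a target cluster.

    ``regulators`` is a subset of {"RpaA", "RpaB"} (always activating);
    ``feedback`` is None or ``(source_cluster, mode)`` where the source's
    measured expression acts through one additional Hill term.
    """

    target: str
    regulators: tuple[str, ...] = ("RpaA", "RpaB")
    feedback: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        for r in self.regulators:
            if r not in ("RpaA", "RpaB"):
                raise ValueError(f"unknown regulator {r!r}")
        if not self.regulators and self.feedback is None:
            raise ValueError("model needs at least one regulator or a feedback term")
        if self.feedback is not None:
            source, mode = self.feedback
            if source == self.target:
                raise ValueError("feedback source must differ from the target cluster")
            if mode not in ("activation", "repression"):
                raise ValueError(f"feedback mode must be activation or repression, got {mode!r}")

    @property
    def input_names(self) -> tuple[str, ...]:
        names = list(self.regulators)
        if self.feedback is not None:
            names.append(self.feedback[0])
        return tuple(names)

    @property
    def n_free_params(self) -> int:
        """B, beta, alpha plus (K, H) per input: 5, 7 or 9."""
        return 3 + 2 * len(self.input_names)


@dataclass(frozen=True)
class ClusterModelParams:
    """The (up to nine) kinetic parameters of one cluster model.

    ``B`` basal and ``beta`` maximal transcription rate, ``alpha``
    decay/dilution rate (all per hour, normalized expression units);
    one :class:`HillTerm` per input present in the model spec.
    """

    B: float
    beta: float
    alpha: float
    hill_A: HillTerm | None = None
    hill_B: HillTerm | None = None
    hill_Y: HillTerm | None = None

    def validate(self, spec: ClusterModelSpec, bounds: Mapping[str, tuple[float, float]] = BOUNDS) -> None:
        """Check structural consistency with ``spec`` and box bounds.

        Raises ``ValueError`` naming the violated bound.
        """
        def check(name: str, value: float, kind: str) -> None:
            lo, hi = bounds[kind]
            if not (lo <= value <= hi):
                raise ValueError(f"parameter {name}={value} outside bound [{lo}, {hi}]")

        check("B", self.B, "B")
        check("beta", self.beta, "beta")
        check("alpha", self.alpha, "alpha")
        pairs = (("RpaA", self.hill_A), ("RpaB", self.hill_B), ("feedback", self.hill_Y))
        present = {"RpaA": self.hill_A, "RpaB": self.hill_B}
        for reg in ("RpaA", "RpaB"):
            if (reg in spec.regulators) != (present[reg] is not None):
                raise ValueError(f"hill term for {reg} inconsistent with model spec")
        if (spec.feedback is not None) != (self.hill_Y is not None):
            raise ValueError("feedback hill term inconsistent with model spec")
        for label, term in pairs:
            if term is not None:
                check(f"K_{label}", term.K, "K")
                check(f"H_{label}", term.H, "H")

    def terms(self, spec: ClusterModelSpec) -> list[tuple[str, HillTerm]]:
        """(input name, Hill term) pairs in spec order."""
        out: list[tuple[str, HillTerm]] = []
        if "RpaA" in spec.regulators:
            out.append(("RpaA", self.hill_A))
        if "RpaB" in spec.regulators:
            out.append(("RpaB", self.hill_B))
        if spec.feedback is not None:
            out.append((spec.feedback[0], self.hill_Y))
        return out

    # -- flat-vector round trip used by the fitter --------------------------

    def to_vector(self, spec: ClusterModelSpec) -> np.ndarray:
        vec = [self.B, self.beta, self.alpha]
        for _, term in self.terms(spec):
            vec.extend([term.K, term.H])
        return np.asarray(vec)

    @staticmethod
    def from_vector(x: Sequence[float], spec: ClusterModelSpec) -> "ClusterModelParams":
        x = list(x)
        B, beta, alpha = x[:3]
        rest = x[3:]
        hill_A = hill_B = hill_Y = None
        i = 0
        if "RpaA" in spec.regulators:
            hill_A = HillTerm(rest[i], rest[i + 1], "activation")
            i += 2
        if "RpaB" in spec.regulators:
            hill_B = HillTerm(rest[i], rest[i + 1], "activation")
            i += 2
        if spec.feedback is not None:
            hill_Y = HillTerm(rest[i], rest[i + 1], spec.feedback[1])
            i += 2
        return ClusterModelParams(B, beta, alpha, hill_A, hill_B, hill_Y)

    @staticmethod
    def vector_bounds(
        spec: ClusterModelSpec, bounds: Mapping[str, tuple[float, float]] = BOUNDS
    ) -> tuple[np.ndarray, np.ndarray]:
        kinds = ["B", "beta", "alpha"] + ["K", "H"] * len(spec.input_names)
        lo = np.array([bounds[k][0] for k in kinds])
        hi = np.array([bounds[k][1] for k in kinds])
        return lo, hi


def spec_from_variant(variant: str, cluster: str) -> ClusterModelSpec:
    """Build a model spec from a variant label.

    Labels: ``rpaA_only``, ``rpaB_only``, ``joint``, or
    ``feedback:<SourceCluster>:<activation|repression>``.
    """
    if variant == "rpaA_only":
        return ClusterModelSpec(cluster, ("RpaA",))
    if variant == "rpaB_only":
        return ClusterModelSpec(cluster, ("RpaB",))
    if variant == "joint":
        return ClusterModelSpec(cluster, ("RpaA", "RpaB"))
    if variant.startswith("feedback:"):
        _, source, mode = variant.split(":")
        return ClusterModelSpec(cluster, ("RpaA", "RpaB"), (source, mode))
    raise ValueError(f"unknown model variant {variant!r}")


def params_from_reference(variant: str, cluster: str) -> tuple[ClusterModelSpec, ClusterModelParams]:
    """Model spec plus the stored best-fit parameter set for one variant."""
    try:
        row = REFERENCE_FITS[(variant, cluster)]
    except KeyError:
        raise KeyError(f"no reference parameter set for variant {variant!r}, cluster {cluster!r}")
    spec = spec_from_variant(variant, cluster)
    hill_A = HillTerm(row["K_A"], row["H_A"]) if "RpaA" in spec.regulators else None
    hill_B = HillTerm(row["K_B"], row["H_B"]) if "RpaB" in spec.regulators else None
    hill_Y = (
        HillTerm(row["K_Y"], row["H_Y"], spec.feedback[1]) if spec.feedback is not None else None
    )
    return spec, ClusterModelParams(row["B"], row["beta"], row["alpha"], hill_A, hill_B, hill_Y)


# ---------------------------------------------------------------------------
# Simulation


def _production(
    params: ClusterModelParams,
    spec: ClusterModelSpec,
    inputs: Mapping[str, np.ndarray],
) -> np.ndarray:
    """B + beta * prod of Hill terms, vectorized over pre-evaluated inputs."""
    prod = 1.0
    for name, term in params.terms(spec):
        prod = prod * term(inputs[name])
    return params.B + params.beta * prod


def cluster_rhs(
    t: float,
    X: float,
    params: ClusterModelParams,
    spec: ClusterModelSpec,
    regulators: Mapping[str, RegulatorTrajectory],
) -> float:
    """dX/dt = B + beta * prod_i f_i(u_i(t)) - alpha * X."""
    for name in spec.input_names:
        traj = regulators[name]
        if t < traj.times[0] - 1e-9 or t > traj.times[-1] + 1e-9:
            raise ValueError(f"time {t} outside the domain of regulator {name!r}")
    inputs = {name: np.asarray(regulators[name].at(t)) for name in spec.input_names}
    P = _production(params, spec, inputs)
    rhs = P - params.alpha * np.asarray(X, dtype=float)
    return float(rhs) if rhs.ndim == 0 else rhs


def _phi_coefficients(alpha: float, h: float) -> tuple[float, float, float]:
    """Exponential-integrator weights for one step of dX/dt = P(t) - alpha*X.

    With P linear on the step (P0 -> P1):
      X(h) = a*X0 + h*phi1*P0 + h*phi2*(P1 - P0),
      a = exp(-alpha h), phi1 = (1-a)/(alpha h), phi2 = (alpha h - (1-a))/(alpha h)^2.
    Series expansions keep the weights accurate as alpha*h -> 0.
    """
    z = alpha * h
    a = math.exp(-z)
    if z < 1e-6:
        phi1 = 1.0 - z / 2.0 + z * z / 6.0
        phi2 = 0.5 - z / 6.0 + z * z / 24.0
    else:
        phi1 = -math.expm1(-z) / z
        phi2 = (z + math.expm1(-z)) / (z * z)
    return a, phi1, phi2


def simulate_cluster(
    params: ClusterModelParams,
    spec: ClusterModelSpec,
    regulators: Mapping[str, RegulatorTrajectory],
    t_grid: np.ndarray,
    X0: float,
    method: str = "exp",
    dt: float = 0.005,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> np.ndarray:
    """Integrate the cluster ODE and return X at ``t_grid``.

    ``method="exp"`` (default) exploits the linearity of the ODE in X:
    the production term is evaluated on a fixed fine grid (step ``dt``
    hours) and propagated with an exact exponential integrator assuming
    piecewise-linear production — fast and unconditionally stable even
    for decay rates near the upper bound (80/h). ``method="rk45"`` uses
    an adaptive explicit Runge-Kutta solver at the given tolerances and
    serves as an independent cross-check.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if X0 < 0:
        raise ValueError("X0 must be nonnegative")
    for name in spec.input_names:
        traj = regulators[name]
        if traj.times[0] > t_grid[0] + 1e-9 or traj.times[-1] < t_grid[-1] - 1e-9:
            raise ValueError(f"regulator {name!r} does not cover the simulation span")

    if method == "rk45":
        sol = solve_ivp(
            cluster_rhs,
            (t_grid[0], t_grid[-1]),
            [X0],
            t_eval=t_grid,
            args=(params, spec, regulators),
            rtol=rtol,
            atol=atol,
            max_step=0.25,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        return sol.y[0]
    if method != "exp":
        raise ValueError(f"unknown integration method {method!r}")

    t0, t1 = float(t_grid[0]), float(t_grid[-1])
    if t1 == t0:
        return np.full(t_grid.shape, X0)
    n = max(2, int(math.ceil((t1 - t0) / dt)) + 1)
    fine = np.linspace(t0, t1, n)
    h = fine[1] - fine[0]
    inputs = {
        name: np.interp(fine, regulators[name].times, regulators[name].values)
        for name in spec.input_names
    }
    P = np.broadcast_to(np.asarray(_production(params, spec, inputs), dtype=float), fine.shape)

    a, phi1, phi2 = _phi_coefficients(params.alpha, h)
    # Per-step increment c_k maps X_k -> X_{k+1} = a*X_k + c_k.
    c = h * (phi1 * P[:-1] + phi2 * (P[1:] - P[:-1]))
    # The linear recurrence is an IIR filter: X_{k+1} = a*X_k + c_k.
    x_rest = signal.lfilter([1.0], [1.0, -a], c, zi=np.array([a * X0]))[0]
    X = np.concatenate(([X0], x_rest))
    return np.interp(t_grid, fine, X)


def model_error(
    sim: Mapping[str, np.ndarray] | np.ndarray,
    data: Mapping[str, np.ndarray] | np.ndarray,
) -> float:
    """sqrt of the summed squared deviations over all conditions and times."""
    if isinstance(sim, Mapping) != isinstance(data, Mapping):
        raise ValueError("sim and data must both be mappings or both be arrays")
    if isinstance(sim, Mapping):
        if set(sim) != set(data):
            raise ValueError(f"condition mismatch: {sorted(sim)} vs {sorted(data)}")
        sse = 0.0
        for cond in sim:
            s, d = np.asarray(sim[cond]), np.asarray(data[cond])
            if s.shape != d.shape:
                raise ValueError(f"misaligned grids for condition {cond!r}")
            sse += float(np.sum((s - d) ** 2))
        return math.sqrt(sse)
    s, d = np.asarray(sim), np.asarray(data)
    if s.shape != d.shape:
        raise ValueError("misaligned grids")
    return math.sqrt(float(np.sum((s - d) ** 2)))


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitResult:
    """Outcome of a bounded multi-start least-squares fit."""

    spec: ClusterModelSpec
    params: ClusterModelParams
    error: float
    n_starts: int
    seed: int
    simulated: dict[str, np.ndarray]
    data_times: dict[str, np.ndarray]
    n_data: int
    k_params: int

    def aic(self) -> float:
        rss = max(self.error**2, 1e-300)
        return self.n_data * math.log(rss / self.n_data) + 2 * self.k_params


def _residual_factory(spec, data, regulators, conditions, method, dt):
    times = {c: np.asarray(data[c][0], dtype=float) for c in conditions}
    values = {c: np.asarray(data[c][1], dtype=float) for c in conditions}

    def residual(x: np.ndarray) -> np.ndarray:
        p = ClusterModelParams.from_vector(x, spec)
        res = []
        for c in conditions:
            sim = simulate_cluster(
                p, spec, regulators[c], times[c], X0=values[c][0], method=method, dt=dt
            )
            res.append(sim - values[c])
        return np.concatenate(res)

    return residual, times, values


def fit_model(
    spec: ClusterModelSpec,
    data: Mapping[str, tuple[np.ndarray, np.ndarray]],
    regulators: Mapping[str, Mapping[str, RegulatorTrajectory]],
    bounds: Mapping[str, tuple[float, float]] = BOUNDS,
    n_starts: int = 64,
    seed: int = 0,
    conditions: Sequence[str] = FIT_CONDITIONS,
    method: str = "exp",
    dt: float = 0.005,
) -> FitResult:
    """Fit one model variant to 0-1-scaled cluster data.

    ``data`` maps condition -> (times, values); ``regulators`` maps
    condition -> {input name -> 0-1 RegulatorTrajectory}. Both fitted
    conditions share one parameter vector; each condition is simulated
    from its own first observation. Starts are a seeded Latin hypercube
    in the bounding box; the best converged start (lowest cost) wins.
    """
    from scipy.optimize import least_squares

    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    for c in conditions:
        if c not in data:
            raise ValueError(f"fitting condition {c!r} missing from data")

    residual, times, values = _residual_factory(spec, data, regulators, conditions, method, dt)
    lo, hi = ClusterModelParams.vector_bounds(spec, bounds)
    sampler = qmc.LatinHypercube(d=len(lo), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)

    best = None
    failures: list[str] = []
    for x0 in starts:
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi), method="trf", x_scale=np.maximum(hi - lo, 1e-3))
        except Exception as exc:  # pragma: no cover - solver-internal failures
            failures.append(str(exc))
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed to converge: " + "; ".join(failures))

    params = ClusterModelParams.from_vector(best.x, spec)
    params.validate(spec, bounds)
    simulated = {
        c: simulate_cluster(params, spec, regulators[c], times[c], X0=values[c][0], method=method, dt=dt)
        for c in conditions
    }
    err = model_error(simulated, {c: values[c] for c in conditions})
    n_data = int(sum(v.size for v in values.values()))
    return FitResult(
        spec=spec,
        params=params,
        error=err,
        n_starts=n_starts,
        seed=seed,
        simulated=simulated,
        data_times=times,
        n_data=n_data,
        k_params=spec.n_free_params,
    )


@dataclass
class ModelComparison:
    """AIC comparison of fits of one cluster against identical data."""

    fits: list[FitResult]
    aic: list[float]
    ranking: list[int]  # indices into fits, ascending AIC

    @property
    def best(self) -> FitResult:
        return self.fits[self.ranking[0]]


def compare_models_aic(fits: Sequence[FitResult]) -> ModelComparison:
    """Rank model fits by AIC = n*ln(RSS/n) + 2k (ascending)."""
    if not fits:
        raise ValueError("no fits to compare")
    n = fits[0].n_data
    for f in fits:
        if f.n_data != n:
            raise ValueError("fits compare different data sizes; AIC is not comparable")
    aics = [f.aic() for f in fits]
    ranking = sorted(range(len(fits)), key=lambda i: aics[i])
    return ModelComparison(list(fits), aics, ranking)


def aic_from_error(error: float, n: int, k: int) -> float:
    """AIC for a least-squares fit given its root-summed-square error."""
    rss = max(error**2, 1e-300)
    return n * math.log(rss / n) + 2 * k
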