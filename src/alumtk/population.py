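"""Mixed-effects population layer.

Inter-study (rat) and inter-individual (human) variability is modelled with
fixed effects θ (population values) plus normally distributed random effects
on a transformed scale: log for intrinsically positive parameters,
logit for fraction parameters.  Residual variability is an additive error on
the log scale, i.e. a log-normal multiplicative error on the original scale.

Three layers are provided:

* sampling: draw individual parameter sets and noisy observations;
* Monte-Carlo prediction: percentile bands of the model observables over a
  population (median plus the central 20/40/60/80% bands);
* estimation: :class:`PopulationFitter`, a Laplace-approximated marginal
  maximum-likelihood fitter (Gauss–Newton inner optimisation over the
  per-group random effects) for recovering a reduced set of fixed effects
  from curated observation tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .physiology import InvalidInputError, ReferenceIndividual, reference_for
from .model import DoseEvent, PBTKParameters, simulate
from .model import (_IDX, _LTIPropagator, _N_STATES, _TISSUE_SLICE,
                    _citrate_phase, _lti_matrix, _rate_constants)

__all__ = [
    "ParameterDistribution",
    "PopulationModel",
    "PercentileBands",
    "default_population",
    "population_to_dict",
    "population_from_dict",
    "sample_individual",
    "apply_residual_error",
    "simulate_population",
    "PopulationFitter",
    "fit_population",
]

#: Central band levels of the percentile plots.
BAND_LEVELS = (20, 40, 60, 80)

#: Random-effect SDs of the glomerular filtration rate, shared per species.
GFR_OMEGA = {"rat": 0.894, "human": 0.381}


class ConvergenceError(RuntimeError):
    """Estimation failed to converge; ``.fitter`` holds best-so-far estimates."""

    def __init__(self, message: str, fitter: "PopulationFitter"):
        super().__init__(message)
        self.fitter = fitter


def _transform(transform: str, value: float) -> float:
    if transform == "log":
        return math.log(value)
    if transform == "logit":
        return float(logit(value))
    return value


def _back_transform(transform: str, value: float) -> float:
    if transform == "log":
        return math.exp(value)
    if transform == "logit":
        return float(expit(value))
    return value


@dataclass(frozen=True)
class ParameterDistribution:
    """Population distribution of one structural parameter.

    ``theta`` is the fixed effect on the original scale, ``omega`` the SD of
    the random effect on the transformed scale.  ``transform="fixed"`` means
    the parameter never varies.  ``theta=None`` (only used for GFR) defers
    the fixed effect to the reference individual at sampling time.
    """

    name: str
    transform: str
    theta: float | None
    omega: float = 0.0

    def __post_init__(self) -> None:
        if self.transform not in ("log", "logit", "fixed"):
            raise InvalidInputError(f"unknown transform {self.transform!r}")
        if self.omega < 0:
            raise InvalidInputError(f"omega must be non-negative, got {self.omega}")
        if self.theta is not None:
            if self.transform == "log" and self.theta <= 0:
                raise InvalidInputError(f"{self.name}: log transform needs theta > 0")
            if self.transform == "logit" and not 0.0 < self.theta < 1.0:
                raise InvalidInputError(f"{self.name}: logit transform needs theta in (0,1)")

    def sample(self, rng: np.random.Generator, theta: float | None = None,
               omega: float | None = None) -> float:
        th = self.theta if theta is None else theta
        om = self.omega if omega is None else omega
        if self.transform == "fixed" or om == 0.0:
            return th
        return _back_transform(self.transform, _transform(self.transform, th)
                               + rng.normal(0.0, om))


@dataclass
class PopulationModel:
    """Fixed effects, random-effect SDs and residual error of the population.

    ``sigma_res`` is the residual SD on the log scale, shared across
    observation matrices.
    """

    distributions: dict[str, ParameterDistribution]
    sigma_res: float = 0.5
    gfr_omega: Mapping[str, float] = field(default_factory=lambda: dict(GFR_OMEGA))

    def __post_init__(self) -> None:
        if self.sigma_res < 0:
            raise InvalidInputError(f"sigma_res must be non-negative, got {self.sigma_res}")

    def distribution(self, name: str) -> ParameterDistribution:
        return self.distributions[name]

    def updated(self, **theta_updates) -> "PopulationModel":
        dists = dict(self.distributions)
        for name, theta in theta_updates.items():
            dists[name] = replace(dists[name], theta=theta)
        return replace(self, distributions=dists)


def default_population(sigma_res: float = 0.5) -> PopulationModel:
    """Population model at the calibrated fixed effects and variabilities.

    ω > 0 only for the oral absorption rate, bioavailability, the
    liver/spleen/kidney and bone uptake coefficients, the bone retention
    coefficient and (per species) GFR.
    """
    specs = [
        ("k_gut2blo", "log",   2.43,    1.34),
        ("F",         "logit", 0.00182, 1.03),
        ("I_lsk",     "logit", 8.854e-4, 1.39),
        ("I_mus",     "logit", 0.00981, 0.0),
        ("I_bon",     "logit", 0.01920, 0.763),
        ("I_bra",     "logit", 2.14e-5, 0.0),
        ("I_rob",     "fixed", 1.0,     0.0),
        ("K_lsk",     "log",   5.29e4,  0.0),
        ("K_mus",     "log",   116.0,   0.0),
        ("K_bon",     "log",   1.16e5,  0.556),
        ("K_bra",     "fixed", math.inf, 0.0),
        ("K_rob",     "fixed", 1.0,     0.0),
        ("k_Cit2Mix", "log",   0.193,   0.0),
        ("fu_Cit",    "fixed", 1.0,     0.0),
        ("fu_Mix",    "fixed", 0.1,     0.0),
        ("GFR",       "log",   None,    0.0),  # theta/omega resolved per reference
    ]
    dists = {name: ParameterDistribution(name, tr, th, om) for name, tr, th, om in specs}
    return PopulationModel(distributions=dists, sigma_res=sigma_res)


def population_to_dict(pop: PopulationModel) -> dict:
    """Plain-dict form of a population model (YAML/JSON serialisable)."""
    dists = {}
    for name, d in pop.distributions.items():
        theta = d.theta
        if theta is not None and math.isinf(theta):
            theta = "inf"
        dists[name] = {"transform": d.transform, "theta": theta, "omega": d.omega}
    return {"distributions": dists, "sigma_res": pop.sigma_res,
            "gfr_omega": dict(pop.gfr_omega)}


def population_from_dict(data: Mapping) -> PopulationModel:
    """Inverse of :func:`population_to_dict`."""
    dists = {}
    for name, spec in data["distributions"].items():
        theta = spec["theta"]
        if theta == "inf":
            theta = math.inf
        dists[name] = ParameterDistribution(name, spec["transform"], theta,
                                            spec.get("omega", 0.0))
    return PopulationModel(distributions=dists,
                           sigma_res=data.get("sigma_res", 0.5),
                           gfr_omega=dict(data.get("gfr_omega", GFR_OMEGA)))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_individual(pop: PopulationModel, ref: ReferenceIndividual,
                      seed) -> PBTKParameters:
    """Draw one individual parameter set from the population.

    Each parameter's fixed effect is transformed, perturbed by a
    Normal(0, ω²) random effect and back-transformed; fixed parameters are
    returned unchanged.  Deterministic for a given seed.
    """
    rng = _as_rng(seed)
    values = {}
    for name, dist in pop.distributions.items():
        if name == "GFR":
            theta = dist.theta if dist.theta is not None else ref.GFR
            omega = dist.omega if dist.theta is not None else pop.gfr_omega[ref.species]
            values[name] = dist.sample(rng, theta=theta, omega=omega)
        else:
            values[name] = dist.sample(rng)
    return PBTKParameters(Hct=ref.Hct, **values)


def apply_residual_error(prediction, sigma_res: float, seed):
    """Multiply predictions by a log-normal residual exp(N(0, σ²))."""
    rng = _as_rng(seed)
    pred = np.asarray(prediction, dtype=float)
    if np.any(pred <= 0):
        raise InvalidInputError("predictions must be positive for the log-scale error model")
    noisy = pred * np.exp(rng.normal(0.0, sigma_res, size=pred.shape))
    return float(noisy) if np.isscalar(prediction) else noisy


#: Observables reported by the population simulation.
DEFAULT_OBSERVABLES = ("blo", "pla", "uri", "liv", "spl", "mus", "bon", "bra", "kid", "rob", "ret")


@dataclass
class PercentileBands:
    """Median and central percentile bands of population predictions."""

    t: np.ndarray
    percentiles: dict[str, pd.DataFrame]   # observable -> (n_t × percentile labels)
    n: int

    def median(self, observable: str) -> np.ndarray:
        return self.percentiles[observable]["p50"].to_numpy()

    def band(self, observable: str, level: int) -> tuple[np.ndarray, np.ndarray]:
        """Bounds of the central ``level``% band, e.g. level=80 → (p10, p90)."""
        lo = (100 - level) / 2
        frame = self.percentiles[observable]
        return frame[f"p{lo:g}"].to_numpy(), frame[f"p{100 - lo:g}"].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_h, observable, percentile, value."""
        rows = []
        for obs, frame in self.percentiles.items():
            for col in frame.columns:
                rows.append(pd.DataFrame({
                    "time_h": self.t, "observable": obs,
                    "percentile": float(col[1:]), "value": frame[col].to_numpy(),
                }))
        return pd.concat(rows, ignore_index=True)


def simulate_population(pop: PopulationModel, ref: ReferenceIndividual,
                        doses: Sequence[DoseEvent], t_grid: Sequence[float],
                        n: int = 250, seed=0,
                        observables: Sequence[str] = DEFAULT_OBSERVABLES,
                        ) -> PercentileBands:
    """Monte-Carlo percentile prediction over ``n`` sampled individuals."""
    if n < 2:
        raise InvalidInputError("population simulation needs n >= 2")
    rng = _as_rng(seed)
    t_grid = np.asarray(t_grid, dtype=float)
    traces = {obs: np.empty((n, len(t_grid))) for obs in observables}
    for i in range(n):
        params = sample_individual(pop, ref, rng)
        res = simulate(params, ref, doses, t_grid)
        for obs in observables:
            traces[obs][i] = res.series(obs)
    qs = sorted({50.0} | {(100 - lev) / 2 for lev in BAND_LEVELS}
                | {100 - (100 - lev) / 2 for lev in BAND_LEVELS})
    percentiles = {}
    for obs in observables:
        mat = np.percentile(traces[obs], qs, axis=0).T
        percentiles[obs] = pd.DataFrame(mat, columns=[f"p{q:g}" for q in qs])
    return PercentileBands(t=t_grid, percentiles=percentiles, n=n)


# ---------------------------------------------------------------------------
# estimation


def _human_ref_for_bw(bw_kg: float) -> ReferenceIndividual:
    male, female = reference_for("human", "male"), reference_for("human", "female")
    return male if abs(bw_kg - male.BW) <= abs(bw_kg - female.BW) else female


def resolve_reference(species: str, body_weight_kg: float,
                      sex: str | None = None) -> ReferenceIndividual:
    """Reference individual for one study group.

    Rats resolve by body weight; humans by sex when given, otherwise by the
    nearer reference body weight.
    """
    if species in ("hum", "human"):
        if sex is not None:
            return reference_for("human", sex)
        return _human_ref_for_bw(body_weight_kg)
    return reference_for("rat", body_weight_kg)


@dataclass
class _Group:
    key: str
    ref: ReferenceIndividual
    route: str
    salt: str
    dose: DoseEvent
    times_unique: np.ndarray       # sorted unique observation times, h
    obs_time_idx: np.ndarray       # per-observation index into times_unique
    matrices: list[str]
    log_y: np.ndarray
    eta: np.ndarray | None = None  # warm-started random-effect mode
    cit_cache: tuple | None = None  # (psi_key, early_states, t_switch, y_switch)


def _extract_series(states: np.ndarray, matrix: str) -> np.ndarray:
    """Observable column(s) from a (n_t, n_states) state matrix."""
    if matrix in ("blo", "pla"):
        return states[:, _IDX["addCit"]] + states[:, _IDX["Mix"]]
    if matrix == "ret":
        return (states[:, _IDX["gut"]] + states[:, _IDX["addCit"]]
                + states[:, _IDX["Mix"]] + states[:, _TISSUE_SLICE].sum(axis=1))
    return states[:, _IDX[matrix]]


class PopulationFitter:
    """Approximate marginal maximum-likelihood estimation of fixed effects.

    The marginal likelihood over the per-group random effects is
    approximated by Laplace's method at the posterior mode, with the
    Gauss–Newton curvature JᵀJ/σ² + Ω⁻¹ standing in for the Hessian.  The
    inner mode search is a damped Gauss–Newton iteration with
    finite-difference Jacobians, warm-started across outer iterations.

    Parameters
    ----------
    estimate : names of the fixed effects to estimate; all others stay at
        their ``pop0`` values.
    estimate_sigma : whether to estimate the residual SD.
    random_effects : names carrying a per-group random effect during the
        fit; defaults to every parameter with ω > 0 in ``pop0`` (including
        GFR, whose ω is species-specific), so that the variability model
        matches the generating population.  The ω values themselves are
        held fixed.

    Attributes (after ``fit``)
    --------------------------
    theta_ : dict of estimated fixed effects on the original scale.
    se_transformed_ : approximate SEs on the log/logit scale.
    sigma_res_ : estimated (or fixed) residual SD.
    eta_ : per-group MAP modes of the random effects (empirical Bayes).
    loglik_ : approximate marginal log-likelihood at the optimum.
    converged_ : optimiser success flag.
    """

    def __init__(self, estimate: Sequence[str] = ("F", "k_gut2blo", "K_bon"),
                 estimate_sigma: bool = True,
                 random_effects: Sequence[str] | None = None,
                 rtol: float = 1e-4, atol: float = 1e-9,
                 maxiter: int = 300, inner_maxiter: int = 25,
                 cit_switch: float = 1e-9, sigma_min: float = 1e-4,
                 raise_on_failure: bool = True):
        self.estimate = tuple(estimate)
        self.estimate_sigma = estimate_sigma
        self.random_effects = None if random_effects is None else tuple(random_effects)
        self.rtol = rtol
        self.atol = atol
        self.maxiter = maxiter
        self.inner_maxiter = inner_maxiter
        self.cit_switch = cit_switch
        self.sigma_min = sigma_min
        self.raise_on_failure = raise_on_failure

    # -- data plumbing ------------------------------------------------------

    def _build_groups(self, data: pd.DataFrame) -> list[_Group]:
        from .curation import parse_identifier

        required = {"identifier", "group_id", "time_h", "matrix", "value"}
        missing = required - set(data.columns)
        if missing:
            raise InvalidInputError(f"fit data lacks columns {sorted(missing)}")
        groups = []
        for key, sub in data.groupby("group_id", sort=True):
            if len(sub) == 0 or sub["value"].le(0).any():
                raise InvalidInputError(f"group {key!r} is empty or has non-positive values")
            ident = parse_identifier(sub["identifier"].iloc[0])
            sex = sub["sex"].iloc[0] if "sex" in sub.columns and pd.notna(sub["sex"].iloc[0]) else None
            ref = resolve_reference(ident.species, ident.body_weight_kg, sex)
            salt = "citrate" if ident.salt == "AlCit" else "chloride"
            times = sub["time_h"].to_numpy(dtype=float)
            times_unique = np.unique(times)
            groups.append(_Group(key=str(key), ref=ref, route=ident.route,
                                 salt=salt, dose=DoseEvent(0.0, ident.route, salt, 1.0),
                                 times_unique=times_unique,
                                 obs_time_idx=np.searchsorted(times_unique, times),
                                 matrices=list(sub["matrix"]),
                                 log_y=np.log(sub["value"].to_numpy(dtype=float))))
        if not groups:
            raise InvalidInputError("no groups in fit data")
        return groups

    def _states_at(self, group: _Group, params: PBTKParameters,
                   psi: np.ndarray, eta: np.ndarray) -> np.ndarray:
        """States at the group's unique observation times.

        Groups without circulating injected citrate are linear and are
        propagated exactly by eigendecomposition.  For iv citrate groups the
        short non-linear phase is integrated once per outer iteration at the
        population random effects (η = 0) and cached — the random effects of
        the estimated parameters have negligible influence there — while the
        η-dependent linear continuation is recomputed exactly.
        """
        y0 = np.zeros(_N_STATES)
        y0[_IDX[group.dose.target_state]] = group.dose.amount
        times = group.times_unique
        k_in, k_out = _rate_constants(params, group.ref)
        if not (group.route == "iv" and group.salt == "citrate"):
            prop = _LTIPropagator(_lti_matrix(params, group.ref, k_in, k_out))
            return prop(y0, times)

        psi_key = psi.tobytes()
        if group.cit_cache is None or group.cit_cache[0] != psi_key:
            values0 = self._values_for(psi, group, np.zeros(len(self._re_names)))
            params0 = PBTKParameters(Hct=group.ref.Hct, **values0)
            k_in0, k_out0 = _rate_constants(params0, group.ref)
            t1 = float(times[-1])
            vals, filled, t_sw, y_sw = _citrate_phase(
                params0, group.ref, k_in0, k_out0, y0, 0.0, t1, times,
                self.rtol, self.atol, switch=self.cit_switch)
            y_sw = y_sw.copy()
            y_sw[_IDX["Mix"]] += max(y_sw[_IDX["addCit"]], 0.0)
            y_sw[_IDX["addCit"]] = 0.0
            group.cit_cache = (psi_key, vals, filled, t_sw, y_sw)
        _, vals, filled, t_sw, y_sw = group.cit_cache
        states = np.array(vals, copy=True)
        rest = ~filled
        if np.any(rest):
            prop = _LTIPropagator(_lti_matrix(params, group.ref, k_in, k_out))
            states[rest] = prop(y_sw, times[rest] - t_sw)
        return states

    def _predict_log(self, group: _Group, values: dict[str, float],
                     psi: np.ndarray, eta: np.ndarray) -> np.ndarray:
        params = PBTKParameters(Hct=group.ref.Hct, **values)
        states = np.clip(self._states_at(group, params, psi, eta), 0.0, None)
        out = np.empty(len(group.matrices))
        cache = {}
        for i, (mat, gi) in enumerate(zip(group.matrices, group.obs_time_idx)):
            if mat not in cache:
                cache[mat] = _extract_series(states, mat)
            out[i] = cache[mat][gi]
        return np.log(np.clip(out, 1e-300, None))

    # -- likelihood ---------------------------------------------------------

    def _omega_for(self, group: _Group) -> np.ndarray:
        """Random-effect SDs for one group (GFR ω is species-specific)."""
        out = np.empty(len(self._re_names))
        for i, name in enumerate(self._re_names):
            if name == "GFR":
                out[i] = self._pop0.gfr_omega[group.ref.species]
            else:
                out[i] = self._pop0.distributions[name].omega
        return out

    def _values_for(self, psi: np.ndarray, group: _Group, eta: np.ndarray) -> dict:
        values = {}
        for name, dist in self._pop0.distributions.items():
            theta = dist.theta
            if name == "GFR" and theta is None:
                theta = group.ref.GFR
            tr = dist.transform
            z = _transform(tr, theta) if tr != "fixed" else theta
            if name in self._psi_index:
                z = psi[self._psi_index[name]]
            if name in self._re_index:
                z = z + eta[self._re_index[name]]
            values[name] = _back_transform(tr, z) if tr != "fixed" else z
        return values

    def _group_marginal_nll(self, psi: np.ndarray, sigma: float, group: _Group) -> float:
        d = len(self._re_names)
        omega = self._omega_for(group)
        eta = group.eta if group.eta is not None else np.zeros(d)

        def residuals(eta_):
            pred = self._predict_log(group, self._values_for(psi, group, eta_),
                                     psi, eta_)
            return group.log_y - pred

        # oral-absorption parameters cannot influence iv groups
        active = [j for j, name in enumerate(self._re_names)
                  if not (group.route == "iv" and name in ("F", "k_gut2blo"))]

        def joint_nll(eta_, r):
            return (0.5 * float(r @ r) / sigma**2 + len(r) * math.log(sigma)
                    + 0.5 * float((eta_ / omega) @ (eta_ / omega))
                    + float(np.sum(np.log(omega))) + 0.5 * d * math.log(2 * math.pi))

        if d == 0:
            r = residuals(np.zeros(0))
            return 0.5 * float(r @ r) / sigma**2 + len(r) * math.log(sigma)

        # damped Gauss-Newton search for the posterior mode of eta; the
        # finite-difference Jacobian is frozen across accepted steps and
        # recomputed only after a rejected step
        h = 1e-4
        r = residuals(eta)
        nll = joint_nll(eta, r)
        lam = 1e-6
        J = np.zeros((len(r), d))

        def refresh_J():
            for j in active:
                e = eta.copy()
                e[j] += h
                J[:, j] = (residuals(e) - r) / h  # d(residual)/d(eta) = -df/d(eta)

        refresh_J()
        stale = False
        for _ in range(self.inner_maxiter):
            H = J.T @ J / sigma**2 + np.diag(1.0 / omega**2)
            g = J.T @ r / sigma**2 + eta / omega**2
            step = np.linalg.solve(H + lam * np.eye(d), -g)
            if float(np.abs(step).max()) < 1e-5:
                break  # at the mode (common once warm-started)
            eta_new = eta + step
            r_new = residuals(eta_new)
            nll_new = joint_nll(eta_new, r_new)
            if nll_new <= nll + 1e-12:
                improvement = nll - nll_new
                eta, r, nll = eta_new, r_new, nll_new
                lam = max(lam / 4, 1e-8)
                stale = True
                if improvement < 1e-8:
                    break
            elif stale:
                refresh_J()
                stale = False
            else:
                lam *= 10
                if lam > 1e6:
                    break
        group.eta = eta.copy()
        if stale:
            refresh_J()
        H = J.T @ J / sigma**2 + np.diag(1.0 / omega**2)
        sign, logdet = np.linalg.slogdet(H)
        # Laplace: -log integral = joint nll at mode + 0.5 log det H - d/2 log(2pi)
        return nll + 0.5 * logdet - 0.5 * d * math.log(2 * math.pi)

    def _total_nll(self, x: np.ndarray) -> float:
        psi = x[: len(self.estimate)]
        sigma = math.exp(x[-1]) if self.estimate_sigma else self._sigma0
        sigma = max(sigma, self.sigma_min)  # numerical floor for noise-free data
        if sigma <= 0 or not np.all(np.isfinite(x)):
            return 1e10
        try:
            return float(sum(self._group_marginal_nll(psi, sigma, g) for g in self._groups))
        except (InvalidInputError, np.linalg.LinAlgError):
            return 1e10

    # -- public API ---------------------------------------------------------

    def fit(self, data: pd.DataFrame, pop0: PopulationModel | None = None) -> "PopulationFitter":
        """Estimate the selected fixed effects from a curated fid table.

        ``data`` columns: identifier, group_id, time_h, matrix, value (fid),
        optionally sex.  ``pop0`` supplies initial values and the fixed ω's.
        """
        self._pop0 = pop0 if pop0 is not None else default_population()
        self._groups = self._build_groups(data)
        for name in self.estimate:
            if name not in self._pop0.distributions:
                raise InvalidInputError(f"unknown parameter {name!r}")
            if self._pop0.distributions[name].transform == "fixed":
                raise InvalidInputError(f"parameter {name!r} is fixed and cannot be estimated")
        if self.random_effects is not None:
            re_names = tuple(self.random_effects)
        else:
            re_names = tuple(
                n for n, dist in self._pop0.distributions.items()
                if dist.omega > 0
                or (n == "GFR" and max(self._pop0.gfr_omega.values()) > 0))
        self._re_names = re_names
        self._re_index = {n: i for i, n in enumerate(re_names)}
        self._psi_index = {n: i for i, n in enumerate(self.estimate)}
        self._sigma0 = self._pop0.sigma_res if self._pop0.sigma_res > 0 else 0.5
        for group in self._groups:
            if np.any(self._omega_for(group) <= 0):
                raise InvalidInputError("random-effect parameters need omega > 0 in pop0")

        x0 = []
        for name in self.estimate:
            dist = self._pop0.distributions[name]
            x0.append(_transform(dist.transform, dist.theta))
        if self.estimate_sigma:
            x0.append(math.log(self._sigma0))
        x0 = np.asarray(x0)

        for g in self._groups:
            g.eta = np.zeros(len(re_names))

        opt = minimize(self._total_nll, x0, method="Nelder-Mead",
                       options={"maxiter": self.maxiter, "xatol": 1e-2,
                                "fatol": 2e-2, "adaptive": True})
        self.converged_ = bool(opt.success)
        self.n_iter_ = int(opt.nit)
        self.loglik_ = -float(opt.fun)
        x_hat = opt.x

        psi_hat = x_hat[: len(self.estimate)]
        self.theta_ = {}
        self.theta_transformed_ = {}
        for name in self.estimate:
            tr = self._pop0.distributions[name].transform
            self.theta_transformed_[name] = float(psi_hat[self._psi_index[name]])
            self.theta_[name] = _back_transform(tr, psi_hat[self._psi_index[name]])
        self.sigma_res_ = (max(math.exp(x_hat[-1]), self.sigma_min)
                           if self.estimate_sigma else self._sigma0)
        self.population_ = self._pop0.updated(**self.theta_)
        if self.estimate_sigma:
            self.population_ = replace(self.population_, sigma_res=self.sigma_res_)

        self._compute_uncertainty(x_hat)
        self.eta_ = {g.key: (g.eta.copy() if g.eta is not None else None)
                     for g in self._groups}
        if not self.converged_:
            msg = f"optimiser did not converge in {self.maxiter} iterations"
            if self.raise_on_failure:
                raise ConvergenceError(msg, self)
            warnings.warn(msg, RuntimeWarning)
        return self

    def _compute_uncertainty(self, x_hat: np.ndarray) -> None:
        """Approximate SEs from a finite-difference Hessian of the marginal NLL.

        The step is sized well above the inner-optimisation tolerance so the
        profile (not the joint) curvature is measured.  A non-positive
        curvature (optimiser stopped short of a clean optimum) is handled by
        enlarging the step and, failing that, clipping the Hessian spectrum.
        """
        n = len(x_hat)

        def fd_hessian(h: float) -> np.ndarray:
            H = np.empty((n, n))
            f0 = self._total_nll(x_hat)
            fp = np.empty(n)
            fm = np.empty(n)
            for i in range(n):
                e = np.zeros(n)
                e[i] = h
                fp[i] = self._total_nll(x_hat + e)
                fm[i] = self._total_nll(x_hat - e)
                H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
            for i in range(n):
                for j in range(i + 1, n):
                    ei = np.zeros(n); ei[i] = h
                    ej = np.zeros(n); ej[j] = h
                    fpp = self._total_nll(x_hat + ei + ej)
                    fmm = self._total_nll(x_hat - ei - ej)
                    H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0
                                         - fm[i] - fm[j] + fmm) / (2 * h**2)
            return H

        H = fd_hessian(0.05)
        if not np.all(np.linalg.eigvalsh(H) > 0):
            H = fd_hessian(0.15)
        evals, evecs = np.linalg.eigh(H)
        evals = np.clip(evals, 1e-6, None)  # guard against a sloppy optimum
        cov = (evecs / evals) @ evecs.T
        se = np.sqrt(np.diag(cov))
        self.cov_transformed_ = cov
        self.se_transformed_ = {name: float(se[i]) for name, i in self._psi_index.items()}
        self.se_sigma_log_ = float(se[-1]) if self.estimate_sigma else 0.0

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.estimate:
            rows.append({"parameter": name, "estimate": self.theta_[name],
                         "estimate_transformed": self.theta_transformed_[name],
                         "se_transformed": self.se_transformed_[name]})
        if self.estimate_sigma:
            rows.append({"parameter": "sigma_res", "estimate": self.sigma_res_,
                         "estimate_transformed": math.log(self.sigma_res_),
                         "se_transformed": self.se_sigma_log_})
        return pd.DataFrame(rows)

    def get_params(self, deep: bool = True) -> dict:
        return {"estimate": self.estimate, "estimate_sigma": self.estimate_sigma,
                "random_effects": self.random_effects, "rtol": self.rtol,
                "atol": self.atol, "maxiter": self.maxiter,
                "inner_maxiter": self.inner_maxiter, "cit_switch": self.cit_switch,
                "sigma_min": self.sigma_min,
                "raise_on_failure": self.raise_on_failure}

    def set_params(self, **params) -> "PopulationFitter":
        for key, value in params.items():
            if not hasattr(self, key):
                raise InvalidInputError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self


def fit_population(data: pd.DataFrame, pop0: PopulationModel | None = None,
                   estimate: Sequence[str] = ("F", "k_gut2blo", "K_bon"),
                   **kwargs) -> PopulationFitter:
    """Convenience wrapper around :class:`PopulationFitter`."""
    return PopulationFitter(estimate=estimate, **kwargs).fit(data, pop0)
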