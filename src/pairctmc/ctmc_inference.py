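"""Exact-transition-time CTMC likelihood, estimation and inference.

With exactly observed transition times, the log-likelihood of a trajectory
decomposes over sojourns: each sojourn of length ``t`` in state ``s``
contributes ``-(sum of exit rates of s) * t``, and each observed transition
adds the log of its edge's rate.  The final, right-censored sojourn of a
session contributes exposure only.  Under a tying scheme that maps edges to
shared rate classes, the sufficient statistics are the per-class event
counts and exposures, so without covariates the MLE has the closed form
``rate = events / exposure`` per class.

Pair-level covariates (the two temperament scores) act log-linearly: for
pair ``p`` and class ``c`` the rate is
``exp(theta_c + sum_v gamma_{v,c} * (x_{v,p} - centre_v))``.
Because each coefficient belongs to a single class, the likelihood is a
sum of independent Poisson-regression-like terms and is maximised
numerically on the log scale.

Model comparison uses likelihood-ratio tests for nested tying/covariate
structures and AIC otherwise; uncertainty is quantified by a nonparametric
bootstrap that resamples pairs (the independent sampling units) with
replacement.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .event_encoding import SessionLog, Trajectory, encode_individual, encode_pair, \
    project_one_step
from .state_space import (
    BOLD,
    SHY,
    TransitionClassScheme,
    enumerate_pair_states,
    individual_scheme,
    one_step_memory_space,
    tying_scheme,
)

__all__ = [
    "CovariateSpec",
    "FitResult",
    "LRTResult",
    "BootstrapResult",
    "InvalidParameterError",
    "SchemeMismatchError",
    "DegenerateDesignError",
    "NotNestedError",
    "MismatchedDataError",
    "exact_loglik",
    "mle_closed_form",
    "mle_fit",
    "lrt",
    "aic_compare",
    "delta_aic_from_lrt",
    "bootstrap",
    "fit_session_logs",
    "scheme_from_names",
    "fit_result_from_dict",
    "SECONDS_PER_MINUTE",
]

SECONDS_PER_MINUTE = 60.0

MODEL_NAMES = ("full", "initiator_only", "memory_free", "one_step_memory", "two_state")


class InvalidParameterError(ValueError):
    """A non-positive rate on a transition class with observed events."""


class SchemeMismatchError(ValueError):
    """A trajectory edge with no class under the given tying scheme."""


class DegenerateDesignError(ValueError):
    """A covariate with no between-pair contrast (constant across units)."""


class NotNestedError(ValueError):
    """Likelihood-ratio test requested for non-nested models."""


class MismatchedDataError(ValueError):
    """Fits being compared were computed on different data."""


@dataclass(frozen=True)
class CovariateSpec:
    """Log-linear pair-level covariates entering transition intensities.

    ``affected_classes`` maps each covariate name to the set of class
    labels it enters (None = all classes).  ``own_effects_only`` restricts
    each temperament score to the classes whose mover is the corresponding
    fish (``x_bold`` -> bold-mover classes, ``x_shy`` -> shy-mover classes).
    ``centering`` holds per-covariate offsets; if None they are set to the
    across-pair mean at fit time.
    """

    covariates: tuple[str, ...] = ("x_bold", "x_shy")
    centering: Optional[Mapping[str, float]] = None
    affected_classes: Optional[Mapping[str, frozenset]] = None
    own_effects_only: bool = False

    def classes_for(self, cov: str, scheme: TransitionClassScheme) -> tuple[str, ...]:
        if self.affected_classes is not None and cov in self.affected_classes:
            allowed = self.affected_classes[cov]
            out = tuple(c for c in scheme.classes if c in allowed)
        else:
            out = scheme.classes
        if self.own_effects_only:
            mover = {"x_bold": BOLD, "x_shy": SHY}.get(cov)
            if mover is not None:
                out = tuple(c for c in out if scheme.mover_of(c) == mover)
        return out


@dataclass
class LRTResult:
    stat: float
    df: int
    pvalue: float


@dataclass
class FitResult:
    """A fitted CTMC model under a tying scheme.

    Rates are per ``time_unit`` trajectory time units (with second-based
    logs and ``time_unit = 60`` they are per-minute intensities).
    """

    scheme: TransitionClassScheme
    classes: tuple[str, ...]
    rates: dict[str, float]
    baseline_log_rates: dict[str, float]
    coefficients: dict[tuple[str, str], float]  # (covariate, class) -> value
    centering: dict[str, float]
    loglik: float
    k: int
    aic: float
    converged: bool
    grad_norm: Optional[float]
    n_events: dict[str, int]
    exposure: dict[str, float]
    non_estimable: tuple[str, ...]
    n_units: int
    time_unit: float
    fingerprint: str

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme.name,
            "space": self.scheme.space_name,
            "classes": list(self.classes),
            "rates_per_unit_time": self.rates,
            "coefficients": [
                {"covariate": cov, "class": cls, "value": v}
                for (cov, cls), v in self.coefficients.items()
            ],
            "centering": self.centering,
            "loglik": self.loglik,
            "k": self.k,
            "aic": self.aic,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "n_events": self.n_events,
            "exposure": self.exposure,
            "non_estimable": list(self.non_estimable),
            "n_units": self.n_units,
            "time_unit": self.time_unit,
            "fingerprint": self.fingerprint,
        }


def scheme_from_names(name: str, space_name: str) -> TransitionClassScheme:
    """Rebuild a tying scheme from its (scheme, space) names."""
    if space_name == "pair":
        return tying_scheme(enumerate_pair_states(), name)
    if space_name == "one_step":
        return tying_scheme(one_step_memory_space(), name)
    if space_name == "individual":
        return individual_scheme()
    raise ValueError(f"unknown space {space_name!r}")


def fit_result_from_dict(d: Mapping) -> FitResult:
    """Inverse of :meth:`FitResult.to_dict` (scheme rebuilt from its names)."""
    return FitResult(
        scheme=scheme_from_names(d["scheme"], d["space"]),
        classes=tuple(d["classes"]),
        rates={k: float(v) for k, v in d["rates_per_unit_time"].items()},
        baseline_log_rates={k: (float(np.log(v)) if v and v > 0 else -np.inf)
                            for k, v in d["rates_per_unit_time"].items()},
        coefficients={(e["covariate"], e["class"]): float(e["value"])
                      for e in d["coefficients"]},
        centering=dict(d["centering"] or {}),
        loglik=float(d["loglik"]),
        k=int(d["k"]),
        aic=float(d["aic"]),
        converged=bool(d["converged"]),
        grad_norm=d["grad_norm"],
        n_events={k: int(v) for k, v in d["n_events"].items()},
        exposure={k: float(v) for k, v in d["exposure"].items()},
        non_estimable=tuple(d["non_estimable"]),
        n_units=int(d["n_units"]),
        time_unit=float(d["time_unit"]),
        fingerprint=d["fingerprint"],
    )


# ---------------------------------------------------------------------------
# Sufficient statistics
# ---------------------------------------------------------------------------

@dataclass
class _Stats:
    classes: tuple[str, ...]
    units: tuple[str, ...]
    counts: np.ndarray     # (n_units, n_classes)
    exposure: np.ndarray   # (n_units, n_classes), in rate time units
    fingerprint: str


def _group_trajectories(trajs) -> dict[str, list[Trajectory]]:
    if isinstance(trajs, Mapping):
        return {str(k): list(v) for k, v in trajs.items()}
    groups: dict[str, list[Trajectory]] = {}
    for tr in trajs:
        key = str(tr.pair_id) if tr.pair_id is not None else "_all"
        groups.setdefault(key, []).append(tr)
    return groups


def _fingerprint(groups: dict[str, list[Trajectory]]) -> str:
    """Hash of the observation times, shared by all encodings of one log set."""
    h = hashlib.sha256()
    for unit in sorted(groups):
        for tr in sorted(groups[unit], key=lambda t: (str(t.session_id), t.end_time)):
            times = np.round(np.array([t for _, t in tr.visits] + [tr.end_time]), 9)
            h.update(repr((unit, str(tr.session_id))).encode())
            h.update(times.tobytes())
    return h.hexdigest()[:16]


def _sufficient_stats(trajs, scheme: TransitionClassScheme,
                      time_unit: float = 1.0) -> _Stats:
    groups = _group_trajectories(trajs)
    if not groups or all(not v for v in groups.values()):
        raise ValueError("empty trajectory set")
    classes = scheme.classes
    cidx = {c: i for i, c in enumerate(classes)}
    n_classes = len(classes)
    K = max(s for s, _ in scheme.assignment) + 1
    # incidence of source states on the classes of their outgoing edges, and
    # a dense lookup of edge -> class index (-1: not an edge of the scheme)
    M = np.zeros((K + 1, n_classes))
    edge_cls = np.full((K + 1) * (K + 1), -1, dtype=np.int64)
    has_out = np.zeros(K + 1, dtype=bool)
    for (s, t), label in scheme.assignment.items():
        M[s, cidx[label]] = 1.0
        edge_cls[s * (K + 1) + t] = cidx[label]
        has_out[s] = True
    units = tuple(sorted(groups))
    counts = np.zeros((len(units), n_classes))
    exposure = np.zeros((len(units), n_classes))
    for ui, unit in enumerate(units):
        for tr in groups[unit]:
            # state 0 stands in for the unknown-status prefix (no exposure)
            states = np.array([0 if s is None else s for s, _ in tr.visits],
                              dtype=np.int64)
            times = np.array([t for _, t in tr.visits] + [tr.end_time])
            dts = np.diff(times)
            known = states > 0
            if states.max() > K:
                raise SchemeMismatchError(
                    f"state {int(states.max())} is not part of scheme "
                    f"'{scheme.name}' on space '{scheme.space_name}'")
            if np.any(known & ~has_out[states]):
                bad = states[known & ~has_out[states]][0]
                raise SchemeMismatchError(
                    f"state {bad} has no outgoing edges under scheme "
                    f"'{scheme.name}' on space '{scheme.space_name}'")
            state_dt = np.bincount(states, weights=dts, minlength=K + 1)
            exposure[ui] += state_dt @ M / time_unit
            src, dst = states[:-1], states[1:]
            obs = src > 0
            ci = edge_cls[src[obs] * (K + 1) + dst[obs]]
            if np.any(ci < 0):
                s_bad = src[obs][ci < 0][0]
                t_bad = dst[obs][ci < 0][0]
                raise SchemeMismatchError(
                    f"edge {s_bad}->{t_bad} has no class under scheme "
                    f"'{scheme.name}'")
            counts[ui] += np.bincount(ci, minlength=n_classes)
    return _Stats(classes, units, counts, exposure, _fingerprint(groups))


def _covariate_matrix(stats: _Stats, cov_spec: CovariateSpec, cov_values):
    """Centered covariate matrix Z (units x covariates) and the centres used."""
    if isinstance(cov_values, pd.DataFrame):
        tbl = cov_values.set_index(cov_values["pair_id"].astype(str))
        values = {u: {c: float(tbl.loc[u, c]) for c in cov_spec.covariates}
                  for u in stats.units}
    else:
        values = {str(u): {c: float(v[c]) for c in cov_spec.covariates}
                  for u, v in cov_values.items()}
    missing = [u for u in stats.units if u not in values]
    if missing:
        raise ValueError(f"missing covariate values for pairs: {missing}")
    Z = np.array([[values[u][c] for c in cov_spec.covariates] for u in stats.units])
    if cov_spec.centering is not None:
        centres = np.array([cov_spec.centering[c] for c in cov_spec.covariates])
    else:
        centres = Z.mean(axis=0)
    if not np.all(np.isfinite(centres)):
        raise ValueError("non-finite covariate centering offsets")
    return Z - centres, dict(zip(cov_spec.covariates, centres.tolist()))


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _loglik_from_stats(stats: _Stats, rate_vec: np.ndarray,
                       eta: Optional[np.ndarray] = None) -> float:
    """Exact-times log-likelihood from sufficient statistics.

    ``eta`` is the (units x classes) matrix of log-linear covariate terms
    (zero if None); rates are the per-class baselines.
    """
    N, T = stats.counts, stats.exposure
    bad = (rate_vec <= 0) & (N.sum(axis=0) > 0)
    if np.any(bad):
        labels = [stats.classes[i] for i in np.where(bad)[0]]
        raise InvalidParameterError(
            f"non-positive rate on classes with observed events: {labels}")
    mult = np.ones_like(N) if eta is None else np.exp(eta)
    lam = rate_vec[None, :] * mult
    with np.errstate(divide="ignore"):
        log_lam = np.where(N > 0, np.log(np.where(lam > 0, lam, 1.0)), 0.0)
    return float((N * log_lam).sum() - (T * lam).sum())


def exact_loglik(trajs, scheme: TransitionClassScheme,
                 rates: Mapping[str, float],
                 coefficients: Optional[Mapping[tuple[str, str], float]] = None,
                 cov_spec: Optional[CovariateSpec] = None,
                 cov_values=None,
                 time_unit: float = 1.0) -> float:
    """Exact-transition-time log-likelihood of trajectories under a scheme.

    Parameters
    ----------
    trajs:
        Iterable of trajectories, or mapping pair_id -> trajectories.
    rates:
        Baseline intensity per class, in events per ``time_unit`` trajectory
        time units.
    coefficients, cov_spec, cov_values:
        Optional log-linear pair-level covariate structure; the rate for a
        pair is ``baseline * exp(sum coef * centred covariate)``.
    """
    stats_ = _sufficient_stats(trajs, scheme, time_unit)
    rate_vec = np.array([float(rates[c]) for c in stats_.classes])
    eta = None
    if coefficients:
        if cov_spec is None or cov_values is None:
            raise ValueError("coefficients given without cov_spec/cov_values")
        Z, _ = _covariate_matrix(stats_, cov_spec, cov_values)
        eta = np.zeros_like(stats_.counts)
        cidx = {c: i for i, c in enumerate(stats_.classes)}
        vidx = {c: i for i, c in enumerate(cov_spec.covariates)}
        for (cov, cls), val in coefficients.items():
            eta[:, cidx[cls]] += Z[:, vidx[cov]] * val
    return _loglik_from_stats(stats_, rate_vec, eta)


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def _result_from_stats(stats: _Stats, scheme, rate_vec, coefficients, centering,
                       loglik, k, converged, grad_norm, time_unit) -> FitResult:
    n_tot = stats.counts.sum(axis=0)
    t_tot = stats.exposure.sum(axis=0)
    non_est = tuple(c for c, t in zip(stats.classes, t_tot) if t <= 0)
    with np.errstate(divide="ignore"):
        logr = {c: (float(np.log(r)) if r > 0 else -np.inf)
                for c, r in zip(stats.classes, rate_vec)}
    return FitResult(
        scheme=scheme,
        classes=stats.classes,
        rates={c: float(r) for c, r in zip(stats.classes, rate_vec)},
        baseline_log_rates=logr,
        coefficients=dict(coefficients or {}),
        centering=dict(centering or {}),
        loglik=float(loglik),
        k=int(k),
        aic=float(2 * k - 2 * loglik),
        converged=bool(converged),
        grad_norm=grad_norm,
        n_events={c: int(n) for c, n in zip(stats.classes, n_tot)},
        exposure={c: float(t) for c, t in zip(stats.classes, t_tot)},
        non_estimable=non_est,
        n_units=len(stats.units),
        time_unit=time_unit,
        fingerprint=stats.fingerprint,
    )


def mle_closed_form(trajs, scheme: TransitionClassScheme,
                    time_unit: float = 1.0) -> FitResult:
    """Closed-form exact-times MLE: per class, rate = events / exposure.

    Classes with zero exposure are non-estimable (rate NaN, flagged);
    classes with exposure but no events have MLE zero.  The free-parameter
    count ``k`` is the number of estimable classes.
    """
    stats_ = _sufficient_stats(trajs, scheme, time_unit)
    n = stats_.counts.sum(axis=0)
    t = stats_.exposure.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_vec = np.where(t > 0, n / np.where(t > 0, t, 1.0), np.nan)
    if np.any(t <= 0):
        warnings.warn("classes with zero exposure are non-estimable", stacklevel=2)
    ll = _loglik_from_stats(stats_, np.where(np.isnan(rate_vec), 0.0, rate_vec))
    k = int((t > 0).sum())
    return _result_from_stats(stats_, scheme, rate_vec, None, None,
                              ll, k, True, None, time_unit)


def mle_fit(trajs, scheme: TransitionClassScheme,
            cov_spec: Optional[CovariateSpec] = None,
            cov_values=None,
            time_unit: float = 1.0,
            n_starts: int = 1,
            start_seed: int = 0,
            gtol: float = 1e-8,
            start: Optional[np.ndarray] = None) -> FitResult:
    """Maximum-likelihood fit by numerical optimisation on the log scale.

    Baseline rates are parameterised as log-rates (positive by
    construction); optional log-linear covariate coefficients are estimated
    jointly.  Classes with zero events are held at rate zero and excluded
    from the optimisation; a covariate constant across pairs raises
    :class:`DegenerateDesignError`.
    """
    stats_ = _sufficient_stats(trajs, scheme, time_unit)
    n = stats_.counts.sum(axis=0)
    t = stats_.exposure.sum(axis=0)
    if np.any(t <= 0):
        warnings.warn("classes with zero exposure are non-estimable and excluded",
                      stacklevel=2)
    active = np.where((n > 0) & (t > 0))[0]  # classes optimised on log scale
    m = len(active)
    Na = stats_.counts[:, active]
    Ta = stats_.exposure[:, active]

    coef_keys: list[tuple[str, str]] = []
    Z = None
    centering: dict[str, float] = {}
    if cov_spec is not None:
        if cov_values is None:
            raise ValueError("cov_spec given without cov_values")
        Z, centering = _covariate_matrix(stats_, cov_spec, cov_values)
        if len(stats_.units) < 2 or np.any(Z.std(axis=0) == 0):
            degenerate = ([] if len(stats_.units) < 2 else
                          [c for c, sd in zip(cov_spec.covariates, Z.std(axis=0))
                           if sd == 0])
            raise DegenerateDesignError(
                "no between-pair contrast in covariates "
                f"{degenerate or list(cov_spec.covariates)}")
        active_labels = {stats_.classes[i] for i in active}
        for cov in cov_spec.covariates:
            for cls in cov_spec.classes_for(cov, scheme):
                if cls in active_labels:
                    coef_keys.append((cov, cls))
    ncoef = len(coef_keys)
    apos = {stats_.classes[i]: j for j, i in enumerate(active)}
    vidx = {c: i for i, c in enumerate(cov_spec.covariates)} if cov_spec else {}

    # design for eta: eta[:, j] = sum over coef on class j of gamma * Z[:, cov]
    coef_cols = np.array([apos[cls] for _, cls in coef_keys], dtype=int)
    coef_covs = np.array([vidx[cov] for cov, _ in coef_keys], dtype=int)

    def eta_of(gamma: np.ndarray) -> np.ndarray:
        eta = np.zeros((len(stats_.units), m))
        for g, col, cv in zip(gamma, coef_cols, coef_covs):
            eta[:, col] += g * Z[:, cv]
        return eta

    def negloglik(params: np.ndarray):
        theta, gamma = params[:m], params[m:]
        eta = eta_of(gamma) if ncoef else 0.0
        lam = np.exp(theta[None, :] + eta)
        resid = Ta * lam - Na
        nll = float((Ta * lam).sum() - (Na * (theta[None, :] + eta)).sum())
        grad_theta = resid.sum(axis=0)
        grad = np.concatenate([
            grad_theta,
            np.array([(resid[:, col] * Z[:, cv]).sum()
                      for col, cv in zip(coef_cols, coef_covs)])
            if ncoef else np.empty(0),
        ])
        return nll, grad

    with np.errstate(divide="ignore"):
        theta0 = np.log(np.where(Na.sum(axis=0) > 0,
                                 Na.sum(axis=0) / Ta.sum(axis=0), 1.0))
    x0 = np.concatenate([theta0, np.zeros(ncoef)]) if start is None else start

    rng = np.random.default_rng(start_seed)
    best = None
    for s in range(max(1, n_starts)):
        xs = x0 if s == 0 else x0 + rng.normal(0, 0.5, size=x0.size)
        res = optimize.minimize(negloglik, xs, jac=True, method="L-BFGS-B",
                                options={"gtol": gtol, "ftol": 1e-13,
                                         "maxiter": 10_000, "maxcor": 30})
        if best is None or res.fun < best.fun:
            best = res
    grad_norm = float(np.max(np.abs(best.jac)))
    # the gradient is in event-count units, so judge it relative to the
    # total number of events
    gscale = max(1.0, float(stats_.counts.sum()))
    converged = np.isfinite(best.fun) and (bool(best.success)
                                           or grad_norm <= gtol * gscale)
    if not converged:
        warnings.warn(f"optimizer did not converge: {best.message}", stacklevel=2)

    rate_vec = np.zeros(len(stats_.classes))
    rate_vec[active] = np.exp(best.x[:m])
    rate_vec[t <= 0] = np.nan
    coefficients = dict(zip(coef_keys, best.x[m:].tolist()))
    k = int((t > 0).sum()) + ncoef
    return _result_from_stats(stats_, scheme, rate_vec, coefficients, centering,
                              -best.fun, k, converged, grad_norm, time_unit)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

def _is_nested(fit_full: FitResult, fit_nested: FitResult) -> bool:
    sf, sn = fit_full.scheme, fit_nested.scheme
    full_keys = set(fit_full.coefficients)
    nested_keys = set(fit_nested.coefficients)
    if sf.name == sn.name and sf.space_name == sn.space_name \
            and sf.assignment == sn.assignment:
        return nested_keys <= full_keys
    if not sf.is_refinement_of(sn):
        return False
    # across different schemes, nesting of the covariate structure is only
    # guaranteed when the nested fit carries no covariates
    return not nested_keys


def lrt(fit_full: FitResult, fit_nested: FitResult) -> LRTResult:
    """Likelihood-ratio test of a nested model against a richer one.

    ``stat = 2 (loglik_full - loglik_nested)``, ``df = k_full - k_nested``,
    with the p-value from the chi-squared distribution.
    """
    if fit_full.fingerprint != fit_nested.fingerprint:
        raise MismatchedDataError("fits were computed on different data")
    if not _is_nested(fit_full, fit_nested):
        raise NotNestedError(
            f"'{fit_nested.scheme.name}' is not nested in "
            f"'{fit_full.scheme.name}'; compare by AIC instead")
    stat = 2.0 * (fit_full.loglik - fit_nested.loglik)
    if stat < 0:
        if stat < -1e-6 * max(1.0, abs(fit_full.loglik)):
            warnings.warn(
                f"negative LRT statistic ({stat:.3g}) suggests non-convergence",
                stacklevel=2)
        stat = 0.0
    df = fit_full.k - fit_nested.k
    if df <= 0:
        raise NotNestedError("full model has no extra free parameters")
    return LRTResult(stat=stat, df=df, pvalue=float(stats.chi2.sf(stat, df)))


def aic_compare(fit_a: FitResult, fit_b: FitResult) -> float:
    """``AIC_b - AIC_a`` (positive favours model a); data must match."""
    if fit_a.fingerprint != fit_b.fingerprint:
        raise MismatchedDataError("fits were computed on different data")
    return float(fit_b.aic - fit_a.aic)


def delta_aic_from_lrt(stat: float, df: int) -> float:
    """AIC difference implied by an LRT statistic with ``df`` extra parameters."""
    return float(stat - 2 * df)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Percentile bootstrap intervals over pair-resampled replicates."""

    point: dict[str, float]
    replicates: pd.DataFrame
    ci: dict[str, tuple[float, float]]
    level: float
    n_failures: int
    seed: int

    @property
    def B(self) -> int:
        return len(self.replicates)

    def pvalue(self, name: str, null: float = 1.0) -> float:
        """Two-sided bootstrap p-value against ``null`` (floored at 2/B).

        For a ratio of intensities the natural null is 1.
        """
        r = self.replicates[name].to_numpy()
        r = r[np.isfinite(r)]
        if len(r) == 0:
            return float("nan")
        p = 2.0 * min((r <= null).mean(), (r >= null).mean())
        return float(min(1.0, max(p, 2.0 / self.B)))


def bootstrap(logs: Sequence[SessionLog],
              estimator: Callable,
              B: int = 1000,
              seed: int = 0,
              level: float = 0.95,
              covariates: Optional[pd.DataFrame] = None,
              max_failures: int = 100) -> BootstrapResult:
    """Nonparametric bootstrap resampling pairs (with their sessions).

    ``estimator`` maps a list of session logs (and, if supplied, a matching
    covariate table) to a dict of named scalar quantities; it is applied to
    the original data for the point estimates and to ``B`` resampled
    datasets for percentile confidence intervals.  Resampled pairs are
    relabelled so repeated draws stay distinct sampling units.  A replicate
    on which the estimator fails is recorded and redrawn, up to
    ``max_failures`` times in total.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    by_pair: dict[str, list[SessionLog]] = {}
    for log in logs:
        by_pair.setdefault(str(log.pair_id), []).append(log)
    pair_ids = sorted(by_pair)
    n_pairs = len(pair_ids)
    cov_by_pair = None
    if covariates is not None:
        cov_by_pair = {str(r["pair_id"]): r for _, r in covariates.iterrows()}

    def call(sample_logs, sample_cov):
        if covariates is not None:
            return estimator(sample_logs, sample_cov)
        return estimator(sample_logs)

    point = call(logs if covariates is None else list(logs),
                 covariates)
    point = {k: float(v) for k, v in point.items()}

    rng = np.random.default_rng(seed)
    rows = []
    failures = 0
    while len(rows) < B:
        idx = rng.integers(0, n_pairs, size=n_pairs)
        sample_logs: list[SessionLog] = []
        cov_rows = []
        for j, i in enumerate(idx):
            pid = pair_ids[i]
            new_id = f"bs{j}"
            for log in by_pair[pid]:
                sample_logs.append(SessionLog(new_id, log.session_id,
                                              log.partition, log.duration_s,
                                              log.events))
            if cov_by_pair is not None:
                row = cov_by_pair[pid]
                cov_rows.append({"pair_id": new_id,
                                 "x_bold": row["x_bold"], "x_shy": row["x_shy"]})
        sample_cov = pd.DataFrame(cov_rows) if cov_by_pair is not None else None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = call(sample_logs, sample_cov)
        except Exception:
            failures += 1
            if failures > max_failures:
                raise RuntimeError(
                    f"estimator failed on more than {max_failures} bootstrap "
                    "replicates")
            continue
        rows.append({k: float(v) for k, v in est.items()})

    reps = pd.DataFrame(rows)
    alpha = (1.0 - level) / 2.0
    ci = {}
    for name in point:
        vals = reps[name].to_numpy()
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            ci[name] = (float("nan"), float("nan"))
        else:
            ci[name] = (float(np.quantile(vals, alpha)),
                        float(np.quantile(vals, 1.0 - alpha)))
    return BootstrapResult(point, reps, ci, level, failures, seed)


# ---------------------------------------------------------------------------
# High-level fitting from session logs
# ---------------------------------------------------------------------------

def _build_scheme(model: str):
    if model in ("full", "initiator_only", "memory_free"):
        return tying_scheme(enumerate_pair_states(), model)
    if model == "one_step_memory":
        return tying_scheme(one_step_memory_space(), "full")
    if model == "two_state":
        return individual_scheme()
    raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")


def fit_session_logs(logs: Sequence[SessionLog], model: str = "full",
                     covariates: Optional[pd.DataFrame] = None,
                     cov_spec: Optional[CovariateSpec] = None,
                     pool_sessions: bool = True,
                     time_unit: float = SECONDS_PER_MINUTE,
                     numerical: Optional[bool] = None,
                     **fit_kwargs) -> FitResult:
    """Encode logs for a named model variant and fit it.

    Models ``full``, ``initiator_only`` and ``memory_free`` are tying
    schemes over the 12-state pair space; ``one_step_memory`` is the free
    model over the 8-state reduced space; ``two_state`` pools all fish into
    the individual cover/exposed model.  With second-based logs and the
    default ``time_unit`` of 60, fitted intensities are per minute.

    ``pool_sessions`` keeps each pair's sessions together as one sampling
    unit (one likelihood term per pair); when False each session is its
    own unit.
    """
    scheme = _build_scheme(model)
    groups: dict[str, list[Trajectory]] = {}
    for log in logs:
        if model == "two_state":
            trs = [encode_individual(log, fish) for fish in (BOLD, SHY)]
        else:
            if log.partition != "transparent":
                continue
            tr = encode_pair(log)
            if model == "one_step_memory":
                tr = project_one_step(tr)
            trs = [tr]
        unit = str(log.pair_id) if pool_sessions else f"{log.pair_id}/{log.session_id}"
        groups.setdefault(unit, []).extend(trs)
    if not groups:
        raise ValueError("no usable sessions for model "
                         f"{model!r} (pair models need transparent partitions)")
    if covariates is not None or cov_spec is not None:
        spec = cov_spec or CovariateSpec()
        if covariates is None:
            raise ValueError("cov_spec given without a covariate table")
        return mle_fit(groups, scheme, cov_spec=spec, cov_values=covariates,
                       time_unit=time_unit, **fit_kwargs)
    if numerical:
        return mle_fit(groups, scheme, time_unit=time_unit, **fit_kwargs)
    return mle_closed_form(groups, scheme, time_unit=time_unit)
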