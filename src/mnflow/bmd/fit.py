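"""Maximum-likelihood covariate fitting of dose-response curves.

Lognormal error model: responses are log-transformed and fitted as normal
with curve-defined means. The covariate ladder starts from an all-shared
model and tests level-specific within-group variance, background (a) and
potency (b) -- in that order -- by likelihood-ratio test; log-steepness (d)
and maximum response (c) are always held shared across levels. Within-group
variances are profiled out analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from mnflow.bmd.data import DoseResponseDataset
from mnflow.bmd.models import BMDConfig, BMDModelParams, bmd_from_bcd, _check_family

_LOG_C_MIN_MARGIN = 1e-9
_VAR_FLOOR = 1e-12

#: ladder order of level-specific parameter candidates
LADDER_ORDER = ("var", "a", "b")


class FitError(RuntimeError):
    """Optimisation failed to converge after all restarts."""


@dataclass(frozen=True)
class _Problem:
    x: np.ndarray          # concentrations
    ylog: np.ndarray       # log responses
    lev: np.ndarray        # integer level index per record
    levels: tuple          # level labels, index-aligned
    family: str
    ces: float

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def _build_problem(data: DoseResponseDataset, family: str, ces: float) -> _Problem:
    tab = data.table
    y = tab["response"].to_numpy(float)
    if (y <= 0).any():
        raise ValueError(
            "responses must be > 0 for the lognormal error model; apply a "
            "pseudo-count upstream"
        )
    levels = tuple(sorted(tab["covariate_level"].unique().tolist()))
    lev_map = {l: i for i, l in enumerate(levels)}
    lev = tab["covariate_level"].map(lev_map).to_numpy(int)
    x = tab["concentration"].to_numpy(float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    return _Problem(x=x, ylog=np.log(y), lev=lev, levels=levels,
                    family=_check_family(family), ces=ces)


def _curve_logmu(x, a_vec, b_vec, c, d, family):
    """Log expected response per record (vectorised, overflow-safe)."""
    with np.errstate(over="ignore", invalid="ignore"):
        if family == "exponential":
            expo = np.clip((x / b_vec) ** d, 0.0, 700.0)
            mu_rel = c - (c - 1.0) * np.exp(-expo)
        else:
            pos = x > 0
            frac = np.zeros_like(x)
            # x^d / (b^d + x^d) computed in log space for stability
            lr = d * (np.log(np.where(pos, x, 1.0)) - np.log(b_vec))
            lr = np.clip(lr, -700.0, 700.0)
            r = np.exp(lr)
            frac[pos] = r[pos] / (1.0 + r[pos])
            mu_rel = 1.0 + (c - 1.0) * frac
    return np.log(a_vec) + np.log(mu_rel)


@dataclass(frozen=True)
class _ParamSpec:
    """Packing layout for the free parameter vector of one model structure."""

    n_levels: int
    a_specific: bool
    b_specific: bool
    var_specific: bool
    # profile mode: BMD fixed for one level (or for the shared b)
    fixed_bmd_level: Optional[int] = None  # None = not profiling
    fixed_bmd: Optional[float] = None

    @property
    def n_a(self) -> int:
        return self.n_levels if self.a_specific else 1

    @property
    def n_b_free(self) -> int:
        n_b = self.n_levels if self.b_specific else 1
        if self.fixed_bmd_level is not None:
            n_b -= 1  # that b is derived from the fixed BMD and (c, d)
        return n_b

    @property
    def size(self) -> int:
        return self.n_a + self.n_b_free + 2  # + log(c-1), log d

    def n_free_params(self) -> int:
        """Total free parameters incl. profiled variances (for LRT df)."""
        n_var = self.n_levels if self.var_specific else 1
        return self.size + n_var

    def unpack(self, theta, lev, ces, family):
        """Return (a_vec, b_vec, c, d) per-record vectors/scalars."""
        n_a, n_bf = self.n_a, self.n_b_free
        log_a = theta[:n_a]
        log_b_free = theta[n_a:n_a + n_bf]
        c = 1.0 + math.exp(theta[-2])
        d = math.exp(theta[-1])
        a_lev = np.exp(log_a if self.a_specific else np.repeat(log_a, 1))
        a_vec = a_lev[lev] if self.a_specific else np.full(lev.shape, float(np.exp(log_a[0])))

        if self.fixed_bmd_level is None:
            b_lev = np.exp(log_b_free)
            b_vec = b_lev[lev] if self.b_specific else np.full(lev.shape, float(b_lev[0]))
        else:
            # derive the profiled b from the fixed BMD: BMD = b * h(c, d)
            h = bmd_from_bcd(1.0, c, d, ces, family)
            b_fixed = self.fixed_bmd / h
            if self.b_specific:
                b_lev = np.empty(self.n_levels)
                free = [i for i in range(self.n_levels) if i != self.fixed_bmd_level]
                b_lev[free] = np.exp(log_b_free)
                b_lev[self.fixed_bmd_level] = b_fixed
                b_vec = b_lev[lev]
            else:
                b_vec = np.full(lev.shape, b_fixed)
        return a_vec, b_vec, c, d


def _profiled_nll(resid, lev, n_levels, var_specific):
    """NLL with within-group variance(s) profiled out analytically."""
    if var_specific:
        nll = 0.0
        for l in range(n_levels):
            r = resid[lev == l]
            s2 = max(float(np.mean(r * r)), _VAR_FLOOR)
            nll += 0.5 * r.size * (math.log(2 * math.pi * s2) + 1.0)
        return nll
    s2 = max(float(np.mean(resid * resid)), _VAR_FLOOR)
    return 0.5 * resid.size * (math.log(2 * math.pi * s2) + 1.0)


def _sigma2_hat(resid, lev, n_levels, var_specific):
    if var_specific:
        return [max(float(np.mean(resid[lev == l] ** 2)), _VAR_FLOOR)
                for l in range(n_levels)]
    return [max(float(np.mean(resid**2)), _VAR_FLOOR)] * n_levels


def _make_objective(prob: _Problem, spec: _ParamSpec):
    x, ylog, lev = prob.x, prob.ylog, prob.lev

    def nll(theta):
        try:
            a_vec, b_vec, c, d = spec.unpack(theta, lev, prob.ces, prob.family)
        except (ValueError, OverflowError):
            return 1e12
        logmu = _curve_logmu(x, a_vec, b_vec, c, d, prob.family)
        if not np.all(np.isfinite(logmu)):
            return 1e12
        resid = ylog - logmu
        return _profiled_nll(resid, lev, prob.n_levels, spec.var_specific)

    return nll


def _start_points(prob: _Problem, spec: _ParamSpec, ces: float) -> list[np.ndarray]:
    """Deterministic data-driven multi-start values."""
    x, ylog, lev = prob.x, prob.ylog, prob.lev
    ctrl = x == 0
    log_a0 = float(np.mean(ylog[ctrl])) if ctrl.any() else float(ylog.min())
    log_ymax = float(np.max(ylog))
    c0 = max(math.exp(log_ymax - log_a0), 1.0 + 1.5 * ces)
    pos = np.unique(x[x > 0])
    b0 = float(np.median(pos)) if pos.size else 1.0

    starts = []
    for b_mult, d0 in ((1.0, 1.0), (1.0, 2.0), (0.4, 1.0), (2.5, 3.0), (1.0, 0.6)):
        log_a = np.full(spec.n_a, log_a0)
        log_b = np.full(spec.n_b_free, math.log(max(b0 * b_mult, 1e-12)))
        theta = np.concatenate(
            [log_a, log_b, [math.log(max(c0 - 1.0, 1.05 * ces))], [math.log(d0)]]
        )
        starts.append(theta)
    return starts


def _bounds(prob: _Problem, spec: _ParamSpec) -> list[tuple[float, float]]:
    ylo, yhi = float(prob.ylog.min()), float(prob.ylog.max())
    pos = prob.x[prob.x > 0]
    lxlo = math.log(pos.min()) if pos.size else 0.0
    lxhi = math.log(pos.max()) if pos.size else 0.0
    b = []
    b += [(ylo - 5.0, yhi + 5.0)] * spec.n_a
    b += [(lxlo - 9.0, lxhi + 9.0)] * spec.n_b_free
    b += [(math.log(prob.ces) + _LOG_C_MIN_MARGIN, 8.0)]   # log(c-1): keep BMD defined
    b += [(math.log(0.1), math.log(10.0))]                 # log d
    return b


def _minimize(prob: _Problem, spec: _ParamSpec, starts: Sequence[np.ndarray] | None = None):
    """Multi-start bounded quasi-Newton minimisation. Returns (nll, theta)."""
    nll = _make_objective(prob, spec)
    bounds = _bounds(prob, spec)
    if starts is None:
        starts = _start_points(prob, spec, prob.ces)
    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, [lo for lo, _ in bounds], [hi for _, hi in bounds])
        res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise FitError("dose-response fit failed to converge from all starts")
    return float(best.fun), np.asarray(best.x)


@dataclass
class LevelResult:
    """Fitted curve and benchmark dose for one covariate level."""

    level: object
    params: BMDModelParams
    bmd: Optional[float]
    bmdl: Optional[float] = None
    bmdu: Optional[float] = None
    bmdl_unbounded: bool = False
    bmdu_unbounded: bool = False


@dataclass
class LadderStep:
    parameter: str
    loglik: float
    p_value: float
    accepted: bool


@dataclass
class BMDResult:
    """Outcome of a covariate benchmark-dose fit for one model family."""

    family: str
    ces: float
    levels: dict = field(default_factory=dict)  # level -> LevelResult
    loglik: float = float("nan")
    level_specific: tuple[str, ...] = ()
    covariate_rejected_for_potency: bool = False
    ladder: list[LadderStep] = field(default_factory=list)
    # internals needed for profile CIs
    _problem: Optional[_Problem] = None
    _spec: Optional[_ParamSpec] = None
    _theta: Optional[np.ndarray] = None


def _result_from_fit(prob: _Problem, spec: _ParamSpec, theta: np.ndarray,
                     nll: float, ces: float) -> BMDResult:
    a_vec, b_vec, c, d = spec.unpack(theta, prob.lev, ces, prob.family)
    logmu = _curve_logmu(prob.x, a_vec, b_vec, c, d, prob.family)
    resid = prob.ylog - logmu
    sig2 = _sigma2_hat(resid, prob.lev, prob.n_levels, spec.var_specific)

    res = BMDResult(family=prob.family, ces=ces, loglik=-nll,
                    _problem=prob, _spec=spec, _theta=theta)
    for i, level in enumerate(prob.levels):
        idx = np.argmax(prob.lev == i)
        a_l = float(a_vec[idx])
        b_l = float(b_vec[idx])
        params = BMDModelParams(a=a_l, b=b_l, c=float(c), d=float(d), var=sig2[i])
        try:
            bmd = bmd_from_bcd(b_l, c, d, ces, prob.family)
        except ValueError:
            bmd = None
        res.levels[level] = LevelResult(level=level, params=params, bmd=bmd)
    return res


def fit_covariate_model(
    data: DoseResponseDataset,
    cfg: BMDConfig | None = None,
    family: str | None = None,
):
    """Fit the covariate dose-response model and run the acceptance ladder.

    With a single covariate level this reduces exactly to a plain fit.
    With ``cfg.model_family == "both"`` (and no explicit ``family``), both
    families are fitted and a dict ``{family: BMDResult}`` is returned.
    """
    cfg = cfg or BMDConfig()
    fam = family or cfg.model_family
    if fam == "both":
        return {
            f: fit_covariate_model(data, cfg, family=f) for f in ("exponential", "hill")
        }

    prob = _build_problem(data, fam, cfg.ces)
    L = prob.n_levels

    def make_spec(specific: set[str]) -> _ParamSpec:
        return _ParamSpec(
            n_levels=L,
            a_specific="a" in specific,
            b_specific="b" in specific,
            var_specific="var" in specific,
        )

    accepted: set[str] = set()
    spec = make_spec(accepted)
    nll, theta = _minimize(prob, spec)
    ladder: list[LadderStep] = []

    if L > 1:
        for name in LADDER_ORDER:
            cand = accepted | {name}
            cand_spec = make_spec(cand)
            # warm start: replicate the shared estimate across levels
            starts = _start_points(prob, cand_spec, cfg.ces)
            starts.append(_expand_theta(theta, spec, cand_spec))
            cand_nll, cand_theta = _minimize(prob, cand_spec, starts)
            lr = max(2.0 * (nll - cand_nll), 0.0)
            df = (L - 1)
            p = float(stats.chi2.sf(lr, df))
            accept = p < cfg.acceptance_alpha
            ladder.append(LadderStep(parameter=name, loglik=-cand_nll,
                                     p_value=p, accepted=accept))
            if accept:
                accepted = cand
                spec, nll, theta = cand_spec, cand_nll, cand_theta

    res = _result_from_fit(prob, spec, theta, nll, cfg.ces)
    res.level_specific = tuple(n for n in LADDER_ORDER if n in accepted)
    res.covariate_rejected_for_potency = (L > 1) and ("b" not in accepted)
    res.ladder = ladder
    return res


def _expand_theta(theta, old: _ParamSpec, new: _ParamSpec) -> np.ndarray:
    """Broadcast a simpler structure's estimate into a richer packing."""
    a_part = theta[:old.n_a]
    b_part = theta[old.n_a:old.n_a + old.n_b_free]
    tail = theta[-2:]
    a_new = np.repeat(a_part[0], new.n_a) if new.n_a > old.n_a else a_part
    b_new = np.repeat(b_part[0], new.n_b_free) if new.n_b_free > old.n_b_free else b_part
    return np.concatenate([a_new, b_new, tail])
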