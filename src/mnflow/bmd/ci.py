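"""Profile-likelihood confidence intervals for the benchmark dose."""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from mnflow.bmd.fit import (
    BMDResult,
    FitError,
    _minimize,
    _ParamSpec,
    _start_points,
)
from mnflow.bmd.models import BMDConfig

#: widest BMD bracket searched before declaring the profile unbounded
_MAX_FACTOR = 1e6


def _profile_nll(res: BMDResult, level_idx: int, bmd_value: float,
                 warm: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """NLL minimised over all parameters with one level's BMD held fixed."""
    prob, spec = res._problem, res._spec
    pspec = _ParamSpec(
        n_levels=spec.n_levels,
        a_specific=spec.a_specific,
        b_specific=spec.b_specific,
        var_specific=spec.var_specific,
        fixed_bmd_level=level_idx,
        fixed_bmd=bmd_value,
    )
    starts = _start_points(prob, pspec, prob.ces)
    if warm is not None:
        starts = [warm] + starts[:2]
    return (*_minimize(prob, pspec, starts),)


def _drop_b_entry(theta: np.ndarray, spec: _ParamSpec, level_idx: int) -> np.ndarray:
    """Warm start for the profile: remove the profiled b from the packing."""
    n_a = spec.n_a
    n_b = spec.n_levels if spec.b_specific else 1
    b_part = list(theta[n_a:n_a + n_b])
    if spec.b_specific:
        del b_part[level_idx]
    else:
        b_part = []
    return np.concatenate([theta[:n_a], b_part, theta[-2:]])


def bmd_confidence_interval(res: BMDResult, cfg: BMDConfig | None = None) -> BMDResult:
    """Attach two-sided profile-likelihood (BMDL, BMDU) to each level.

    The cutoff is the chi-square(1) quantile at ``cfg.ci_level`` (two-sided
    interval from the one-dimensional profile). A profile that stays under
    the cutoff out to a 1e6-fold range is flagged unbounded on that side.
    Levels sharing a single potency share one interval.
    """
    cfg = cfg or BMDConfig(model_family=res.family, ces=res.ces)
    if res._problem is None or res._theta is None:
        raise ValueError("BMDResult lacks fit internals; refit before computing CIs")
    cut = 0.5 * float(stats.chi2.ppf(cfg.ci_level, 1))
    nll_hat = -res.loglik
    spec = res._spec
    prob = res._problem

    shared_b = not spec.b_specific
    done_shared: tuple | None = None
    for i, level in enumerate(prob.levels):
        lres = res.levels[level]
        if lres.bmd is None:
            continue
        if shared_b and done_shared is not None:
            lres.bmdl, lres.bmdu, lres.bmdl_unbounded, lres.bmdu_unbounded = done_shared
            continue
        warm0 = _drop_b_entry(res._theta, spec, i)
        lo, lo_unb = _search_bound(res, i, lres.bmd, nll_hat, cut, warm0, down=True)
        hi, hi_unb = _search_bound(res, i, lres.bmd, nll_hat, cut, warm0, down=False)
        lres.bmdl, lres.bmdu = lo, hi
        lres.bmdl_unbounded, lres.bmdu_unbounded = lo_unb, hi_unb
        if shared_b:
            done_shared = (lo, hi, lo_unb, hi_unb)
    return res


def _search_bound(res, level_idx, bmd_hat, nll_hat, cut, warm0, down: bool):
    """Bracket then bisect the profile crossing on one side of the BMD."""

    def excess(t, warm):
        try:
            nll, theta = _profile_nll(res, level_idx, t, warm)
        except FitError:
            return None, warm
        return nll - nll_hat - cut, theta

    factor = 0.75 if down else 1.0 / 0.75
    t_in = bmd_hat
    f_in = -cut
    warm = warm0
    t_out = bmd_hat
    while True:
        t_out = t_out * factor
        ratio = t_out / bmd_hat if not down else bmd_hat / t_out
        if ratio > _MAX_FACTOR:
            return (t_out, True)
        f_out, warm = excess(t_out, warm)
        if f_out is None:
            # treat a failed profile point as outside the interval
            f_out = 1.0
        if f_out > 0:
            break
        t_in, f_in = t_out, f_out

    # bisect between t_in (inside) and t_out (outside)
    for _ in range(40):
        t_mid = math.sqrt(t_in * t_out)
        f_mid, warm = excess(t_mid, warm)
        if f_mid is None:
            f_mid = 1.0
        if f_mid > 0:
            t_out = t_mid
        else:
            t_in = t_mid
        if abs(math.log(t_out / t_in)) < 1e-3:
            break
    return (math.sqrt(t_in * t_out), False)
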