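"""Significance of micronucleus responses relative to vehicle control.

Decision framework: responses are log10-transformed; normality
(Shapiro-Wilk, on within-group-centred residuals pooled across groups) and
variance homogeneity (Bartlett) are pretested. If both pass (p > 0.05) the
concentrations are compared to control by a one-sided (increase) Dunnett
test; otherwise by the non-parametric one-sided Dunn many-to-one test with
Sidak family correction. Stars at p < 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

ALPHA_LEVELS = (0.05, 0.01, 0.001)

#: fixed seed for the randomised QMC integration inside Dunnett's test
_DUNNETT_QMC_SEED = 1852


@dataclass(frozen=True)
class ConcentrationDecision:
    concentration: float
    p_value: float
    significant_at: tuple[float, ...]  # subset of ALPHA_LEVELS

    @property
    def stars(self) -> str:
        return "*" * len(self.significant_at)


@dataclass(frozen=True)
class SignificanceResult:
    branch: str                 # "dunnett" | "dunn"
    normality_p: float
    variance_homogeneity_p: float
    decisions: tuple[ConcentrationDecision, ...]

    def any_significant(self, alpha: float = 0.05) -> bool:
        return any(d.p_value < alpha for d in self.decisions)


def _log10_with_pseudocount(values: np.ndarray, n_binucleates: int | None) -> np.ndarray:
    """log10 transform; zero frequencies replaced by the half-minimum
    pseudo-count 0.5/n_binucleates (or half the smallest positive value when
    the denominator is unknown)."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("frequencies must be >= 0")
    if (v == 0).any():
        if n_binucleates is not None:
            floor = 0.5 / n_binucleates
        else:
            pos = v[v > 0]
            if pos.size == 0:
                raise ValueError("all responses are zero; nothing to test")
            floor = pos.min() / 2.0
        v = np.where(v == 0, floor, v)
    return np.log10(v)


def significance_pipeline(
    groups: Mapping[float, Sequence[float]],
    alpha: float = 0.05,
    pretest_alpha: float = 0.05,
    n_binucleates: int | None = None,
) -> SignificanceResult:
    """Run the full decision framework on replicate frequencies by concentration.

    ``groups`` maps concentration -> replicate MN frequencies and must
    include the vehicle control at concentration 0. Each group needs at
    least 2 replicates.
    """
    concs = sorted(groups)
    if 0.0 not in groups:
        raise ValueError("groups must include the vehicle control at concentration 0")
    if len(concs) < 2:
        raise ValueError("need at least one treated concentration plus control")
    arrays = {}
    for c in concs:
        a = np.asarray(groups[c], dtype=float)
        if a.size < 2:
            raise ValueError(f"concentration {c}: need >= 2 replicates, got {a.size}")
        arrays[c] = a

    logs = {c: _log10_with_pseudocount(a, n_binucleates) for c, a in arrays.items()}
    control = logs[0.0]
    treated = [logs[c] for c in concs if c != 0.0]

    # degenerate: every replicate identical across all groups -> no effect
    all_vals = np.concatenate(list(logs.values()))
    if np.ptp(all_vals) == 0:
        decisions = tuple(
            ConcentrationDecision(concentration=c, p_value=1.0, significant_at=())
            for c in concs if c != 0.0
        )
        return SignificanceResult(branch="dunnett", normality_p=1.0,
                                  variance_homogeneity_p=1.0, decisions=decisions)

    # pretests on the transformed data
    residuals = np.concatenate([v - v.mean() for v in logs.values()])
    if np.allclose(residuals, residuals[0]):
        norm_p, bart_p = 1.0, 1.0  # degenerate: identical replicates
    else:
        norm_p = float(stats.shapiro(residuals).pvalue)
        try:
            bart_p = float(stats.bartlett(*logs.values()).pvalue)
        except ValueError:
            bart_p = 0.0

    if norm_p > pretest_alpha and bart_p > pretest_alpha:
        branch = "dunnett"
        # fixed rng: the multivariate-t integration is randomised QMC and
        # p-values must be reproducible run to run
        res = stats.dunnett(*treated, control=control, alternative="greater",
                            rng=np.random.default_rng(_DUNNETT_QMC_SEED))
        pvals = np.asarray(res.pvalue, dtype=float)
    else:
        branch = "dunn"
        pvals = dunn_many_to_one(control, treated, alternative="greater")

    decisions = []
    for c, p in zip([c for c in concs if c != 0.0], pvals):
        sig = tuple(a for a in ALPHA_LEVELS if p < a)
        decisions.append(ConcentrationDecision(concentration=c, p_value=float(p),
                                               significant_at=sig))
    return SignificanceResult(
        branch=branch, normality_p=norm_p, variance_homogeneity_p=bart_p,
        decisions=tuple(decisions),
    )


def dunn_many_to_one(
    control: np.ndarray,
    treated: Sequence[np.ndarray],
    alternative: str = "greater",
) -> np.ndarray:
    """Dunn's rank-based many-to-one comparisons against control.

    Joint ranking over all groups with tie correction; z statistic per
    comparison; one-sided p-values with Sidak family correction across the
    k many-to-one comparisons.
    """
    groups = [np.asarray(control, float)] + [np.asarray(t, float) for t in treated]
    all_vals = np.concatenate(groups)
    n = all_vals.size
    ranks = stats.rankdata(all_vals)
    # tie correction term for the variance of mean ranks
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_unit = n * (n + 1) / 12.0 - tie_term

    sizes = [g.size for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(groups))
    ]
    k = len(treated)
    pvals = np.empty(k)
    for i in range(k):
        se = np.sqrt(var_unit * (1.0 / sizes[0] + 1.0 / sizes[i + 1]))
        z = (mean_ranks[i + 1] - mean_ranks[0]) / se if se > 0 else 0.0
        if alternative == "greater":
            p = stats.norm.sf(z)
        elif alternative == "less":
            p = stats.norm.cdf(z)
        else:
            p = 2.0 * stats.norm.sf(abs(z))
        # Sidak family correction over the k comparisons
        pvals[i] = 1.0 - (1.0 - min(p, 1.0)) ** k
    return np.clip(pvals, 0.0, 1.0)
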