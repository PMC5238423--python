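"""Repeatability (intraclass correlation) of migration timing with a
permutation test.

Repeatability r is the between-individual share of the total phenotypic
variance, r = sigma2_b / (sigma2_b + sigma2_w), estimated from a one-way
random-effects ANOVA decomposition with the unbalanced-design group-size
correction k0 = (N - sum(n_i^2)/N) / (I - 1). A negative between-group
variance estimate is truncated to zero. Significance comes from permuting
individual labels across observations and ranking the observed r in the
permutation ensemble, with the add-one convention so p is never exactly 0.

Only individuals with more than one observation contribute; singletons are
dropped (and counted) before estimation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np


@dataclass
class RepeatabilityResult:
    r: float
    sigma2_between: float
    sigma2_within: float
    n_individuals: int
    n_obs: int
    n_singletons_dropped: int
    event: str = ""
    n_permutations: Optional[int] = None
    p_perm: Optional[float] = None


def _prepare(values, ids, years=None) -> Tuple[np.ndarray, np.ndarray, int]:
    values = np.asarray(values, dtype=float)
    ids = np.asarray(ids)
    if len(values) != len(ids):
        raise ValueError("values and ids must align")
    keep = np.isfinite(values)
    values, ids = values[keep], ids[keep]
    if years is not None:
        yr = np.asarray(years, dtype=float)[keep]
        X = np.column_stack([np.ones_like(yr), yr])
        beta, *_ = np.linalg.lstsq(X, values, rcond=None)
        values = values - X @ beta
    _, inv, counts = np.unique(ids, return_inverse=True, return_counts=True)
    multi = counts[inv] > 1
    dropped = int(np.sum(counts == 1))
    values, inv = values[multi], inv[multi]
    # re-index groups compactly
    _, inv = np.unique(inv, return_inverse=True)
    return values, inv, dropped


def _icc_core(values: np.ndarray, inv: np.ndarray) -> Tuple[float, float, float, float]:
    """(r, sigma2_b, sigma2_w, r_untruncated) from pre-indexed group labels.

    ``r_untruncated`` keeps a negative between-group component; the reported
    r truncates it at zero. The permutation test ranks on the untruncated
    statistic, which is continuous under the null — ranking on the truncated
    r would pile null p-values at 1 because of the point mass at r = 0.
    """
    N = len(values)
    I = int(inv.max()) + 1
    ni = np.bincount(inv, minlength=I).astype(float)
    sums = np.bincount(inv, weights=values, minlength=I)
    means = sums / ni
    grand = values.mean()
    ssb = float(np.sum(ni * (means - grand) ** 2))
    ssw = float(np.sum((values - means[inv]) ** 2))
    msb = ssb / (I - 1)
    msw = ssw / (N - I)
    k0 = (N - float(np.sum(ni * ni)) / N) / (I - 1)
    s2b_raw = (msb - msw) / k0
    s2b = max(s2b_raw, 0.0)
    s2w = msw
    total = s2b + s2w
    r = s2b / total if total > 0 else 1.0
    if s2b_raw + s2w != 0:
        r_raw = s2b_raw / (s2b_raw + s2w)
    else:
        r_raw = 1.0
    return r, s2b, s2w, r_raw


def icc_estimate(values, ids, event: str = "", detrend_years=None) -> RepeatabilityResult:
    """ANOVA-based intraclass correlation across individuals.

    Requires at least two individuals with at least two observations each.
    When ``detrend_years`` (an aligned year vector) is given, the shared
    linear year trend is removed first; with individuals sampled in different
    periods a population trend otherwise masquerades as between-individual
    variance.
    """
    v, inv, dropped = _prepare(values, ids, detrend_years)
    I = int(inv.max()) + 1 if len(inv) else 0
    if I < 2:
        raise ValueError("need >=2 individuals with >=2 observations each")
    r, s2b, s2w, _ = _icc_core(v, inv)
    return RepeatabilityResult(r=r, sigma2_between=s2b, sigma2_within=s2w,
                               n_individuals=I, n_obs=len(v),
                               n_singletons_dropped=dropped, event=event)


def permutation_test(values, ids, n_perm: int = 5000,
                     seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None,
                     event: str = "", detrend_years=None) -> RepeatabilityResult:
    """Permutation significance of repeatability: individual labels shuffled
    across observations, p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)."""
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    v, inv, dropped = _prepare(values, ids, detrend_years)
    I = int(inv.max()) + 1 if len(inv) else 0
    if I < 2:
        raise ValueError("need >=2 individuals with >=2 observations each")
    r_obs, s2b, s2w, r_obs_raw = _icc_core(v, inv)
    count = 0
    vv = v.copy()
    for _ in range(n_perm):
        rng.shuffle(vv)
        _, _, _, r_p_raw = _icc_core(vv, inv)
        if r_p_raw >= r_obs_raw:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return RepeatabilityResult(r=r_obs, sigma2_between=s2b, sigma2_within=s2w,
                               n_individuals=I, n_obs=len(v),
                               n_singletons_dropped=dropped, event=event,
                               n_permutations=n_perm, p_perm=p)


def lmm_variance_ratio(values, ids) -> float:
    """Mixed-model (REML) variance-ratio repeatability, used as an
    independent cross-check of the ANOVA estimator (the two coincide on
    balanced designs with an interior variance estimate)."""
    import statsmodels.api as sm

    v, inv, _ = _prepare(values, ids)
    X = np.ones((len(v), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MixedLM(v, X, groups=inv).fit(reml=True, method="powell", maxiter=2000)
    s2b = float(np.asarray(res.cov_re)[0, 0])
    s2w = float(res.scale)
    return s2b / (s2b + s2w)
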