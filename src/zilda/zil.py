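"""Ratio-based zero-inflated lognormal (ZIL) differential abundance.

The method normalises a compositional abundance table by dividing every
feature by a *divisor* feature (or the geometric mean of a set of features)
that is strictly positive in all samples.  The resulting per-feature ratio
vector ``r_ij`` is modelled as a two-component mixture:

    R ~ Unif(0, eps)        with probability p      (dropout / undersampling)
    R ~ LogNormal(mu, s^2)  with probability 1 - p  (true abundance)

where ``eps`` is the smallest positive ratio observed anywhere in the table,
so the dropout component's support contains no observed positive value.
Observed zeros are the (censored) dropout candidates; they are imputed at
the midpoint ``eps/2`` of the uniform support and assigned a posterior
responsibility ``tau`` of belonging to the dropout component by EM.  The
mixture weight, log-mean and log-sd are estimated per feature and per group,
and group differences in the log-mean are tested with a responsibility-
weighted Welch t statistic.  When a feature has no zeros the procedure
collapses exactly to the classical Welch t-test on log ratios.

Because every feature is divided by the same per-sample divisor value, all
results are invariant to sample-wise rescaling (sequencing depth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import CountTable, SampleMetadata, group_map, write_commented_tsv

SIGMA_FLOOR = 1e-6
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class ZILError(ValueError):
    """Raised for invalid inputs to the differential-abundance machinery."""


@dataclass(frozen=True)
class DivisorSpec:
    """The feature(s) used as the ratio denominator.

    ``combine_rule='single'`` requires exactly one feature; with
    ``'geometric_mean'`` the per-sample denominator is the geometric mean of
    the set.  Every referenced feature must be strictly positive in all
    samples entering the analysis.
    """

    feature_ids: tuple[str, ...]
    combine_rule: str = "single"

    def __post_init__(self) -> None:
        if len(self.feature_ids) == 0:
            raise ZILError("divisor needs at least one feature")
        if self.combine_rule not in ("single", "geometric_mean"):
            raise ZILError(f"unknown combine_rule {self.combine_rule!r}")
        if self.combine_rule == "single" and len(self.feature_ids) != 1:
            raise ZILError("combine_rule 'single' requires exactly one feature")


@dataclass
class RatioTable:
    """Per-sample abundance ratios against the divisor, with the eps floor."""

    feature_ids: list[str]
    sample_ids: list[str]
    ratios: np.ndarray
    epsilon: float
    zero_mask: np.ndarray
    divisor: DivisorSpec


@dataclass
class ZILParams:
    """Converged mixture parameters for one feature in one group."""

    p: float
    mu: float
    sigma: float
    loglik: float
    n_iter: int
    converged: bool
    trace: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


@dataclass
class EMState:
    """Log-scale observations and dropout responsibilities after EM.

    ``tau`` is exactly 0 for positive ratios (the uniform component's support
    lies entirely below the smallest positive ratio).
    """

    y: np.ndarray
    tau: np.ndarray

    @property
    def n_effective(self) -> float:
        return float(np.sum(1.0 - self.tau))


@dataclass
class DifferentialResult:
    feature_id: str
    delta_mu: float
    t_stat: float
    df: float
    p_value: float
    q_value: float = math.nan
    significant: bool = False
    untestable: bool = False


@dataclass
class DifferentialTable:
    """Full output of :func:`run_differential`, sorted by q-value."""

    results: list[DifferentialResult]
    divisor: DivisorSpec
    epsilon: float
    fdr_level: float
    group_a: str
    group_b: str
    min_prevalence: float
    n_features_input: int
    n_features_tested: int

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": [r.feature_id for r in self.results],
                "delta_mu": [r.delta_mu for r in self.results],
                "t_stat": [r.t_stat for r in self.results],
                "df": [r.df for r in self.results],
                "p_value": [r.p_value for r in self.results],
                "q_value": [r.q_value for r in self.results],
                "significant": [r.significant for r in self.results],
            }
        )

    def significant_ids(self) -> list[str]:
        return [r.feature_id for r in self.results if r.significant]

    def write(self, path, version: str = "") -> None:
        comment = (
            f"zilda{(' ' + version) if version else ''} differential: "
            f"groups={self.group_a} vs {self.group_b}; "
            f"divisor={','.join(self.divisor.feature_ids)} "
            f"({self.divisor.combine_rule}); epsilon={self.epsilon:.6g}; "
            f"min_prevalence={self.min_prevalence}; fdr_level={self.fdr_level}"
        )
        write_commented_tsv(self.frame, path, comment)


# ---------------------------------------------------------------------------
# divisor selection and ratio transform
# ---------------------------------------------------------------------------


def _all_positive_mask(values: np.ndarray) -> np.ndarray:
    return (values > 0).all(axis=1)


def select_divisor(
    table: CountTable,
    samples: Sequence[str] | None = None,
    strategy: str = "min_variance",
    manual_features: Sequence[str] | None = None,
    metadata: Sequence[SampleMetadata] | None = None,
    group_a: str | None = None,
    group_b: str | None = None,
    fdr_level: float = 0.05,
    min_prevalence: float = 0.2,
    max_rounds: int = 5,
) -> DivisorSpec:
    """Choose the ratio denominator.

    ``min_variance`` picks the all-positive feature whose log relative
    abundance varies least across samples (a stable "reference" taxon).
    ``iterative`` starts from that choice, runs the full differential test,
    rebuilds the divisor as the geometric mean of all-positive features *not*
    called significant, and repeats until the significant set stabilises (at
    most ``max_rounds`` rounds).  ``manual`` validates a caller-supplied set.
    """
    sub = table if samples is None else table.subset_samples(list(samples))
    values = sub.values
    if strategy == "manual":
        if not manual_features:
            raise ZILError("manual divisor strategy requires manual_features")
        for fid in manual_features:
            row = values[sub.feature_index(fid)]
            if (row <= 0).any():
                j = int(np.argmax(row <= 0))
                raise ZILError(
                    f"manual divisor feature {fid!r} is not positive in sample "
                    f"{sub.sample_ids[j]!r}"
                )
        rule = "single" if len(manual_features) == 1 else "geometric_mean"
        return DivisorSpec(tuple(manual_features), rule)

    allpos = _all_positive_mask(values)
    if not allpos.any():
        raise ZILError(
            "no feature is positive in every sample; apply a prevalence filter "
            "or supply a pseudo-divisor manually"
        )
    colsums = values.sum(axis=0)
    with np.errstate(divide="ignore"):
        logrel = np.log(values[allpos] / colsums)
    variances = logrel.var(axis=1)
    candidates = np.flatnonzero(allpos)
    best = candidates[int(np.argmin(variances))]
    divisor = DivisorSpec((sub.feature_ids[best],), "single")
    if strategy == "min_variance":
        return divisor
    if strategy != "iterative":
        raise ZILError(f"unknown divisor strategy {strategy!r}")

    if metadata is None or group_a is None or group_b is None:
        raise ZILError("iterative divisor strategy requires metadata and group labels")
    prev_sig: set[str] | None = None
    for _ in range(max_rounds):
        diff = run_differential(
            table,
            metadata,
            group_a,
            group_b,
            fdr_level=fdr_level,
            divisor=divisor,
            min_prevalence=min_prevalence,
        )
        sig = set(diff.significant_ids())
        if sig == prev_sig:
            break
        prev_sig = sig
        keep = [
            fid
            for fid, ok in zip(sub.feature_ids, allpos)
            if ok and fid not in sig
        ]
        if not keep:
            break
        rule = "single" if len(keep) == 1 else "geometric_mean"
        divisor = DivisorSpec(tuple(keep), rule)
    return divisor


def compute_ratios(table: CountTable, divisor: DivisorSpec) -> RatioTable:
    """Form r_ij = gamma_ij / d_j and determine the global eps floor.

    ``d_j`` is the divisor feature's abundance in sample j (or the geometric
    mean over the divisor set); divisor rows are removed from the output.
    eps is the minimum positive ratio over all remaining entries.
    """
    idx = [table.feature_index(f) for f in divisor.feature_ids]
    div_rows = table.values[idx]
    if (div_rows <= 0).any():
        i, j = np.argwhere(div_rows <= 0)[0]
        raise ZILError(
            f"divisor feature {divisor.feature_ids[i]!r} is zero in sample "
            f"{table.sample_ids[j]!r}"
        )
    if divisor.combine_rule == "single":
        d = div_rows[0]
    else:
        d = np.exp(np.mean(np.log(div_rows), axis=0))
    keep = [i for i in range(len(table.feature_ids)) if i not in set(idx)]
    ratios = table.values[keep] / d
    positive = ratios[ratios > 0]
    if positive.size == 0:
        raise ZILError("ratio table has no positive entries")
    epsilon = float(positive.min())
    return RatioTable(
        feature_ids=[table.feature_ids[i] for i in keep],
        sample_ids=list(table.sample_ids),
        ratios=ratios,
        epsilon=epsilon,
        zero_mask=ratios == 0,
        divisor=divisor,
    )


# ---------------------------------------------------------------------------
# the ZIL mixture and its EM fit
# ---------------------------------------------------------------------------


def _lognorm_logpdf(r: float | np.ndarray, mu: float, sigma: float):
    logr = np.log(r)
    return -np.log(sigma) - _LOG_SQRT_2PI - logr - (logr - mu) ** 2 / (2.0 * sigma**2)


def zil_density(r, params, epsilon: float):
    """Mixture density p * Unif(0,eps) + (1-p) * LogNormal(mu, sigma^2) at r > 0."""
    p, mu, sigma = _unpack_params(params)
    r = np.asarray(r, dtype=float)
    if (r <= 0).any():
        raise ZILError("zil_density is defined for r > 0 only")
    if epsilon <= 0:
        raise ZILError("epsilon must be positive")
    uniform = np.where(r < epsilon, 1.0 / epsilon, 0.0)
    dens = p * uniform + (1.0 - p) * np.exp(_lognorm_logpdf(r, mu, sigma))
    return float(dens) if dens.ndim == 0 else dens


def _unpack_params(params) -> tuple[float, float, float]:
    if isinstance(params, ZILParams):
        return params.p, params.mu, params.sigma
    p, mu, sigma = params
    return float(p), float(mu), float(sigma)


def observed_loglik(
    p: float, mu: float, sigma: float, ratios: np.ndarray, epsilon: float
) -> float:
    """Observed-data log-likelihood with zeros imputed at eps/2.

    This is the objective the EM iterations monotonically increase, and the
    one the brute-force grid oracle maximises.
    """
    r = np.asarray(ratios, dtype=float)
    pos = r[r > 0]
    n0 = r.size - pos.size
    ll = pos.size * math.log1p(-p) if p < 1 else -math.inf
    ll += float(np.sum(_lognorm_logpdf(pos, mu, sigma)))
    if n0:
        delta = epsilon / 2.0
        log_drop = (math.log(p) if p > 0 else -math.inf) - math.log(epsilon)
        log_ln = math.log1p(-p) + float(_lognorm_logpdf(delta, mu, sigma))
        ll += n0 * float(np.logaddexp(log_drop, log_ln))
    return ll


def fit_zil_em_state(
    ratios_row,
    epsilon: float,
    tol: float = 1e-8,
    max_iter: int = 500,
    sigma_floor: float = SIGMA_FLOOR,
) -> tuple[ZILParams, EMState]:
    """EM fit of the ZIL mixture for one feature's ratio vector.

    E-step: zeros (imputed at delta = eps/2) receive responsibility
    tau = p*u / (p*u + (1-p)*LN(delta)) of being dropouts, with u = 1/eps;
    positive entries have tau = 0.  M-step: p = mean(tau),
    mu = sum((1-tau) y) / sum(1-tau), sigma^2 analogously.  Because all
    zeros share the same imputed value, each iteration reduces to scalar
    updates on sufficient statistics of the positive entries.
    """
    r = np.asarray(ratios_row, dtype=float).ravel()
    if r.size == 0:
        raise ZILError("empty ratio vector")
    if (r < 0).any():
        raise ZILError("ratios must be nonnegative")
    if epsilon <= 0:
        raise ZILError("epsilon must be positive")
    pos = r > 0
    n = r.size
    n_pos = int(pos.sum())
    n0 = n - n_pos
    if n_pos == 0:
        raise ZILError("all entries are zero; feature is unidentifiable")
    if n_pos < 3:
        raise ZILError(
            f"need at least 3 positive entries to fit the mixture, got {n_pos}"
        )
    ypos = np.log(r[pos])
    s1 = float(ypos.sum())
    s2 = float((ypos**2).sum())
    delta = epsilon / 2.0
    y0 = math.log(delta)
    log_u = -math.log(epsilon)

    p = n0 / n
    mu = s1 / n_pos
    sigma = max(float(ypos.std()), sigma_floor)

    trace: list[float] = []
    converged = False
    tau0 = 0.0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step
        if n0:
            if p <= 0.0:
                tau0 = 0.0
            elif p >= 1.0:
                tau0 = 1.0
            else:
                la = math.log(p) + log_u
                lb = math.log1p(-p) + float(_lognorm_logpdf(delta, mu, sigma))
                diff = min(lb - la, 700.0)  # avoid overflow; tau0 underflows to 0
                tau0 = 1.0 / (1.0 + math.exp(diff))
        # M-step
        w0 = 1.0 - tau0
        weight = n_pos + n0 * w0
        p = (n0 * tau0) / n
        mu = (s1 + n0 * w0 * y0) / weight
        ss = (s2 - 2.0 * mu * s1 + n_pos * mu * mu) + n0 * w0 * (y0 - mu) ** 2
        sigma = max(math.sqrt(max(ss / weight, 0.0)), sigma_floor)

        ll = _loglik_scalar(p, mu, sigma, n_pos, n0, s1, s2, delta, log_u)
        trace.append(ll)
        if n_iter > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    params = ZILParams(
        p=p,
        mu=mu,
        sigma=sigma,
        loglik=trace[-1],
        n_iter=n_iter,
        converged=converged,
        trace=np.asarray(trace),
    )
    y = np.where(pos, np.log(np.where(pos, r, 1.0)), y0)
    tau = np.where(pos, 0.0, tau0)
    return params, EMState(y=y, tau=tau)


def _loglik_scalar(p, mu, sigma, n_pos, n0, s1, s2, delta, log_u) -> float:
    quad = (s2 - 2.0 * mu * s1 + n_pos * mu * mu) / (2.0 * sigma**2)
    ll = (
        (n_pos * math.log1p(-p) if p < 1 else -math.inf)
        - n_pos * (math.log(sigma) + _LOG_SQRT_2PI)
        - s1
        - quad
    )
    if n0:
        log_drop = (math.log(p) if p > 0 else -math.inf) + log_u
        logd = math.log(delta)
        log_ln = (
            (math.log1p(-p) if p < 1 else -math.inf)
            - math.log(sigma)
            - _LOG_SQRT_2PI
            - logd
            - (logd - mu) ** 2 / (2.0 * sigma**2)
        )
        ll += n0 * float(np.logaddexp(log_drop, log_ln))
    return ll


def fit_zil_em(
    ratios_row,
    epsilon: float,
    tol: float = 1e-8,
    max_iter: int = 500,
    sigma_floor: float = SIGMA_FLOOR,
) -> ZILParams:
    """Convenience wrapper returning only the converged parameters."""
    params, _ = fit_zil_em_state(ratios_row, epsilon, tol, max_iter, sigma_floor)
    return params


# ---------------------------------------------------------------------------
# the two-group test
# ---------------------------------------------------------------------------


def test_feature(
    params_a: ZILParams,
    state_a: EMState,
    params_b: ZILParams,
    state_b: EMState,
    feature_id: str = "",
) -> DifferentialResult:
    """Responsibility-weighted Welch t-test of mu_a vs mu_b.

    Effective sample sizes are sum(1 - tau); variances are weighted with an
    (n_eff - 1) denominator so the statistic equals the classical Welch t on
    log ratios when no zeros are present.  Degrees of freedom follow
    Welch-Satterthwaite.  Features with effective size < 2 in either group
    are reported untestable with p = 1.
    """
    wa = 1.0 - state_a.tau
    wb = 1.0 - state_b.tau
    na = float(wa.sum())
    nb = float(wb.sum())
    delta_mu = params_b.mu - params_a.mu
    if na < 2.0 or nb < 2.0:
        return DifferentialResult(
            feature_id, delta_mu, math.nan, math.nan, 1.0, untestable=True
        )
    s2a = float(np.sum(wa * (state_a.y - params_a.mu) ** 2)) / (na - 1.0)
    s2b = float(np.sum(wb * (state_b.y - params_b.mu) ** 2)) / (nb - 1.0)
    va = s2a / na
    vb = s2b / nb
    se = math.sqrt(va + vb)
    if se == 0.0:
        if delta_mu == 0.0:
            return DifferentialResult(feature_id, delta_mu, 0.0, na + nb - 2.0, 1.0)
        return DifferentialResult(
            feature_id, delta_mu, math.copysign(math.inf, delta_mu), na + nb - 2.0, 0.0
        )
    t = delta_mu / se
    df = (va + vb) ** 2 / (va**2 / (na - 1.0) + vb**2 / (nb - 1.0))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return DifferentialResult(feature_id, delta_mu, t, df, min(p, 1.0))


def run_differential(
    table: CountTable,
    metadata: Sequence[SampleMetadata],
    group_a: str,
    group_b: str,
    fdr_level: float = 0.05,
    divisor: DivisorSpec | None = None,
    divisor_strategy: str = "min_variance",
    min_prevalence: float = 0.2,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> DifferentialTable:
    """Full two-group differential-abundance analysis.

    Prevalence filter -> divisor selection -> ratio transform (one divisor
    and one shared eps across both groups) -> per-feature, per-group EM fits
    -> per-feature weighted Welch test -> Benjamini-Hochberg adjustment at
    ``fdr_level``.  Features positive in fewer than ``min_prevalence`` of the
    samples of *both* groups, or with fewer than 3 positive samples in either
    group (below which the lognormal component is unidentifiable), are
    excluded before testing.
    """
    gm = group_map(metadata)
    sa = [s for s in table.sample_ids if gm.get(s) == group_a]
    sb = [s for s in table.sample_ids if gm.get(s) == group_b]
    if len(sa) < 3 or len(sb) < 3:
        raise ZILError(
            f"both groups need at least 3 samples; got {len(sa)} "
            f"({group_a!r}) and {len(sb)} ({group_b!r})"
        )
    sub = table.subset_samples(sa + sb)
    a_cols = np.arange(len(sa))
    b_cols = np.arange(len(sa), len(sa) + len(sb))

    pos = sub.values > 0
    npos_a = pos[:, a_cols].sum(axis=1)
    npos_b = pos[:, b_cols].sum(axis=1)
    prev_a = npos_a / len(sa)
    prev_b = npos_b / len(sb)
    keep = (
        ((prev_a >= min_prevalence) | (prev_b >= min_prevalence))
        & (npos_a >= 3)
        & (npos_b >= 3)
    )

    if divisor is None:
        divisor = select_divisor(
            sub,
            strategy=divisor_strategy,
            metadata=metadata,
            group_a=group_a,
            group_b=group_b,
            fdr_level=fdr_level,
            min_prevalence=min_prevalence,
        )
    for fid in divisor.feature_ids:
        keep[sub.feature_index(fid)] = True  # divisor rows must enter the transform

    kept_ids = [fid for fid, k in zip(sub.feature_ids, keep) if k]
    if len(kept_ids) < 2:
        raise ZILError("fewer than 2 features pass the prevalence filter")
    rt = compute_ratios(sub.subset_features(kept_ids), divisor)

    results: list[DifferentialResult] = []
    for i, fid in enumerate(rt.feature_ids):
        row = rt.ratios[i]
        try:
            pa, sta = fit_zil_em_state(row[a_cols], rt.epsilon, tol, max_iter)
            pb, stb = fit_zil_em_state(row[b_cols], rt.epsilon, tol, max_iter)
        except ZILError as exc:
            raise ZILError(f"feature {fid!r}: {exc}") from exc
        results.append(test_feature(pa, sta, pb, stb, feature_id=fid))

    pvals = np.array([r.p_value for r in results])
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr_level, method="fdr_bh")
    for r, q, rej in zip(results, qvals, reject):
        r.q_value = float(q)
        r.significant = bool(rej) and not r.untestable
    results.sort(key=lambda r: (r.q_value, r.p_value, r.feature_id))

    return DifferentialTable(
        results=results,
        divisor=divisor,
        epsilon=rt.epsilon,
        fdr_level=fdr_level,
        group_a=group_a,
        group_b=group_b,
        min_prevalence=min_prevalence,
        n_features_input=len(table.feature_ids),
        n_features_tested=len(results),
    )
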