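"""Alpha diversity, rank-based group comparison, and the diversity-disease logit.

Shannon entropy H = -sum(a_j ln a_j) (nats) and the inverse-Simpson
effective species number n_eff = 1 / sum(a_j^2) are computed per sample on
relative abundances.  Disease states are compared with Kruskal-Wallis plus
Dunn's pairwise post-hoc z tests (tie-corrected).  A univariate logistic
regression links Shannon diversity d to the probability of CRC:
logit(P) = b1 * d + b0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit as _logit_fn

from .tables import CountTable, SampleMetadata, group_map, to_relative_abundance


class DiversityError(ValueError):
    """Raised for invalid diversity inputs."""


@dataclass
class DiversityRecord:
    sample_id: str
    shannon: float
    inv_simpson: float
    group: str


@dataclass
class LogitFit:
    """Logistic diversity-disease fit: logit(P) = slope * d + intercept."""

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    p_slope: float
    converged: bool


def _check_relative(abundances) -> np.ndarray:
    a = np.asarray(abundances, dtype=float).ravel()
    if a.size == 0:
        raise DiversityError("empty abundance vector")
    if (a < 0).any():
        raise DiversityError("abundances must be nonnegative")
    total = a.sum()
    if abs(total - 1.0) > 1e-9:
        raise DiversityError(f"abundances must sum to 1 (got {total!r})")
    return a


def shannon_index(abundances) -> float:
    """Shannon entropy in nats; zero entries contribute 0 (x ln x -> 0 limit)."""
    a = _check_relative(abundances)
    nz = a[a > 0]
    return float(-np.sum(nz * np.log(nz)))


def inverse_simpson(abundances) -> float:
    """Effective species number 1 / sum(a_j^2)."""
    a = _check_relative(abundances)
    return float(1.0 / np.sum(a**2))


def diversity_table(
    table: CountTable, metadata: Sequence[SampleMetadata]
) -> pd.DataFrame:
    """Per-sample Shannon and inverse-Simpson indices, with group labels."""
    rel = to_relative_abundance(table)
    gm = group_map(metadata)
    rows = []
    for j, sid in enumerate(rel.sample_ids):
        col = rel.values[:, j]
        rows.append(
            {
                "sample_id": sid,
                "group": gm.get(sid, ""),
                "shannon": shannon_index(col),
                "inv_simpson": inverse_simpson(col),
            }
        )
    return pd.DataFrame(rows)


def kruskal_test(values_by_group: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H and p over the groups."""
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise DiversityError("need at least 2 groups")
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(
    values_by_group: Mapping[str, Sequence[float]],
    adjust: str | None = None,
) -> pd.DataFrame:
    """Dunn's pairwise post-hoc test on joint mid-ranks.

    For groups a, b with mean ranks Ra, Rb over the pooled sample of size N,

        z = (Ra - Rb) / sqrt([N(N+1)/12 - T/(12(N-1))] (1/na + 1/nb))

    with the tie correction T = sum(t^3 - t) over tie groups; p is two-sided
    normal.  ``adjust`` may be None (default, matching unadjusted pairwise
    reporting), 'bonferroni', or 'bh'.
    """
    names = list(values_by_group.keys())
    groups = {k: np.asarray(values_by_group[k], dtype=float) for k in names}
    if len(names) < 2:
        raise DiversityError("need at least 2 groups")
    for k, v in groups.items():
        if v.size < 2:
            raise DiversityError(f"group {k!r} has fewer than 2 values")
    pooled = np.concatenate([groups[k] for k in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for k in names:
        size = groups[k].size
        mean_ranks[k] = float(ranks[start : start + size].mean())
        start += size
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    rows = []
    for a, b in combinations(names, 2):
        na, nb = groups[a].size, groups[b].size
        var = base_var * (1.0 / na + 1.0 / nb)
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / math.sqrt(var)
            p = 2.0 * float(stats.norm.sf(abs(z)))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": min(p, 1.0)})
    frame = pd.DataFrame(rows)
    if adjust is None:
        frame["p_adjusted"] = frame["p"]
        frame["method"] = "none"
    elif adjust == "bonferroni":
        frame["p_adjusted"] = np.minimum(frame["p"] * len(frame), 1.0)
        frame["method"] = "bonferroni"
    elif adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        frame["p_adjusted"] = multipletests(frame["p"], method="fdr_bh")[1]
        frame["method"] = "bh"
    else:
        raise DiversityError(f"unknown adjustment {adjust!r}")
    return frame


def fit_logit(diversity, status) -> LogitFit:
    """Maximum-likelihood logistic regression of binary status on diversity.

    Complete separation is flagged (``converged=False``) with a warning
    rather than raised, keeping the plain MLE semantics.  A zero-variance
    predictor degenerates to the intercept-only model: slope 0, intercept
    logit(prevalence).
    """
    d = np.asarray(diversity, dtype=float).ravel()
    y = np.asarray(status, dtype=float).ravel()
    if d.size != y.size:
        raise DiversityError("diversity and status must have equal length")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or classes.size < 2:
        raise DiversityError("status must contain both classes coded 0/1")
    prev = float(y.mean())
    if np.ptp(d) == 0.0:
        # predictor collinear with the intercept; only the class mean is estimable
        se_int = math.sqrt(1.0 / (d.size * prev * (1.0 - prev)))
        return LogitFit(0.0, float(_logit_fn(prev)), math.inf, se_int, 1.0, True)
    x = sm.add_constant(d)
    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, x).fit(disp=0, maxiter=200)
        except Exception:  # e.g. PerfectSeparationError on older statsmodels
            separated = True
            res = sm.Logit(y, x).fit(method="bfgs", disp=0, maxiter=200)
        for w in caught:
            if "separation" in str(w.message).lower():
                separated = True
    converged = bool(res.mle_retvals.get("converged", False)) and not separated
    try:
        bse = np.asarray(res.bse, dtype=float)
        pvals = np.asarray(res.pvalues, dtype=float)
    except Exception:
        bse = np.array([math.nan, math.nan])
        pvals = np.array([math.nan, math.nan])
    if not np.all(np.isfinite(bse)):
        converged = False
    if separated:
        warnings.warn(
            "complete separation detected in logistic fit; estimates diverge "
            "and standard errors are unreliable",
            stacklevel=2,
        )
    return LogitFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        se_slope=float(bse[1]) if bse.size > 1 else math.inf,
        se_intercept=float(bse[0]),
        p_slope=float(pvals[1]) if pvals.size > 1 else 1.0,
        converged=converged,
    )


def predict_probability(fit_or_coeffs, d) -> float | np.ndarray:
    """Logistic probability at diversity d, from a LogitFit or (slope, intercept)."""
    if isinstance(fit_or_coeffs, LogitFit):
        slope, intercept = fit_or_coeffs.slope, fit_or_coeffs.intercept
    else:
        slope, intercept = fit_or_coeffs
    eta = slope * np.asarray(d, dtype=float) + intercept
    p = expit(eta)
    tiny = np.finfo(float).tiny
    p = np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)
    return float(p) if p.ndim == 0 else p


def crc_logit_from_diversity(
    div_frame: pd.DataFrame, mode: str = "healthy-vs-crc"
) -> LogitFit:
    """Fit the diversity-disease logit from a :func:`diversity_table` frame.

    ``mode='healthy-vs-crc'`` (default) fits on healthy + CRC samples only;
    ``mode='all'`` uses every sample with CRC as the positive class.
    """
    if mode == "healthy-vs-crc":
        sel = div_frame[div_frame["group"].isin(["healthy", "crc"])]
    elif mode == "all":
        sel = div_frame
    else:
        raise DiversityError(f"unknown logit mode {mode!r}")
    status = (sel["group"] == "crc").astype(float).to_numpy()
    return fit_logit(sel["shannon"].to_numpy(), status)


def three_state_groups(div_frame: pd.DataFrame) -> dict[str, np.ndarray]:
    """Shannon values keyed by the three progression states.

    Small and large adenoma are pooled into one 'adenoma' state for the
    healthy -> adenoma -> cancer comparison.
    """
    state_of = {
        "healthy": "healthy",
        "small_adenoma": "adenoma",
        "large_adenoma": "adenoma",
        "crc": "crc",
    }
    out: dict[str, list[float]] = {"healthy": [], "adenoma": [], "crc": []}
    for _, row in div_frame.iterrows():
        state = state_of.get(row["group"])
        if state:
            out[state].append(float(row["shannon"]))
    return {k: np.asarray(v) for k, v in out.items() if len(v) > 0}
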