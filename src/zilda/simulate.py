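"""Synthetic sparse metagenomic studies with known ground truth.

The generator emulates the statistical structure of a stool-metagenome
genus table from a colorectal-cancer case-control cohort:

* four disease states (healthy / small adenoma / large adenoma / CRC) with
  cohort-like default group sizes 61/27/15/53,
* per-feature lognormal latent abundances with feature-specific dropout
  probabilities, giving structural zeros; multinomial sampling at a
  lognormal sequencing depth adds sampling zeros on top, so the emitted
  table is more than half zeros under the defaults,
* a stage-graded evenness gradient (compositions sharpened by a per-state
  power) so expected Shannon diversity declines healthy -> adenoma -> CRC,
* an optional fraction of planted differential features whose log-mean is
  shifted in CRC samples, and
* one guaranteed all-positive, non-differential reference feature so
  divisor selection is always well-posed.

Every draw flows from a single integer seed; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .tables import GROUPS, STAGES, CountTable, SampleMetadata


class SimulationError(ValueError):
    """Raised for invalid simulation configs."""


#: Cohort-like default group sizes (healthy, small adenoma, large adenoma, CRC).
DEFAULT_GROUP_SIZES = {
    "healthy": 61,
    "small_adenoma": 27,
    "large_adenoma": 15,
    "crc": 53,
}

#: CRC stage proportions used when assigning stages (I/II/III/IV of 53).
_STAGE_WEIGHTS = np.array([15, 7, 10, 21], dtype=float) / 53.0


@dataclass
class SimConfig:
    """Study-level generative parameters.

    ``evenness_gradient`` g sharpens each state's compositions by raising
    them to the power 1 + g * stage_index (healthy = 0 ... CRC = 3); any
    g > 0 makes expected Shannon diversity strictly decreasing along
    progression.  ``effect_log`` is the shift added to the log-mean of
    planted features in CRC samples.
    """

    seed: int
    n_features: int = 200
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    frac_differential: float = 0.1
    effect_log: float = 2.0
    dropout_range: tuple[float, float] = (0.3, 0.8)
    mu_range: tuple[float, float] = (0.0, 3.0)
    sigma_range: tuple[float, float] = (0.3, 1.2)
    depth_logmean: float = math.log(50_000.0)
    depth_logsd: float = 0.3
    evenness_gradient: float = 0.1

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if self.n_features < 3:
            raise SimulationError("need at least 3 features")
        for name in ("dropout_range", "mu_range", "sigma_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise SimulationError(f"{name} must be ordered (lo <= hi)")
        if not (0.0 <= self.frac_differential <= 1.0):
            raise SimulationError("frac_differential must be in [0, 1]")
        lo, hi = self.dropout_range
        if not (0.0 <= lo and hi <= 1.0):
            raise SimulationError("dropout_range must lie in [0, 1]")
        for g in self.n_samples_per_group:
            if g not in GROUPS:
                raise SimulationError(f"unknown group {g!r} in n_samples_per_group")
        if self.evenness_gradient < 0:
            raise SimulationError("evenness_gradient must be nonnegative")


@dataclass
class GroundTruth:
    """What was planted, for use as a test oracle."""

    differential_ids: frozenset[str]
    true_params: dict[str, dict[str, tuple[float, float, float]]]
    reference_id: str


def simulate_zil_vector(
    n: int, p: float, mu: float, sigma: float, epsilon: float, seed: int
) -> np.ndarray:
    """Direct sampler of the ZIL mixture: 0 with probability p (a dropout,
    later imputed below the eps floor), else exp(Normal(mu, sigma^2))."""
    if not (0.0 <= p <= 1.0):
        raise SimulationError("p must be in [0, 1]")
    if sigma < 0:
        raise SimulationError("sigma must be nonnegative")
    if epsilon <= 0:
        raise SimulationError("epsilon must be positive")
    rng = np.random.default_rng(seed)
    values = np.exp(rng.normal(mu, sigma, size=n))
    drop = rng.random(n) < p
    values[drop] = 0.0
    return values


def simulate_study(
    config: SimConfig,
) -> tuple[CountTable, list[SampleMetadata], GroundTruth]:
    """Draw a full study: counts, metadata with stages, and ground truth."""
    rng = np.random.default_rng(config.seed)
    n_feat = config.n_features

    feature_ids = [f"g{i:04d}" for i in range(n_feat)]
    reference_id = feature_ids[0]

    mu = rng.uniform(*config.mu_range, size=n_feat)
    sigma = rng.uniform(*config.sigma_range, size=n_feat)
    dropout = rng.uniform(*config.dropout_range, size=n_feat)
    # the planted reference: always present, high and stable abundance
    mu[0] = config.mu_range[1] + 1.0
    sigma[0] = 0.05
    dropout[0] = 0.0

    n_diff = int(round(config.frac_differential * n_feat))
    n_diff = min(n_diff, n_feat - 1)
    if n_diff > 0:
        diff_idx = rng.choice(np.arange(1, n_feat), size=n_diff, replace=False)
    else:
        diff_idx = np.array([], dtype=int)
    diff_mask = np.zeros(n_feat, dtype=bool)
    diff_mask[diff_idx] = True

    log_p_all_zero = float(np.sum(np.log(np.clip(dropout[1:], 1e-300, 1.0))))
    if log_p_all_zero > math.log(0.5):
        warnings.warn(
            "configuration gives each sample > 0.5 probability of dropping "
            "every non-reference feature",
            stacklevel=2,
        )

    stage_index = {g: k for k, g in enumerate(GROUPS)}
    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    metadata: list[SampleMetadata] = []
    for group in GROUPS:
        n_samples = int(config.n_samples_per_group.get(group, 0))
        if n_samples == 0:
            continue
        mu_g = mu.copy()
        if group == "crc":
            mu_g[diff_mask] += config.effect_log
        beta = 1.0 + config.evenness_gradient * stage_index[group]
        latent = np.exp(
            rng.normal(mu_g[:, None], sigma[:, None], size=(n_feat, n_samples))
        )
        drop = rng.random((n_feat, n_samples)) < dropout[:, None]
        latent[drop] = 0.0
        comp = latent**beta
        comp /= comp.sum(axis=0)
        depths = np.maximum(
            np.rint(np.exp(rng.normal(config.depth_logmean, config.depth_logsd, n_samples))),
            1.0,
        ).astype(np.int64)
        for j in range(n_samples):
            sid = f"{group}-{j + 1:03d}"
            sample_ids.append(sid)
            columns.append(rng.multinomial(depths[j], comp[:, j]).astype(float))
            stage = None
            if group == "crc":
                stage = STAGES[int(rng.choice(4, p=_STAGE_WEIGHTS))]
            metadata.append(SampleMetadata(sid, group, stage))

    table = CountTable(feature_ids, sample_ids, np.column_stack(columns))

    true_params: dict[str, dict[str, tuple[float, float, float]]] = {}
    for i, fid in enumerate(feature_ids):
        per_group: dict[str, tuple[float, float, float]] = {}
        for group in GROUPS:
            shift = config.effect_log if (group == "crc" and diff_mask[i]) else 0.0
            per_group[group] = (float(dropout[i]), float(mu[i] + shift), float(sigma[i]))
        true_params[fid] = per_group
    truth = GroundTruth(
        differential_ids=frozenset(feature_ids[i] for i in diff_idx),
        true_params=true_params,
        reference_id=reference_id,
    )
    return table, metadata, truth


def truth_frame(truth: GroundTruth):
    """Flatten ground truth to a writable table (one row per feature)."""
    import pandas as pd

    rows = []
    for fid in sorted(truth.true_params):
        p, mu_h, sig = truth.true_params[fid]["healthy"]
        _, mu_c, _ = truth.true_params[fid]["crc"]
        rows.append(
            {
                "feature_id": fid,
                "is_differential": fid in truth.differential_ids,
                "is_reference": fid == truth.reference_id,
                "dropout_p": p,
                "mu": mu_h,
                "sigma": sig,
                "mu_crc": mu_c,
            }
        )
    return pd.DataFrame(rows)
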