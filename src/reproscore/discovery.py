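"""Univariate biomarker discovery: per-feature two-sample tests with MCC.

The canonical discovery operator tests every feature with a pooled-variance
two-sided two-sample t-test, adjusts the p-values across all tested
features (Benjamini-Hochberg by default), and proposes as biomarkers the
features whose adjusted p-value falls strictly below the significance
threshold.  Welch's unequal-variance t is available as a non-canonical
alternative (``test="welch"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import BiomarkerSet, LabeledDataset

__all__ = [
    "DiscoveryError",
    "InsufficientDataError",
    "DiscoveryConfig",
    "FeatureTestResult",
    "pooled_t",
    "two_sided_p",
    "adjust_p",
    "discover",
]

_VALID_MCC = ("bh", "bonferroni", "none")
_VALID_TESTS = ("t", "welch")


class DiscoveryError(ValueError):
    """Discovery cannot be run on the given input."""


class InsufficientDataError(DiscoveryError):
    """A group has fewer than two observations, so no variance exists."""


@dataclass(frozen=True)
class DiscoveryConfig:
    """The (test, alpha, mcc) triple naming a discovery operator.

    ``test="t"`` is the pooled-variance two-sided two-sample t-test;
    ``alpha`` is the threshold applied to adjusted p-values (strict ``<``);
    ``mcc`` is one of ``bh`` (Benjamini-Hochberg step-up), ``bonferroni``,
    or ``none``.
    """

    test: str = "t"
    alpha: float = 0.05
    mcc: str = "bh"

    def __post_init__(self) -> None:
        object.__setattr__(self, "test", self.test.lower())
        object.__setattr__(self, "mcc", self.mcc.lower())
        if self.test not in _VALID_TESTS:
            raise DiscoveryError(f"test must be one of {_VALID_TESTS}")
        if not (0.0 < self.alpha <= 1.0):
            raise DiscoveryError("alpha must lie in (0, 1]")
        if self.mcc not in _VALID_MCC:
            raise DiscoveryError(f"mcc must be one of {_VALID_MCC}")


@dataclass(frozen=True)
class FeatureTestResult:
    """Per-feature test outcome (statistic, dof, raw and adjusted p)."""

    feature_id: str
    t_stat: float
    df: float
    p_raw: float
    p_adj: float


def pooled_t(
    values_plus: np.ndarray, values_minus: np.ndarray
) -> tuple[float, int]:
    """Pooled-variance two-sample t-statistic and degrees of freedom.

    ``t = (mean_+ - mean_-) / (s_p * sqrt(1/n_+ + 1/n_-))`` where ``s_p``
    pools the unbiased per-group variances; ``df = n_+ + n_- - 2``.

    When the pooled variance is zero the continuity limit applies: equal
    means give ``t = 0`` and differing means give ``t = +/-inf``.
    """
    xp = np.asarray(values_plus, dtype=float)
    xm = np.asarray(values_minus, dtype=float)
    n_plus, n_minus = xp.size, xm.size
    if n_plus < 2 or n_minus < 2:
        raise InsufficientDataError(
            f"each group needs >= 2 observations (got {n_plus}, {n_minus})"
        )
    df = n_plus + n_minus - 2
    diff = xp.mean() - xm.mean()
    sp2 = ((n_plus - 1) * xp.var(ddof=1) + (n_minus - 1) * xm.var(ddof=1)) / df
    denom = np.sqrt(sp2 * (1.0 / n_plus + 1.0 / n_minus))
    if denom == 0.0:
        t = 0.0 if diff == 0.0 else float(np.copysign(np.inf, diff))
    else:
        t = float(diff / denom)
    return t, df


def two_sided_p(t_stat: float, df: float) -> float:
    """Two-sided p-value of *t_stat* under Student's t with *df* dof."""
    if df < 1:
        raise DiscoveryError("degrees of freedom must be >= 1")
    if np.isinf(t_stat):
        return 0.0
    return float(2.0 * stats.t.sf(abs(t_stat), df))


def adjust_p(p_raw: np.ndarray, mcc: str = "bh") -> np.ndarray:
    """Multiple-comparison-corrected p-values in the input order.

    ``bh`` applies the Benjamini-Hochberg step-up procedure; ``bonferroni``
    multiplies by the family size and caps at 1; ``none`` is the identity.
    """
    p = np.asarray(p_raw, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise DiscoveryError("p-values must lie in [0, 1]")
    mcc = mcc.lower()
    if mcc not in _VALID_MCC:
        raise DiscoveryError(f"mcc must be one of {_VALID_MCC}")
    if p.size == 0 or mcc == "none":
        return p.copy()
    method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[mcc]
    return multipletests(p, alpha=0.05, method=method)[1]


def _test_matrix(
    values: np.ndarray, positive_mask: np.ndarray, test: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-feature (t, df, p_raw) over all columns."""
    xp = values[positive_mask]
    xm = values[~positive_mask]
    n_plus, n_minus = xp.shape[0], xm.shape[0]
    diff = xp.mean(axis=0) - xm.mean(axis=0)
    vp = xp.var(axis=0, ddof=1)
    vm = xm.var(axis=0, ddof=1)
    if test == "t":
        df_pooled = n_plus + n_minus - 2
        sp2 = ((n_plus - 1) * vp + (n_minus - 1) * vm) / df_pooled
        denom = np.sqrt(sp2 * (1.0 / n_plus + 1.0 / n_minus))
        df = np.full(values.shape[1], float(df_pooled))
    else:  # welch
        se2 = vp / n_plus + vm / n_minus
        denom = np.sqrt(se2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (vp / n_plus) ** 2 / (n_plus - 1)
                + (vm / n_minus) ** 2 / (n_minus - 1)
            )
        df = np.where(np.isfinite(df), df, float(n_plus + n_minus - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    # zero-variance continuity limit
    zero = denom == 0.0
    t = np.where(zero & (diff == 0.0), 0.0, t)
    t = np.where(zero & (diff != 0.0), np.copysign(np.inf, diff), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return t, df, p


def _selected_mask(
    values: np.ndarray, positive_mask: np.ndarray, cfg: DiscoveryConfig
) -> np.ndarray:
    """Boolean biomarker mask; fast path used by the resampling loops."""
    _, _, p = _test_matrix(values, positive_mask, cfg.test)
    p_adj = adjust_p(p, cfg.mcc)
    return p_adj < cfg.alpha


def discover(
    dataset: LabeledDataset, cfg: DiscoveryConfig = DiscoveryConfig()
) -> tuple[BiomarkerSet, list[FeatureTestResult]]:
    """Run the discovery operator over every feature of *dataset*.

    Returns the proposed biomarker set ``{f : p_adj(f) < alpha}`` together
    with the full per-feature test results.  Deterministic for fixed input.

    Raises
    ------
    DiscoveryError
        if either outcome class has fewer than two subjects.
    """
    cc = dataset.class_counts()
    if cc.n_plus < 2 or cc.n_minus < 2:
        raise DiscoveryError(
            f"each class needs >= 2 subjects for the t-test, got {cc.as_tuple()}"
        )
    t, df, p = _test_matrix(dataset.values, dataset.positive_mask, cfg.test)
    p_adj = adjust_p(p, cfg.mcc)
    results = [
        FeatureTestResult(
            feature_id=fid,
            t_stat=float(t[j]),
            df=float(df[j]),
            p_raw=float(p[j]),
            p_adj=float(p_adj[j]),
        )
        for j, fid in enumerate(dataset.feature_ids)
    ]
    members = [
        fid for j, fid in enumerate(dataset.feature_ids) if p_adj[j] < cfg.alpha
    ]
    return BiomarkerSet(members), results
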