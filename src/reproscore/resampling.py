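"""Reproducibility-score estimators built on resampled dataset pairs.

The reproducibility score RS of a discovery operator BD on a dataset D is
the expected Jaccard overlap of the biomarker sets BD would return on two
comparable datasets (same per-class subject counts) drawn from the same
distribution.  RS cannot be computed from a single dataset, but it can be
bracketed:

* ``oRS`` (overbound) duplicates every subject and partitions the doubled
  multiset into two outcome-balanced full-size halves; the halves overlap,
  which inflates the expected Jaccard above RS.
* ``uRS`` (underbound) partitions D into two disjoint outcome-balanced
  half-size subsets; the smaller samples identify the true biomarkers less
  reliably, deflating the expected Jaccard below RS.
* ``bRS`` (bootstrap variant) draws two class-stratified full-size
  resamples with replacement; subjects recur even more often than under
  the doubling scheme, so bRS >= oRS >= RS in expectation — it is reported
  for comparison, not as a bound of choice.

Each estimator averages the Jaccard score over ``k`` independent
repetitions.  ``uRS`` on the full dataset doubles as a truth estimate
("RS-hat") for the reproducibility of its half-sized subsets, which is
what makes the bounds falsifiable on real data.  On synthetic data with a
known generating law, :func:`rs_star_monte_carlo` computes the true RS* by
drawing fully independent dataset pairs.

Randomness discipline: every estimator takes one root ``seed``; repetition
``i`` uses the child stream ``default_rng([seed, salt, i])`` with a fixed
per-construction salt, so increasing ``k`` extends a run without
reshuffling earlier repetitions and any single repetition is replayable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .datamodel import BiomarkerSet, ClassCounts, DatasetError, LabeledDataset
from .discovery import DiscoveryConfig, _selected_mask
from .synthetic import SyntheticSpec, generate

__all__ = [
    "EstimationError",
    "SplitPair",
    "ScoreEstimate",
    "jaccard",
    "doubled_balanced_partition",
    "disjoint_half_partition",
    "bootstrap_pair",
    "estimate",
    "rs_hat_half",
    "subset_curve",
    "rs_star_monte_carlo",
]

logger = logging.getLogger(__name__)

# fixed per-construction salts for child RNG streams
_SALT = {"oRS": 1, "uRS": 2, "bRS": 3, "subset-curve": 4, "RS-star": 5}

_METHODS = ("oRS", "uRS", "bRS")


class EstimationError(RuntimeError):
    """An estimator repetition failed; the repetition index is attached."""


@dataclass(frozen=True)
class SplitPair:
    """Two comparable datasets produced by one resampling construction."""

    d1: LabeledDataset
    d2: LabeledDataset
    construction: str  # doubled-disjoint | disjoint-half | bootstrap
    parent_counts: ClassCounts


@dataclass(frozen=True)
class ScoreEstimate:
    """Mean +/- sd of k per-repetition Jaccard scores.

    ``sd`` is the sample standard deviation (ddof=1) over the repetitions,
    0.0 when ``k == 1``.
    """

    method: str
    k: int
    per_iteration: tuple[float, ...]
    mean: float
    sd: float
    seed: int
    subset_size: int | None = None

    @classmethod
    def from_values(
        cls,
        method: str,
        values: Sequence[float],
        seed: int,
        subset_size: int | None = None,
    ) -> "ScoreEstimate":
        vals = tuple(float(v) for v in values)
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if len(vals) > 1 else 0.0
        return cls(
            method=method,
            k=len(vals),
            per_iteration=vals,
            mean=float(arr.mean()),
            sd=sd,
            seed=seed,
            subset_size=subset_size,
        )


def jaccard(a, b) -> float:
    """Intersection-over-union of two feature sets, in [0, 1].

    Symmetric; 1 iff the sets are equal and non-empty; 0 iff they are
    disjoint — including, by convention, when both are empty.
    """
    sa = frozenset(getattr(a, "members", a))
    sb = frozenset(getattr(b, "members", b))
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union


def _root_seed(seed: int | None) -> int:
    if seed is None:
        return int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    return int(seed)


def _child_rng(seed: int, salt: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([seed, salt, *extra])


# ---------------------------------------------------------------------------
# split constructions
# ---------------------------------------------------------------------------

def doubled_balanced_partition(
    dataset: LabeledDataset, rng: np.random.Generator
) -> SplitPair:
    """Duplicate every subject, split the doubled multiset into two halves.

    Each class's 2*n_c copy-slots are permuted and divided exactly in half,
    so both halves carry the parent's per-class counts and every parent
    subject appears exactly twice across the pair (possibly twice in one
    half).
    """
    idx1: list[np.ndarray] = []
    idx2: list[np.ndarray] = []
    for mask in (dataset.positive_mask, ~dataset.positive_mask):
        class_idx = np.flatnonzero(mask)
        doubled = np.repeat(class_idx, 2)
        perm = rng.permutation(doubled.size)
        shuffled = doubled[perm]
        idx1.append(shuffled[: class_idx.size])
        idx2.append(shuffled[class_idx.size :])
    return SplitPair(
        d1=dataset.take(np.concatenate(idx1)),
        d2=dataset.take(np.concatenate(idx2)),
        construction="doubled-disjoint",
        parent_counts=dataset.class_counts(),
    )


def disjoint_half_partition(
    dataset: LabeledDataset, rng: np.random.Generator
) -> SplitPair:
    """Split into two subject-disjoint, outcome-balanced half-size subsets.

    Per class, ``floor(n_c / 2)`` subjects go to each half; with an odd
    class count one subject sits out that repetition (a fresh random choice
    each time).  Requires at least 4 subjects per class so each half can
    still feed the t-test.
    """
    cc = dataset.class_counts()
    if min(cc.as_tuple()) < 4:
        raise DatasetError(
            f"disjoint halving needs >= 4 subjects per class, got {cc.as_tuple()}"
        )
    idx1: list[np.ndarray] = []
    idx2: list[np.ndarray] = []
    for mask in (dataset.positive_mask, ~dataset.positive_mask):
        class_idx = np.flatnonzero(mask)
        half = class_idx.size // 2
        perm = rng.permutation(class_idx)
        idx1.append(perm[:half])
        idx2.append(perm[half : 2 * half])
    return SplitPair(
        d1=dataset.take(np.concatenate(idx1)),
        d2=dataset.take(np.concatenate(idx2)),
        construction="disjoint-half",
        parent_counts=cc,
    )


def bootstrap_pair(
    dataset: LabeledDataset, rng: np.random.Generator
) -> SplitPair:
    """Two independent class-stratified full-size resamples with replacement."""
    halves: list[np.ndarray] = []
    for _ in range(2):
        parts = [
            rng.choice(np.flatnonzero(mask), size=mask.sum(), replace=True)
            for mask in (dataset.positive_mask, ~dataset.positive_mask)
        ]
        halves.append(np.concatenate(parts))
    return SplitPair(
        d1=dataset.take(halves[0]),
        d2=dataset.take(halves[1]),
        construction="bootstrap",
        parent_counts=dataset.class_counts(),
    )


_SPLITTERS: dict[str, Callable[[LabeledDataset, np.random.Generator], SplitPair]] = {
    "oRS": doubled_balanced_partition,
    "uRS": disjoint_half_partition,
    "bRS": bootstrap_pair,
}


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _pair_jaccard(
    pair: SplitPair,
    cfg: DiscoveryConfig,
    selector: Callable[[LabeledDataset], BiomarkerSet] | None,
) -> float:
    if selector is not None:
        return jaccard(selector(pair.d1), selector(pair.d2))
    m1 = _selected_mask(pair.d1.values, pair.d1.positive_mask, cfg)
    m2 = _selected_mask(pair.d2.values, pair.d2.positive_mask, cfg)
    union = int(np.logical_or(m1, m2).sum())
    if union == 0:
        return 0.0
    return int(np.logical_and(m1, m2).sum()) / union


def estimate(
    dataset: LabeledDataset,
    cfg: DiscoveryConfig,
    method: str = "oRS",
    k: int = 50,
    seed: int | None = None,
    selector: Callable[[LabeledDataset], BiomarkerSet] | None = None,
) -> ScoreEstimate:
    """Average Jaccard overlap of discoveries over k resampled pairs.

    *method* selects the split construction: ``oRS`` (doubling overbound),
    ``uRS`` (disjoint-halving underbound) or ``bRS`` (bootstrap variant).
    *selector*, when given, replaces the discovery operator (useful for
    testing); otherwise each half is mined with ``discover(half, cfg)``.

    Reproducible: the same (dataset, cfg, method, k, seed) reproduces the
    per-repetition values bit for bit.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    canonical = {m.lower(): m for m in _METHODS}.get(method.lower())
    if canonical is None:
        raise ValueError(f"method must be one of {_METHODS}")
    splitter = _SPLITTERS[canonical]
    salt = _SALT[canonical]
    seed = _root_seed(seed)
    values = np.empty(k)
    for rep in range(k):
        try:
            rng = _child_rng(seed, salt, rep)
            pair = splitter(dataset, rng)
            values[rep] = _pair_jaccard(pair, cfg, selector)
        except Exception as exc:  # noqa: BLE001 - annotate with repetition
            raise EstimationError(
                f"{canonical} repetition {rep} (seed=[{seed},{salt},{rep}]): {exc}"
            ) from exc
        logger.debug(
            "%s rep=%d child_seed=[%d,%d,%d] jaccard=%.4f",
            canonical, rep, seed, salt, rep, values[rep],
        )
    return ScoreEstimate.from_values(canonical, values, seed)


def rs_hat_half(
    dataset: LabeledDataset,
    cfg: DiscoveryConfig,
    k: int = 50,
    seed: int | None = None,
    selector: Callable[[LabeledDataset], BiomarkerSet] | None = None,
) -> ScoreEstimate:
    """uRS on the full dataset, tagged as the truth estimate "RS-hat".

    The disjoint halves of the full dataset are genuine independent
    same-size samples of the half-sized sampling regime, so this value is
    a meaningful reproducibility estimate for half-sized subsets of
    *dataset* and can be compared against oRS/uRS computed on such a
    subset.  Identical to ``estimate(dataset, cfg, "uRS", k, seed)`` up to
    the method tag.
    """
    est = estimate(dataset, cfg, "uRS", k, seed, selector)
    return replace(est, method="RS-hat")


def _largest_remainder_quota(cc: ClassCounts, s: int) -> tuple[int, int]:
    """Per-class counts for a size-s subset, proportional to the parent."""
    exact = (s * cc.n_plus / cc.n, s * cc.n_minus / cc.n)
    base = [int(np.floor(q)) for q in exact]
    rem = s - sum(base)
    fracs = [exact[i] - base[i] for i in range(2)]
    # distribute leftovers by largest fractional part; tie -> larger class,
    # then the positive class
    order = sorted(
        range(2),
        key=lambda i: (fracs[i], cc.as_tuple()[i], i == 0),
        reverse=True,
    )
    for i in order[:rem]:
        base[i] += 1
    return base[0], base[1]


def subset_curve(
    dataset: LabeledDataset,
    cfg: DiscoveryConfig,
    sizes: Sequence[int],
    k: int = 20,
    seed: int | None = None,
    selector: Callable[[LabeledDataset], BiomarkerSet] | None = None,
) -> list[ScoreEstimate]:
    """Reproducibility versus subset size.

    For each requested size ``s <= n/2``, draws ``k`` pairs of disjoint
    outcome-proportional size-s subsets, mines each member, and records
    the Jaccard overlap.  Sizes that cannot host two disjoint subsets with
    at least two subjects per class are skipped with a warning.  On data
    with genuine signal the curve is expected to rise with ``s`` — larger
    samples pin down the true biomarkers more reliably.
    """
    cc = dataset.class_counts()
    seed = _root_seed(seed)
    out: list[ScoreEstimate] = []
    pos_idx = np.flatnonzero(dataset.positive_mask)
    neg_idx = np.flatnonzero(~dataset.positive_mask)
    for s in sizes:
        q_plus, q_minus = _largest_remainder_quota(cc, int(s))
        if (
            q_plus < 2
            or q_minus < 2
            or 2 * q_plus > cc.n_plus
            or 2 * q_minus > cc.n_minus
        ):
            warnings.warn(
                f"subset size {s} (quota {q_plus}+/{q_minus}-) infeasible for "
                f"class counts {cc.as_tuple()}; skipped",
                stacklevel=2,
            )
            continue
        values = np.empty(k)
        for rep in range(k):
            rng = _child_rng(seed, _SALT["subset-curve"], int(s), rep)
            perm_p = rng.permutation(pos_idx)
            perm_m = rng.permutation(neg_idx)
            i1 = np.concatenate([perm_p[:q_plus], perm_m[:q_minus]])
            i2 = np.concatenate(
                [perm_p[q_plus : 2 * q_plus], perm_m[q_minus : 2 * q_minus]]
            )
            pair = SplitPair(
                d1=dataset.take(i1),
                d2=dataset.take(i2),
                construction="disjoint-half",
                parent_counts=cc,
            )
            values[rep] = _pair_jaccard(pair, cfg, selector)
        out.append(
            ScoreEstimate.from_values(
                "subset-curve-point", values, seed, subset_size=int(s)
            )
        )
    return out


def rs_star_monte_carlo(
    spec: SyntheticSpec,
    cfg: DiscoveryConfig,
    k: int = 50,
    seed: int | None = None,
    selector: Callable[[LabeledDataset], BiomarkerSet] | None = None,
) -> ScoreEstimate:
    """Monte-Carlo ground truth RS* under a known generating distribution.

    Each repetition draws two fully independent datasets from *spec* and
    records the Jaccard overlap of their discovered sets.  Available only
    when the generating law is known (synthetic data); used to validate
    that uRS and oRS really bracket the truth.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seed = _root_seed(seed)
    values = np.empty(k)
    for rep in range(k):
        rng = _child_rng(seed, _SALT["RS-star"], rep)
        d1 = generate(spec, rng)
        d2 = generate(spec, rng)
        pair = SplitPair(
            d1=d1, d2=d2, construction="independent",
            parent_counts=d1.class_counts(),
        )
        values[rep] = _pair_jaccard(pair, cfg, selector)
    return ScoreEstimate.from_values("RS-star", values, seed)
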