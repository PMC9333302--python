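"""Core containers for two-class labeled omics matrices.

A :class:`LabeledDataset` holds an ``n`` subjects x ``r`` features value
matrix together with a binary outcome per subject.  Values are either all
continuous (expression-like) or all genotype-encoded minor-allele counts in
``{0, 1, 2}``.  Helpers convert raw two-character genotype strings to
minor-allele counts and derive a binary outcome from survival data by
splitting at the median survival time.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "DatasetError",
    "MalformedGenotypeError",
    "GenotypeParseError",
    "EmptyCohortError",
    "ClassCounts",
    "BiomarkerSet",
    "LabeledDataset",
    "encode_genotypes",
    "class_counts",
    "dichotomize_survival",
]

CONTINUOUS = "continuous"
GENOTYPE = "genotype"
_FEATURE_KINDS = (CONTINUOUS, GENOTYPE)


class DatasetError(ValueError):
    """A dataset violates a structural invariant."""


class MalformedGenotypeError(DatasetError):
    """A genotype column uses more than two allele symbols."""


class GenotypeParseError(DatasetError):
    """A cell is neither a two-character genotype nor an integer in {0,1,2}."""


class EmptyCohortError(DatasetError):
    """Survival dichotomization removed every subject."""


@dataclass(frozen=True)
class ClassCounts:
    """Subject counts per outcome class, ``[n_+, n_-]``."""

    n_plus: int
    n_minus: int

    def __post_init__(self) -> None:
        if self.n_plus < 0 or self.n_minus < 0:
            raise DatasetError("class counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.n_plus + self.n_minus

    def as_tuple(self) -> tuple[int, int]:
        return (self.n_plus, self.n_minus)


@dataclass(frozen=True)
class BiomarkerSet:
    """An unordered set of feature identifiers proposed as biomarkers."""

    members: frozenset[str]

    def __init__(self, members: Iterable[str] = ()) -> None:
        object.__setattr__(self, "members", frozenset(members))

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def __contains__(self, item: object) -> bool:
        return item in self.members

    def __or__(self, other: "BiomarkerSet") -> "BiomarkerSet":
        return BiomarkerSet(self.members | other.members)

    def __and__(self, other: "BiomarkerSet") -> "BiomarkerSet":
        return BiomarkerSet(self.members & other.members)


class LabeledDataset:
    """An ``n x r`` value matrix with one binary outcome per subject.

    Parameters
    ----------
    values
        Real-valued matrix, subjects as rows.  Genotype-encoded matrices
        must contain only ``{0, 1, 2}``.
    outcomes
        One label per subject; exactly two distinct labels must occur.
    feature_ids, subject_ids
        Optional identifiers; generated (``f000…`` / ``s000…``) when omitted.
    positive_label
        Which outcome label plays the "+" (case) role.  Defaults to the
        lexicographically larger label string; with a two-sided test the
        choice does not affect discovery.
    feature_kind
        ``"continuous"`` or ``"genotype"``.
    """

    def __init__(
        self,
        values: np.ndarray,
        outcomes: Sequence,
        feature_ids: Sequence[str] | None = None,
        subject_ids: Sequence[str] | None = None,
        positive_label: object | None = None,
        feature_kind: str = CONTINUOUS,
        _allow_duplicate_subjects: bool = False,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise DatasetError(f"values must be 2-D, got shape {values.shape}")
        n, r = values.shape
        outcomes = np.asarray(outcomes, dtype=object)
        if outcomes.shape != (n,):
            raise DatasetError(
                f"outcomes length {outcomes.shape} does not match {n} subjects"
            )

        if feature_ids is None:
            feature_ids = tuple(f"f{i:04d}" for i in range(r))
        else:
            feature_ids = tuple(str(f) for f in feature_ids)
        if len(feature_ids) != r:
            raise DatasetError("feature_ids length does not match column count")
        if len(set(feature_ids)) != r:
            raise DatasetError("feature_ids must be unique")

        if subject_ids is None:
            subject_ids = tuple(f"s{i:04d}" for i in range(n))
        else:
            subject_ids = tuple(str(s) for s in subject_ids)
        if len(subject_ids) != n:
            raise DatasetError("subject_ids length does not match row count")
        if not _allow_duplicate_subjects and len(set(subject_ids)) != n:
            raise DatasetError("subject_ids must be unique")

        labels = sorted(set(outcomes), key=str)
        if len(labels) != 2:
            raise DatasetError(
                f"outcomes must contain exactly two distinct labels, got {labels}"
            )
        if positive_label is None:
            positive_label = labels[1]  # lexicographically larger label
        if positive_label not in labels:
            raise DatasetError(
                f"positive label {positive_label!r} not among outcomes {labels}"
            )

        if feature_kind not in _FEATURE_KINDS:
            raise DatasetError(f"feature_kind must be one of {_FEATURE_KINDS}")
        if feature_kind == GENOTYPE:
            if not np.isin(values, (0.0, 1.0, 2.0)).all():
                raise DatasetError("genotype-encoded values must lie in {0, 1, 2}")
        elif not np.isfinite(values).all():
            raise DatasetError(
                "values contain missing or non-finite entries; drop or impute "
                "them before constructing the dataset"
            )

        self.values = values
        self.outcomes = outcomes
        self.feature_ids = feature_ids
        self.subject_ids = subject_ids
        self.positive_label = positive_label
        self.feature_kind = feature_kind
        self.positive_mask = np.fromiter(
            (o == positive_label for o in outcomes), dtype=bool, count=n
        )
        n_plus = int(self.positive_mask.sum())
        if n_plus == 0 or n_plus == n:
            raise DatasetError("each outcome class needs at least one subject")

    # -- basic geometry ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def r(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> ClassCounts:
        n_plus = int(self.positive_mask.sum())
        return ClassCounts(n_plus=n_plus, n_minus=self.n - n_plus)

    # -- resampling support ------------------------------------------------
    def take(self, indices: Sequence[int]) -> "LabeledDataset":
        """Row-subset (possibly with repeats) preserving subject identity.

        Used by the resampling constructions, where a subject may appear
        more than once in a resampled dataset.
        """
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            self.values[idx],
            self.outcomes[idx],
            feature_ids=self.feature_ids,
            subject_ids=[self.subject_ids[i] for i in idx],
            positive_label=self.positive_label,
            feature_kind=self.feature_kind,
            _allow_duplicate_subjects=True,
        )

    def __repr__(self) -> str:
        cc = self.class_counts()
        return (
            f"LabeledDataset(n={self.n} [{cc.n_plus}+, {cc.n_minus}-], "
            f"r={self.r}, kind={self.feature_kind!r})"
        )


def class_counts(dataset: LabeledDataset) -> ClassCounts:
    """Exact (+, -) subject counts of *dataset*."""
    return dataset.class_counts()


def _is_numeric_012(token: object) -> bool:
    try:
        v = float(token)
    except (TypeError, ValueError):
        return False
    return v in (0.0, 1.0, 2.0)


def encode_genotypes(raw) -> np.ndarray:
    """Convert two-allele genotype strings to minor-allele counts.

    Each column is treated independently: the minor allele is the symbol
    with the lower total count over all subjects (a 50/50 tie goes to the
    lexicographically later symbol), and each cell becomes the number of
    minor-allele copies it carries, giving values in ``{0, 1, 2}``.
    Columns that already hold numbers in ``{0, 1, 2}`` pass through
    unchanged, so the transformation is idempotent.

    Raises
    ------
    MalformedGenotypeError
        if a column mixes more than two allele symbols.
    GenotypeParseError
        if a cell is neither a two-character genotype nor a number in
        ``{0, 1, 2}``.
    """
    arr = np.asarray(raw, dtype=object)
    if arr.ndim == 1:
        arr = arr[:, None]
    n, r = arr.shape
    out = np.empty((n, r), dtype=float)
    for j in range(r):
        col = arr[:, j]
        if all(_is_numeric_012(v) for v in col):
            out[:, j] = [float(v) for v in col]
            continue
        tokens = []
        for v in col:
            s = str(v).strip()
            if len(s) != 2:
                raise GenotypeParseError(
                    f"column {j}: token {v!r} is not a two-character genotype"
                )
            tokens.append(s)
        allele_counts: Counter[str] = Counter()
        for s in tokens:
            allele_counts.update(s)
        alleles = sorted(allele_counts)
        if len(alleles) > 2:
            raise MalformedGenotypeError(
                f"column {j}: more than two allele symbols {alleles}"
            )
        if len(alleles) == 1:
            # monomorphic: zero copies of the (absent) minor allele
            out[:, j] = 0.0
            continue
        a, b = alleles
        if allele_counts[a] < allele_counts[b]:
            minor = a
        elif allele_counts[b] < allele_counts[a]:
            minor = b
        else:
            minor = b  # tie: lexicographically later symbol is "minor"
        out[:, j] = [s.count(minor) for s in tokens]
    return out


def dichotomize_survival(
    times: Sequence[float],
    events: Sequence[bool],
    positive_label: str = "+",
    negative_label: str = "-",
) -> tuple[np.ndarray, np.ndarray]:
    """Turn survival data into a binary long/short-survival outcome.

    The median survival time is computed once over all input times.
    Subjects surviving at least the median are labeled long-survival
    (positive) whether or not they were later censored; subjects with an
    observed event before the median are labeled short-survival (negative);
    subjects censored before the median are removed, since their class is
    unknown.

    Returns
    -------
    outcomes : ndarray of labels for the retained subjects (input order)
    retained : boolean mask over the input subjects
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise DatasetError("times and events must be equal-length 1-D arrays")
    if t.size == 0:
        raise EmptyCohortError("no subjects supplied")
    if (t < 0).any():
        raise DatasetError("survival times must be nonnegative")
    med = float(np.median(t))
    long_surv = t >= med
    short_surv = (~long_surv) & e
    retained = long_surv | short_surv
    if not retained.any():
        raise EmptyCohortError("all subjects censored before the median time")
    outcomes = np.where(long_surv, positive_label, negative_label)[retained]
    return outcomes.astype(object), retained
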