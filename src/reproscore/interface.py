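"""Dataset readers/writers, the run report, and the evaluation driver.

Input is a delimited text matrix with a header: one row per subject (or
one per feature with ``orientation="features-as-rows"``), a first column
of subject identifiers, and one outcome column holding exactly two labels.
Genotype matrices may hold two-character genotype strings or minor-allele
counts in {0, 1, 2}.

The evaluation driver runs the full-data discovery plus the requested
reproducibility estimators and packs everything into a :class:`RunReport`
serializable as JSON (machine-readable; schema shipped as
``report_schema.json``) or TSV (one row per estimate).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import DatasetError, LabeledDataset, encode_genotypes
from .discovery import DiscoveryConfig, discover
from .resampling import ScoreEstimate, estimate, subset_curve

__all__ = [
    "read_dataset",
    "write_dataset",
    "RunReport",
    "evaluate",
    "report_schema",
]

logger = logging.getLogger(__name__)


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".txt", ".tab") else ","


def read_dataset(
    path: str | Path,
    outcome: str = "outcome",
    positive_label: str | None = None,
    orientation: str = "subjects-as-rows",
    delimiter: str | None = None,
    genotype: bool = False,
    drop_missing: bool = False,
) -> LabeledDataset:
    """Read a labeled matrix from delimited text.

    Parameters
    ----------
    outcome
        Name of the outcome column (or row, in features-as-rows
        orientation).
    positive_label
        Which of the two outcome labels is the "+" class; defaults to the
        lexicographically larger label.
    genotype
        Route values through minor-allele-count encoding.
    drop_missing
        Drop (and log) any feature column containing a missing value
        instead of rejecting the dataset.
    """
    path = Path(path)
    if not path.exists():
        raise DatasetError(f"input file not found: {path}")
    sep = _infer_delimiter(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=object)
    except pd.errors.ParserError as exc:
        raise DatasetError(f"could not parse {path}: {exc}") from exc
    if orientation == "features-as-rows":
        df = df.T
    elif orientation != "subjects-as-rows":
        raise DatasetError(
            "orientation must be 'subjects-as-rows' or 'features-as-rows'"
        )
    if outcome not in df.columns:
        raise DatasetError(
            f"outcome column {outcome!r} not found; columns start with "
            f"{list(df.columns[:5])}"
        )
    labels = df.pop(outcome).astype(str)
    subject_ids = [str(s) for s in df.index]
    feature_ids = [str(c) for c in df.columns]

    if genotype:
        values = encode_genotypes(df.to_numpy(dtype=object))
        kind = "genotype"
    else:
        try:
            # element-wise float() parse: correctly rounded, so written
            # datasets read back bit-identical
            values = df.to_numpy(dtype=object).astype(float)
        except (ValueError, TypeError) as exc:
            raise DatasetError(
                f"non-numeric feature values in {path} "
                f"(use genotype=True for genotype strings): {exc}"
            ) from exc
        kind = "continuous"
        missing = ~np.isfinite(values)
        if missing.any():
            if not drop_missing:
                raise DatasetError(
                    f"{int(missing.sum())} missing value(s) in {path}; pass "
                    "drop_missing=True to drop affected features"
                )
            keep = ~missing.any(axis=0)
            dropped = [f for f, k in zip(feature_ids, keep) if not k]
            logger.warning(
                "dropping %d feature(s) with missing values: %s",
                len(dropped), dropped[:10],
            )
            values = values[:, keep]
            feature_ids = [f for f, k in zip(feature_ids, keep) if k]

    return LabeledDataset(
        values,
        labels.to_numpy(dtype=object),
        feature_ids=feature_ids,
        subject_ids=subject_ids,
        positive_label=positive_label,
        feature_kind=kind,
    )


def write_dataset(
    dataset: LabeledDataset,
    path: str | Path,
    outcome: str = "outcome",
    delimiter: str | None = None,
) -> None:
    """Write a dataset as delimited text (full float precision, round-trips)."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.DataFrame(
        dataset.values,
        index=pd.Index(dataset.subject_ids, name="subject"),
        columns=list(dataset.feature_ids),
    )
    df[outcome] = list(dataset.outcomes)
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# run report
# ---------------------------------------------------------------------------

def _estimate_dict(est: ScoreEstimate) -> dict:
    d = {
        "method": est.method,
        "k": est.k,
        "mean": est.mean,
        "sd": est.sd,
        "seed": est.seed,
        "per_iteration": list(est.per_iteration),
    }
    if est.subset_size is not None:
        d["subset_size"] = est.subset_size
    return d


@dataclass
class RunReport:
    """Everything one evaluation run produced, regenerable from its inputs."""

    dataset: dict
    config: dict
    n_biomarkers_full: int
    estimates: list[dict]
    seed: int
    timestamp: str = ""
    version: str = __version__

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "config": self.config,
            "n_biomarkers_full": self.n_biomarkers_full,
            "estimates": self.estimates,
            "seed": self.seed,
            "timestamp": self.timestamp,
            "version": self.version,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tsv(self, path: str | Path | None = None) -> str:
        """One row per estimate, echoing the mean +/- sd presentation."""
        rows = []
        for est in self.estimates:
            rows.append(
                {
                    "method": est["method"],
                    "subset_size": est.get("subset_size", ""),
                    "k": est["k"],
                    "mean": f"{est['mean']:.4f}",
                    "sd": f"{est['sd']:.4f}",
                    "mean_pm_sd": f"{est['mean']:.3f} ± {est['sd']:.3f}",
                }
            )
        df = pd.DataFrame(
            rows,
            columns=["method", "subset_size", "k", "mean", "sd", "mean_pm_sd"],
        )
        text = df.to_csv(sep="\t", index=False)
        if path is not None:
            Path(path).write_text(text)
        return text


def report_schema() -> dict:
    """The JSON schema the report serialization conforms to."""
    with resources.files("reproscore").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def evaluate(
    dataset: LabeledDataset,
    cfg: DiscoveryConfig = DiscoveryConfig(),
    methods: Sequence[str] = ("oRS", "uRS"),
    k: int = 50,
    subset_sizes: Sequence[int] | None = None,
    curve_k: int = 20,
    seed: int | None = None,
) -> RunReport:
    """Run discovery plus the requested reproducibility estimators."""
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    if cfg.alpha == 1.0:
        logger.warning(
            "alpha = 1.0 declares every testable feature a biomarker; the "
            "resulting score is trivially 1 and carries no information"
        )
    full_set, _ = discover(dataset, cfg)
    estimates = [
        _estimate_dict(estimate(dataset, cfg, method=m, k=k, seed=seed))
        for m in methods
    ]
    if subset_sizes:
        estimates.extend(
            _estimate_dict(e)
            for e in subset_curve(dataset, cfg, subset_sizes, k=curve_k, seed=seed)
        )
    cc = dataset.class_counts()
    return RunReport(
        dataset={
            "n": dataset.n,
            "n_plus": cc.n_plus,
            "n_minus": cc.n_minus,
            "r": dataset.r,
            "feature_kind": dataset.feature_kind,
            "positive_label": str(dataset.positive_label),
        },
        config={"test": cfg.test, "alpha": cfg.alpha, "mcc": cfg.mcc},
        n_biomarkers_full=len(full_set),
        estimates=estimates,
        seed=seed,
    )
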