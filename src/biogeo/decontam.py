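"""Contamination and noise control for amplicon count tables.

Three stages, applied in order: (1) rarefaction to a common library size by
subsampling reads without replacement (samples below the target depth are
dropped, with a logged warning); (2) removal of taxa whose relative
abundance stays below a threshold in every sample; (3) prevalence-based
contaminant scoring against negative controls, comparing each taxon's
detection frequency in controls versus biological samples.

The scorer is a one-sided test that control prevalence exceeds biological
prevalence: chi-squared with continuity correction on the 2x2
presence/absence table, falling back to the exact hypergeometric (Fisher)
test whenever any expected cell is below 5. A taxon is flagged when its
score falls below the threshold (default 0.5, the conventional cut between
true residents and contaminants) and its control prevalence is at least its
biological prevalence — the direction guard keeps genuine taxa sparsely
detected in controls from being flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ParameterError, ValidationError
from .io import CountTable, SampleTable

logger = logging.getLogger(__name__)


@dataclass
class DecontamConfig:
    target_depth: int = 10_000
    rare_threshold: float = 0.001
    score_threshold: float = 0.5
    mode: str = "decontam"  # or "strict": drop every taxon detected in controls
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_depth < 1:
            raise ParameterError("target_depth must be >= 1")
        for name in ("rare_threshold", "score_threshold"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ParameterError(f"{name} must be in (0, 1), got {value}")
        if self.mode not in ("decontam", "strict"):
            raise ParameterError(f"unknown mode {self.mode!r}")


class Rarefier(BaseEstimator, TransformerMixin):
    """Subsample each sample (column) to a fixed depth without replacement.

    Stateless transformer over taxa x samples integer arrays; columns whose
    total is below ``depth`` are dropped. ``kept_samples_`` records the
    surviving column indices after :meth:`transform`.
    """

    def __init__(self, depth: int = 10_000, seed: int = 0):
        self.depth = depth
        self.seed = seed

    def fit(self, X, y=None):
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        X = np.asarray(X)
        rng = np.random.default_rng(self.seed)
        totals = X.sum(axis=0)
        keep = np.flatnonzero(totals >= self.depth)
        if keep.size == 0:
            raise ValidationError(f"all samples are below depth {self.depth}")
        dropped = X.shape[1] - keep.size
        if dropped:
            logger.warning("rarefy: dropped %d sample(s) below depth %d", dropped, self.depth)
        out = np.zeros((X.shape[0], keep.size), dtype=np.int64)
        for j, col in enumerate(keep):
            if totals[col] == self.depth:
                out[:, j] = X[:, col]
            else:
                out[:, j] = rng.multivariate_hypergeometric(
                    X[:, col], self.depth, method="marginals"
                )
        self.kept_samples_ = keep
        return out


class RareTaxonFilter(BaseEstimator, TransformerMixin):
    """Drop taxa (rows) whose relative abundance is below ``threshold`` in
    every sample; a taxon reaching the threshold anywhere is retained."""

    def __init__(self, threshold: float = 0.001):
        self.threshold = threshold

    def fit(self, X, y=None):
        if not 0 < self.threshold < 1:
            raise ParameterError("threshold must be in (0, 1)")
        X = np.asarray(X, dtype=float)
        totals = X.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(totals > 0, X / totals, 0.0)
        self.keep_ = (rel >= self.threshold).any(axis=1)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X)[self.keep_]

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X)


class PrevalenceContaminantDetector(BaseEstimator):
    """Score taxa as contaminants from negative-control prevalence.

    ``fit(X, y)`` takes taxa x samples counts ``X`` and a boolean vector
    ``y`` marking negative-control samples; presence is ``count > 0``.
    Fitted attributes: ``score_``, ``prevalence_control_``,
    ``prevalence_sample_``, ``is_contaminant_``.
    """

    def __init__(self, score_threshold: float = 0.5):
        self.score_threshold = score_threshold

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X)
        is_control = np.asarray(y, dtype=bool)
        n_control = int(is_control.sum())
        n_sample = int((~is_control).sum())
        if n_control == 0 or n_sample == 0:
            raise ValidationError("need at least one control and one biological sample")
        present = X > 0
        a = present[:, is_control].sum(axis=1)  # controls with taxon
        c = present[:, ~is_control].sum(axis=1)  # biological samples with taxon
        self.prevalence_control_ = a / n_control
        self.prevalence_sample_ = c / n_sample
        scores = np.ones(X.shape[0])
        for i in range(X.shape[0]):
            scores[i] = _one_sided_prevalence_p(
                int(a[i]), n_control - int(a[i]), int(c[i]), n_sample - int(c[i])
            )
        self.score_ = scores
        self.is_contaminant_ = (scores < self.score_threshold) & (
            self.prevalence_control_ >= self.prevalence_sample_
        )
        return self


def _one_sided_prevalence_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided p that control prevalence (a/(a+b)) exceeds biological
    prevalence (c/(c+d)); 1.0 when there is no prevalence excess."""
    prev_control = a / (a + b)
    prev_sample = c / (c + d)
    if prev_control <= prev_sample:
        return 1.0
    table = np.array([[a, b], [c, d]])
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected < 5).any():
        return float(stats.fisher_exact(table, alternative="greater")[1])
    p_two = stats.chi2_contingency(table, correction=True)[1]
    return float(p_two / 2.0)


# ---------------------------------------------------------------------------
# Domain-level operations


def rarefy(table: CountTable, depth: int = 10_000, seed: int = 0) -> CountTable:
    """Rarefy every sample to exactly ``depth`` reads (drop shallower ones)."""
    rarefier = Rarefier(depth=depth, seed=seed)
    counts = rarefier.transform(table.counts)
    kept = [table.sample_ids[j] for j in rarefier.kept_samples_]
    return CountTable(list(table.taxon_ids), kept, counts)


def filter_rare(table: CountTable, threshold: float = 0.001) -> CountTable:
    """Discard taxa below ``threshold`` relative abundance in all samples."""
    filt = RareTaxonFilter(threshold=threshold).fit(table.counts)
    kept = [t for t, k in zip(table.taxon_ids, filt.keep_) if k]
    return CountTable(kept, list(table.sample_ids), table.counts[filt.keep_])


@dataclass
class ContaminantReport:
    """Per-taxon contaminant scores against negative controls."""

    table: pd.DataFrame  # taxon_id, prevalence_in_controls, prevalence_in_samples, score, is_contaminant

    @property
    def contaminants(self) -> list[str]:
        return list(self.table.loc[self.table["is_contaminant"], "taxon_id"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def score_contaminants(
    table: CountTable, samples: SampleTable, score_threshold: float = 0.5
) -> ContaminantReport:
    """Prevalence-mode contaminant scoring of every taxon."""
    is_control = np.array(
        [samples.data.loc[s, "organ"] == "negative_control" for s in table.sample_ids]
    )
    detector = PrevalenceContaminantDetector(score_threshold=score_threshold)
    detector.fit(table.counts, is_control)
    report = pd.DataFrame(
        {
            "taxon_id": table.taxon_ids,
            "prevalence_in_controls": detector.prevalence_control_,
            "prevalence_in_samples": detector.prevalence_sample_,
            "score": detector.score_,
            "is_contaminant": detector.is_contaminant_,
        }
    )
    return ContaminantReport(report)


def remove_contaminants(
    table: CountTable, samples: SampleTable, report: ContaminantReport, mode: str = "decontam"
) -> CountTable:
    """Drop flagged taxa and negative-control samples from the table.

    ``mode='strict'`` removes every taxon detected in any control instead of
    only the score-flagged ones.
    """
    missing = set(table.taxon_ids) - set(report.table["taxon_id"])
    if missing:
        raise ValidationError(f"report does not cover taxa: {sorted(missing)[:5]}")
    if mode == "strict":
        flagged = set(
            report.table.loc[report.table["prevalence_in_controls"] > 0, "taxon_id"]
        )
    else:
        flagged = set(report.contaminants)
    keep_taxa = [t for t in table.taxon_ids if t not in flagged]
    keep_samples = [
        s for s in table.sample_ids if samples.data.loc[s, "organ"] != "negative_control"
    ]
    idx_t = [table.taxon_ids.index(t) for t in keep_taxa]
    idx_s = [table.sample_ids.index(s) for s in keep_samples]
    return CountTable(keep_taxa, keep_samples, table.counts[np.ix_(idx_t, idx_s)])


def decontaminate(
    table: CountTable, samples: SampleTable, config: DecontamConfig | None = None
) -> tuple[CountTable, ContaminantReport]:
    """Full pipeline: rarefy -> rare-taxon filter -> score -> remove."""
    config = config or DecontamConfig()
    rarefied = rarefy(table, depth=config.target_depth, seed=config.seed)
    filtered = filter_rare(rarefied, threshold=config.rare_threshold)
    report = score_contaminants(filtered, samples, score_threshold=config.score_threshold)
    cleaned = remove_contaminants(filtered, samples, report, mode=config.mode)
    return cleaned, report
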