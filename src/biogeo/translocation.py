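"""Inter-organ translocation analysis: presence calling, species collapse,
organ prevalence, inter-organ positive-correlation ratios, and
intra-individual core-species co-existence.

Presence: a taxon is present in a (subject, organ) when its relative
abundance strictly exceeds the threshold (default 0.1%) in at least one of
the subject's samples from that organ. Prevalence per organ is the fraction
of subjects with presence; "prevalent" means strictly above the cutoff
(default 50%). Core species: a species is core for a subject within an
organ group when at least one of its ASVs is present in every organ of the
group for that subject; two or more such ASVs upgrade the call to
``core_multi_asv``. Inter-organ positive-correlation ratios count, among
prevalent species, those whose subject-level relative abundance correlates
positively (p below alpha, uncorrected) between the two organs by the
configured methods (Spearman, partial Spearman adjusting for age/sex/BMI,
Pearson).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .errors import ParameterError, ValidationError
from .io import CountTable, SampleTable, TaxonomyTable

logger = logging.getLogger(__name__)


@dataclass
class InterOrganConfig:
    presence_threshold: float = 0.001  # strict >
    prevalence_cutoff: float = 0.5  # strict >
    correlation_alpha: float = 0.05
    correlation_methods: tuple[str, ...] = ("spearman", "partial_spearman", "pearson")
    combine: str = "any"  # or "all"
    min_paired_subjects: int = 5
    organ_groups: dict[str, set[str]] = field(
        default_factory=lambda: {
            "upper_GI": {"esophagus", "stomach"},
            "lower_GI": {"small intestine", "appendix", "large intestine"},
        }
    )

    def __post_init__(self) -> None:
        for name in ("presence_threshold", "prevalence_cutoff"):
            if not 0 < getattr(self, name) < 1:
                raise ParameterError(f"{name} must be in (0, 1)")
        unknown = set(self.correlation_methods) - {"spearman", "partial_spearman", "pearson"}
        if unknown:
            raise ParameterError(f"unknown correlation methods: {sorted(unknown)}")
        if self.combine not in ("any", "all"):
            raise ParameterError("combine must be 'any' or 'all'")


def call_presence(
    table: CountTable,
    samples: SampleTable,
    threshold: float = 0.001,
    require_all_samples: bool = False,
) -> xr.DataArray:
    """Boolean presence tensor over (taxon, subject, organ).

    Present when relative abundance strictly exceeds ``threshold`` in at
    least one sample of the subject-organ (or in all of them when
    ``require_all_samples``).
    """
    if not 0 < threshold < 1:
        raise ParameterError("threshold must be in (0, 1)")
    meta = samples.data
    rel = table.relative_abundance()
    biological = [
        s for s in table.sample_ids if meta.loc[s, "organ"] != "negative_control"
    ]
    subjects = sorted(meta.loc[biological, "subject_id"].unique())
    organs = sorted(meta.loc[biological, "organ"].unique())
    presence = np.zeros((table.n_taxa, len(subjects), len(organs)), dtype=bool)
    col = {s: j for j, s in enumerate(table.sample_ids)}
    for si, subj in enumerate(subjects):
        for oi, organ in enumerate(organs):
            ids = [
                s
                for s in biological
                if meta.loc[s, "subject_id"] == subj and meta.loc[s, "organ"] == organ
            ]
            if not ids:
                continue
            above = rel[:, [col[s] for s in ids]] > threshold
            presence[:, si, oi] = above.all(axis=1) if require_all_samples else above.any(axis=1)
    return xr.DataArray(
        presence,
        dims=("taxon", "subject", "organ"),
        coords={"taxon": table.taxon_ids, "subject": subjects, "organ": organs},
    )


def collapse_species(
    presence: xr.DataArray, taxonomy: TaxonomyTable
) -> tuple[xr.DataArray, xr.DataArray]:
    """Collapse an ASV presence tensor to species level.

    Species presence is the OR over member ASVs; multiplicity counts the
    member ASVs meeting the presence criterion. ASVs with an empty species
    rank are retained as their own pseudo-species keyed by ASV id (logged).
    """
    members: dict[str, list[str]] = {}
    n_unnamed = 0
    for taxon in presence.coords["taxon"].values:
        species = taxonomy.rank_value(str(taxon), "species")
        if not species:
            species = str(taxon)
            n_unnamed += 1
        members.setdefault(species, []).append(str(taxon))
    if n_unnamed:
        logger.info("collapse_species: %d ASVs without species rank kept as pseudo-species", n_unnamed)
    species_ids = sorted(members)
    mult = np.zeros((len(species_ids), *presence.shape[1:]), dtype=np.int64)
    for k, sp in enumerate(species_ids):
        block = presence.sel(taxon=members[sp]).to_numpy()
        mult[k] = block.sum(axis=0)
    coords = {
        "species": species_ids,
        "subject": presence.coords["subject"].values,
        "organ": presence.coords["organ"].values,
    }
    multiplicity = xr.DataArray(mult, dims=("species", "subject", "organ"), coords=coords)
    return multiplicity > 0, multiplicity


def prevalence_by_organ(
    presence: xr.DataArray, prevalence_cutoff: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of subjects with presence per (taxon/species, organ), plus
    the strict > cutoff 'prevalent' flags."""
    if presence.sizes["subject"] < 1:
        raise ValidationError("need at least one subject")
    prev = presence.mean(dim="subject")
    frame = prev.to_pandas()
    return frame, frame > prevalence_cutoff


def subject_organ_abundance(
    table: CountTable, samples: SampleTable, taxonomy: TaxonomyTable | None = None
) -> xr.DataArray:
    """Mean relative abundance per (taxon-or-species, subject, organ),
    averaging over the subject's samples in the organ; species level when a
    taxonomy is given (summing member ASV abundances first)."""
    meta = samples.data
    rel = table.relative_abundance()
    row_ids = list(table.taxon_ids)
    if taxonomy is not None:
        species_of = [
            taxonomy.rank_value(t, "species") or t for t in table.taxon_ids
        ]
        frame = pd.DataFrame(rel, index=species_of).groupby(level=0).sum()
        row_ids = list(frame.index)
        rel = frame.to_numpy()
    biological = [s for s in table.sample_ids if meta.loc[s, "organ"] != "negative_control"]
    subjects = sorted(meta.loc[biological, "subject_id"].unique())
    organs = sorted(meta.loc[biological, "organ"].unique())
    col = {s: j for j, s in enumerate(table.sample_ids)}
    out = np.full((len(row_ids), len(subjects), len(organs)), np.nan)
    for si, subj in enumerate(subjects):
        for oi, organ in enumerate(organs):
            ids = [
                s
                for s in biological
                if meta.loc[s, "subject_id"] == subj and meta.loc[s, "organ"] == organ
            ]
            if ids:
                out[:, si, oi] = rel[:, [col[s] for s in ids]].mean(axis=1)
    return xr.DataArray(
        out,
        dims=("taxon", "subject", "organ"),
        coords={"taxon": row_ids, "subject": subjects, "organ": organs},
    )


def partial_spearman(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given covariates z.

    Rank-transforms all variables, residualizes the ranks of x and y on the
    (intercept-augmented) covariate ranks, and computes the Pearson
    correlation of the residuals; the p-value uses the t distribution with
    n - 2 - k degrees of freedom.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z.reshape(-1, 1)
    n, k = len(x), z.shape[1]
    if n - 2 - k < 1:
        return np.nan, np.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rz = np.column_stack([np.ones(n)] + [stats.rankdata(z[:, j]) for j in range(k)])
    res_x = rx - rz @ np.linalg.lstsq(rz, rx, rcond=None)[0]
    res_y = ry - rz @ np.linalg.lstsq(rz, ry, rcond=None)[0]
    denom = np.sqrt(np.sum(res_x**2) * np.sum(res_y**2))
    if denom == 0:
        return np.nan, np.nan
    r = float(np.clip(np.sum(res_x * res_y) / denom, -1.0, 1.0))
    dof = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t), dof))
    return r, p


def _correlate(method: str, x, y, z) -> tuple[float, float]:
    # constant vectors (e.g. a species at zero throughout one organ) have no
    # defined correlation; report nan, which never counts as positive
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
        return float(r), float(p)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    if method == "partial_spearman":
        if z is None or z.shape[1] == 0:
            r, p = stats.spearmanr(x, y)
            return float(r), float(p)
        return partial_spearman(x, y, z)
    raise ParameterError(f"unknown method {method!r}")


def positive_correlation_ratio(
    abundance: xr.DataArray,
    prevalent: pd.DataFrame,
    organ_a: str,
    organ_b: str,
    config: InterOrganConfig | None = None,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of prevalent species positively correlated between two organs.

    For each species prevalent in either organ, the subject-level relative
    abundances in organ_a and organ_b are correlated across subjects by each
    configured method; the species counts as positive when the coefficient
    is > 0 with p < alpha under the combine rule ('any' method suffices, or
    'all'). Species with fewer than ``min_paired_subjects`` subjects sampled
    in both organs are skipped and excluded from the denominator.
    """
    config = config or InterOrganConfig()
    candidates = [
        sp
        for sp in abundance.coords["taxon"].values
        if sp in prevalent.index and (prevalent.loc[sp, organ_a] or prevalent.loc[sp, organ_b])
    ]
    subjects = abundance.coords["subject"].values
    rows = []
    n_tested = n_positive = 0
    for sp in candidates:
        xa = abundance.sel(taxon=sp, organ=organ_a).to_numpy()
        xb = abundance.sel(taxon=sp, organ=organ_b).to_numpy()
        ok = np.isfinite(xa) & np.isfinite(xb)
        if ok.sum() < config.min_paired_subjects:
            logger.info("skipping %s: only %d paired subjects", sp, int(ok.sum()))
            continue
        z = None
        if covariates is not None:
            z = covariates.loc[subjects[ok]].to_numpy(dtype=float)
        verdicts = []
        record: dict = {"species": sp, "n_subjects": int(ok.sum())}
        for method in config.correlation_methods:
            r, p = _correlate(method, xa[ok], xb[ok], z)
            record[f"r_{method}"] = r
            record[f"p_{method}"] = p
            verdicts.append(bool(np.isfinite(r) and r > 0 and p < config.correlation_alpha))
        positive = any(verdicts) if config.combine == "any" else all(verdicts)
        record["positive"] = positive
        rows.append(record)
        n_tested += 1
        n_positive += int(positive)
    ratio = n_positive / n_tested if n_tested else np.nan
    return ratio, pd.DataFrame(rows)


def core_species(
    presence: xr.DataArray,
    multiplicity: xr.DataArray,
    organ_groups: dict[str, set[str]],
) -> pd.DataFrame:
    """Per (species, subject, group) core-species calls.

    ``core_single_asv``: at least one ASV of the species present in every
    organ of the group for that subject; ``core_multi_asv``: two or more
    such ASVs; otherwise ``absent``. Multiplicity must count, per (species,
    subject, organ), the member ASVs meeting the presence criterion — the
    multi-ASV call requires >= 2 ASVs each present in *all* group organs,
    which is bounded by the minimum multiplicity across the group.
    """
    organs_available = set(map(str, presence.coords["organ"].values))
    rows = []
    for group, organs in organ_groups.items():
        missing = set(organs) - organs_available
        if missing:
            raise ValidationError(f"group {group!r} references absent organs: {sorted(missing)}")
        organs = sorted(organs)
        pres_group = presence.sel(organ=organs)
        mult_group = multiplicity.sel(organ=organs)
        all_present = pres_group.all(dim="organ")
        min_mult = mult_group.min(dim="organ")
        for sp in presence.coords["species"].values if "species" in presence.dims else presence.coords["taxon"].values:
            sel = {"species": sp} if "species" in presence.dims else {"taxon": sp}
            for subj in presence.coords["subject"].values:
                if not bool(all_present.sel(subject=subj, **sel)):
                    status = "absent"
                elif int(min_mult.sel(subject=subj, **sel)) >= 2:
                    status = "core_multi_asv"
                else:
                    status = "core_single_asv"
                rows.append(
                    {"species": str(sp), "group": group, "subject": str(subj), "status": status}
                )
    return pd.DataFrame(rows)


def core_species_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Fraction of subjects called core per (species, group)."""
    calls = calls.assign(core=calls["status"] != "absent")
    return (
        calls.groupby(["species", "group"])["core"].mean().rename("core_fraction").reset_index()
    )


@dataclass
class TranslocationReport:
    presence: xr.DataArray
    multiplicity: xr.DataArray
    prevalence: pd.DataFrame
    prevalent: pd.DataFrame
    ratios: pd.DataFrame
    core_calls: pd.DataFrame


def translocation_analysis(
    table: CountTable,
    samples: SampleTable,
    taxonomy: TaxonomyTable,
    config: InterOrganConfig | None = None,
) -> TranslocationReport:
    """Full inter-organ analysis on a cleaned count table."""
    config = config or InterOrganConfig()
    asv_presence = call_presence(table, samples, config.presence_threshold)
    sp_presence, multiplicity = collapse_species(asv_presence, taxonomy)
    prevalence, prevalent = prevalence_by_organ(sp_presence, config.prevalence_cutoff)
    abundance = subject_organ_abundance(table, samples, taxonomy)
    covariates = _subject_covariates(samples)
    organs = list(map(str, sp_presence.coords["organ"].values))
    rows = []
    for i, organ_a in enumerate(organs):
        for organ_b in organs[i + 1 :]:
            ratio, records = positive_correlation_ratio(
                abundance, prevalent, organ_a, organ_b, config, covariates
            )
            rows.append(
                {
                    "organ_a": organ_a,
                    "organ_b": organ_b,
                    "n_tested": len(records),
                    "n_positive": int(records["positive"].sum()) if len(records) else 0,
                    "ratio": ratio,
                }
            )
    groups = {
        g: o for g, o in config.organ_groups.items() if set(o) & set(organs)
    }
    usable = {g: set(o) & set(organs) for g, o in groups.items()}
    calls = core_species(sp_presence, multiplicity, usable) if usable else pd.DataFrame()
    return TranslocationReport(
        presence=sp_presence,
        multiplicity=multiplicity,
        prevalence=prevalence,
        prevalent=prevalent,
        ratios=pd.DataFrame(rows),
        core_calls=calls,
    )


def _subject_covariates(samples: SampleTable) -> pd.DataFrame | None:
    meta = samples.data
    cols = [c for c in ("age", "sex", "BMI") if c in meta.columns]
    if not cols:
        return None
    sub = (
        meta.loc[meta["organ"] != "negative_control", ["subject_id", *cols]]
        .drop_duplicates("subject_id")
        .set_index("subject_id")
    )
    sub = sub.apply(pd.to_numeric, errors="coerce")
    if sub.isna().any().any():
        return None
    return sub
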