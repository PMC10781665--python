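"""Synthetic multi-organ 16S study generator.

Emulates an amplicon survey across subjects x organs x sites x sample types:
ASV counts with beta-binomial overdispersion, paired lumen/mucosa samples
with planted log-odds enrichment shifts, contaminant taxa shared with
negative controls, organ-specific taxon-taxon correlation structure, and
intra-subject "core" species whose abundance is correlated across the organs
of a group. Every planted effect is recorded in a :class:`GroundTruth` so
each downstream stage can be scored by parameter recovery.

The latent model: per (subject, site) a log-abundance vector is formed from
the organ's base composition, perturbed by subject-level core-species
effects, by correlated Gaussian pair noise (a Gaussian copula in log space —
the structure compositional correlation estimators are designed to detect),
and by i.i.d. sample noise; it is closed to the simplex by softmax. Mucosal
samples receive planted enrichment as exact logit shifts of the affected
taxa's proportions. Counts are then beta-binomial thinned per taxon at a
common intra-class correlation ``rho`` (``a = p(1-rho)/rho``,
``b = (1-p)(1-rho)/rho``; ``rho = 0`` degenerates to binomial sampling).
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from skbio import TreeNode

from .errors import ParameterError, ValidationError
from .io import CountTable, SampleTable, StudyBundle, TaxonomyTable

LUMINAL_TYPES = ("lumen", "gastric_juice")


def sample_beta_binomial(
    n_draws: int,
    trials: int | np.ndarray,
    mean: float | np.ndarray,
    rho: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw from Beta-Binomial(N, p, rho) with the mean/ICC parameterization.

    ``a = p(1-rho)/rho``, ``b = (1-p)(1-rho)/rho``; variance is
    ``N p (1-p) (1 + (N-1) rho)``. ``rho = 0`` falls back to plain binomial
    draws. ``mean`` may be 0 or 1 (degenerate, returns 0 or N).
    """
    if not 0 <= rho < 1:
        raise ParameterError(f"rho must be in [0, 1), got {rho}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trials = np.broadcast_to(np.asarray(trials, dtype=np.int64), (n_draws,)).copy()
    p = np.broadcast_to(np.asarray(mean, dtype=float), (n_draws,)).copy()
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("mean must lie in [0, 1]")
    if rho == 0:
        return rng.binomial(trials, p)
    out = np.zeros(n_draws, dtype=np.int64)
    interior = (p > 0) & (p < 1)
    a = p[interior] * (1 - rho) / rho
    b = (1 - p[interior]) * (1 - rho) / rho
    q = rng.beta(a, b)
    out[interior] = rng.binomial(trials[interior], q)
    out[p == 1] = trials[p == 1]
    return out


@dataclass
class OrganDesign:
    """Sites of an organ and the sample types collected at each site.

    If ``sample_types`` contains both ``mucosa`` and a luminal type, each
    site yields a paired lumen/mucosa sample sharing the same latent
    community (the paired design the enrichment regression exploits).
    """

    sites: list[str]
    sample_types: list[str]


@dataclass
class EnrichmentEffect:
    """Planted mucosa-vs-lumen log-odds shift for one taxon at given sites."""

    sites: list[str]
    beta: float

    @property
    def direction(self) -> str:
        return "mucosa" if self.beta >= 0 else "lumen"


@dataclass
class Contaminant:
    taxon: str
    control_prevalence: float = 0.9
    carryover: float = 0.05


@dataclass
class CoreSpeciesSpec:
    """A species planted present across the organs of a group within subjects,
    with subject-level abundance correlation ``r`` between organs."""

    species: str
    taxa: list[str]
    organs: list[str]
    r: float = 0.8
    log_boost: float = 3.5


@dataclass
class SimConfig:
    n_subjects: int = 6
    organs: dict[str, OrganDesign] = field(default_factory=dict)
    n_taxa: int = 120
    n_controls: int = 3
    library_size_range: tuple[int, int] = (20_000, 50_000)
    rho: float = 0.02
    enrichment_effects: dict[str, EnrichmentEffect] = field(default_factory=dict)
    contaminant_taxa: list[Contaminant] = field(default_factory=list)
    core_species: list[CoreSpeciesSpec] = field(default_factory=list)
    organ_base_composition: dict[str, np.ndarray] | None = None
    network_effects: dict[str, list[tuple[str, str, float]]] = field(default_factory=dict)
    absent_species: dict[str, list[str]] = field(default_factory=dict)
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    one_species_per_asv: bool = False  # skip multi-ASV species in the taxonomy
    latent_noise_sd: float = 0.4
    core_effect_sd: float = 1.0
    network_effect_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.rho < 1:
            raise ParameterError("rho must be in [0, 1)")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ParameterError("library_size_range must be positive and ordered")
        for spec in self.core_species:
            missing = [o for o in spec.organs if o not in self.organs]
            if missing:
                raise ValidationError(
                    f"core species {spec.species!r} references unknown organs {missing}"
                )
        for contaminant in self.contaminant_taxa:
            if not 0 <= contaminant.control_prevalence <= 1:
                raise ParameterError("control_prevalence must be in [0, 1]")
            if not 0 <= contaminant.carryover <= 1:
                raise ParameterError("carryover must be in [0, 1]")
        if self.organ_base_composition is not None:
            for organ, vec in self.organ_base_composition.items():
                if not np.isclose(np.sum(vec), 1.0):
                    raise ValidationError(f"base composition for {organ!r} must sum to 1")


def default_organs() -> dict[str, OrganDesign]:
    """Reduced-scale mirror of a body-wide design: five GI-axis organs,
    paired lumen/mucosa in stomach, small and large intestine."""
    return {
        "oral cavity": OrganDesign(["tongue", "buccal"], ["surface"]),
        "esophagus": OrganDesign(["upper-eso", "lower-eso"], ["mucosa"]),
        "stomach": OrganDesign(["fundus", "antrum"], ["gastric_juice", "mucosa"]),
        "small intestine": OrganDesign(["duodenum", "jejunum", "ileum"], ["lumen", "mucosa"]),
        "large intestine": OrganDesign(["ascending", "transverse", "sigmoid"], ["lumen", "mucosa"]),
    }


def taxon_name(i: int) -> str:
    return f"ASV{i + 1:04d}"


def default_config(seed: int = 0) -> SimConfig:
    """The default reduced-scale study: 6 subjects, 5 organs, 120 taxa,
    planted enrichment / contaminants / core species / pair correlations."""
    n_taxa = 120
    taxa = [taxon_name(i) for i in range(n_taxa)]
    contaminants = [Contaminant(t, 0.9, 0.05) for t in taxa[-6:]]
    enriched = {
        taxa[i]: EnrichmentEffect(["duodenum", "jejunum", "ileum"], beta)
        for i, beta in zip(range(8), [2.0, 2.0, -2.0, -2.0, 2.0, -2.0, 2.0, -2.0])
    }
    core = [
        CoreSpeciesSpec("Core_species_A", taxa[10:12], ["esophagus", "stomach"], r=0.8),
        CoreSpeciesSpec("Core_species_B", taxa[12:13], ["esophagus", "stomach"], r=0.8),
        CoreSpeciesSpec(
            "Core_species_C", taxa[13:15], ["small intestine", "large intestine"], r=0.8
        ),
        CoreSpeciesSpec(
            "Core_species_D", taxa[15:16], ["small intestine", "large intestine"], r=0.8
        ),
    ]
    absent = {
        "Absent_species_A": ["stomach"],
        "Absent_species_B": ["large intestine"],
    }
    network = {
        organ: [
            (taxa[20 + 2 * k], taxa[21 + 2 * k], 0.75 if k % 2 == 0 else -0.75)
            for k in range(3)
        ]
        for organ in ("stomach", "small intestine", "large intestine")
    }
    return SimConfig(
        n_subjects=6,
        organs=default_organs(),
        n_taxa=n_taxa,
        n_controls=3,
        enrichment_effects=enriched,
        contaminant_taxa=contaminants,
        core_species=core,
        absent_species=absent,
        network_effects=network,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Planted parameters of a simulated study, sufficient to score every
    downstream stage without re-reading the config."""

    enrichment: dict[str, dict]
    contaminants: list[str]
    core_species: list[dict]
    absent_species: dict[str, list[str]]
    networks: dict[str, list[tuple[str, str, float]]]
    rho: float
    latent_proportions: pd.DataFrame

    def to_json(self) -> str:
        payload = {
            "enrichment": self.enrichment,
            "contaminants": self.contaminants,
            "core_species": self.core_species,
            "absent_species": self.absent_species,
            "networks": {k: [list(e) for e in v] for k, v in self.networks.items()},
            "rho": self.rho,
            "latent_proportions": {
                "index": list(self.latent_proportions.index),
                "columns": list(self.latent_proportions.columns),
                "values": self.latent_proportions.round(8).to_numpy().tolist(),
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        doc = json.loads(text)
        lp = doc["latent_proportions"]
        return cls(
            enrichment=doc["enrichment"],
            contaminants=doc["contaminants"],
            core_species=doc["core_species"],
            absent_species=doc["absent_species"],
            networks={k: [tuple(e) for e in v] for k, v in doc["networks"].items()},
            rho=doc["rho"],
            latent_proportions=pd.DataFrame(
                lp["values"], index=lp["index"], columns=lp["columns"]
            ),
        )


# ---------------------------------------------------------------------------
# Taxonomy / tree simulation

_PHYLA = ("Firmicutes", "Proteobacteria", "Bacteroidetes", "Actinobacteria", "Fusobacteria")


def _simulate_taxonomy(config: SimConfig, rng: np.random.Generator) -> TaxonomyTable:
    taxa = [taxon_name(i) for i in range(config.n_taxa)]
    named: dict[str, str] = {}
    for spec in config.core_species:
        for t in spec.taxa:
            named[t] = spec.species
    absent_members = _absent_species_members(config)
    for species, members in absent_members.items():
        for t in members:
            named[t] = species
    lineages: dict[str, tuple[str, ...]] = {}
    for i, t in enumerate(taxa):
        phylum = _PHYLA[i % len(_PHYLA)]
        genus = f"Genus{i // 3:03d}"
        if config.one_species_per_asv:
            species = named.get(t, f"Species{i:03d}")
        else:
            # every third pair of ASVs shares a species to exercise multiplicity
            species = named.get(t, f"Species{i // 2:03d}" if i % 6 < 2 else f"Species{i:03d}")
        lineages[t] = ("Bacteria", phylum, f"Class{i % 7}", f"Order{i % 11}",
                       f"Family{i % 13}", genus, species)
    return TaxonomyTable(lineages)


def _absent_species_members(config: SimConfig) -> dict[str, list[str]]:
    """Reserve two ASVs per planted-absent species from the tail of the
    taxon list (before contaminants)."""
    members: dict[str, list[str]] = {}
    start = config.n_taxa - len(config.contaminant_taxa) - 2 * len(config.absent_species)
    for k, species in enumerate(sorted(config.absent_species)):
        members[species] = [taxon_name(start + 2 * k), taxon_name(start + 2 * k + 1)]
    return members


def simulate_tree(taxon_ids: Sequence[str], seed: int | np.random.Generator) -> TreeNode:
    """Random bifurcating tree over the taxa, exponential(1) branch lengths."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = [f"{t}:{rng.exponential():.6f}" for t in taxon_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        merged = f"({nodes[i]},{nodes[j]}):{rng.exponential():.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0].rsplit(":", 1)[0] + ":0.0;"
    return TreeNode.read(_stdio.StringIO(newick), format="newick")


# ---------------------------------------------------------------------------
# Study generation


def _softmax(log_weights: np.ndarray) -> np.ndarray:
    finite = np.isfinite(log_weights)
    out = np.zeros_like(log_weights)
    if finite.any():
        z = np.exp(log_weights[finite] - log_weights[finite].max())
        out[finite] = z / z.sum()
    return out


def _base_log_weights(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    taxa = [taxon_name(i) for i in range(config.n_taxa)]
    n = config.n_taxa
    if config.organ_base_composition is not None:
        with np.errstate(divide="ignore"):
            return {o: np.log(np.asarray(v, dtype=float))
                    for o, v in config.organ_base_composition.items()}
    backbone = rng.normal(0.0, 1.2, size=n)
    contaminant_ids = {c.taxon for c in config.contaminant_taxa}
    absent_members = _absent_species_members(config)
    weights: dict[str, np.ndarray] = {}
    for organ in config.organs:
        w = backbone + rng.normal(0.0, 0.8, size=n)
        for i, t in enumerate(taxa):
            if t in contaminant_ids:
                w[i] = -np.inf  # contaminants have no biological source
        for spec in config.core_species:
            if organ in spec.organs:
                for t in spec.taxa:
                    w[taxa.index(t)] += spec.log_boost
        for species, organs_absent in config.absent_species.items():
            members = absent_members.get(species, [])
            for t in members:
                if organ in organs_absent:
                    w[taxa.index(t)] = -np.inf
                else:
                    w[taxa.index(t)] += 2.0  # clearly present where not planted absent
        weights[organ] = w
    return weights


def _apply_enrichment(p: np.ndarray, shifts: Mapping[int, float]) -> np.ndarray:
    """Shift the listed taxa's proportions by the given log-odds amounts,
    rescaling the remaining taxa so the vector stays on the simplex."""
    if not shifts:
        return p
    q = p.copy()
    idx = np.fromiter(shifts.keys(), dtype=int)
    betas = np.fromiter(shifts.values(), dtype=float)
    old = p[idx]
    movable = (old > 0) & (old < 1)
    new = old.copy()
    new[movable] = expit(logit(old[movable]) + betas[movable])
    q[idx] = new
    rest = np.ones(len(p), dtype=bool)
    rest[idx] = False
    old_rest = p[rest].sum()
    if old_rest > 0:
        q[rest] *= (1.0 - new.sum()) / old_rest
    return q


def generate_study(config: SimConfig) -> tuple[StudyBundle, GroundTruth]:
    """Simulate a full study bundle plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    organs = config.organs or default_organs()
    taxa = [taxon_name(i) for i in range(config.n_taxa)]
    taxon_index = {t: i for i, t in enumerate(taxa)}
    base = _base_log_weights(config, rng)

    subjects = [f"subj{j + 1:02d}" for j in range(config.n_subjects)]
    covariates = pd.DataFrame(
        {
            "subject_id": subjects,
            "age": np.round(rng.normal(50, 12, config.n_subjects)).clip(18, 90),
            "sex": rng.integers(0, 2, config.n_subjects),
            "BMI": np.round(rng.normal(23.5, 3.0, config.n_subjects), 1).clip(15, 40),
            "antibiotics": rng.integers(0, 2, config.n_subjects),
            "hospitalization_days": rng.integers(0, 30, config.n_subjects),
        }
    ).set_index("subject_id")

    sample_rows: list[dict] = []
    count_cols: list[np.ndarray] = []
    latent_cols: list[np.ndarray] = []
    sample_ids: list[str] = []

    core_u = {
        (subj, t): rng.normal()
        for subj in subjects
        for spec in config.core_species
        for t in spec.taxa
    }

    lo, hi = config.library_size_range
    for subj in subjects:
        organ_core_noise = {
            (organ, t): rng.normal()
            for organ in organs
            for spec in config.core_species
            if organ in spec.organs
            for t in spec.taxa
        }
        for organ, design in organs.items():
            for site in design.sites:
                y = base[organ].astype(float).copy()
                for spec in config.core_species:
                    if organ in spec.organs:
                        for t in spec.taxa:
                            shared = np.sqrt(spec.r) * core_u[(subj, t)]
                            own = np.sqrt(1 - spec.r) * organ_core_noise[(organ, t)]
                            y[taxon_index[t]] += config.core_effect_sd * (shared + own)
                for a, b, corr in config.network_effects.get(organ, []):
                    z1 = rng.normal()
                    z2 = corr * z1 + np.sqrt(1 - corr**2) * rng.normal()
                    y[taxon_index[a]] += config.network_effect_sd * z1
                    y[taxon_index[b]] += config.network_effect_sd * z2
                if config.latent_noise_sd > 0:
                    y = y + rng.normal(0.0, config.latent_noise_sd, config.n_taxa)
                for taxon, effects in config.covariate_effects.items():
                    for cov, coef in effects.items():
                        y[taxon_index[taxon]] += coef * float(covariates.loc[subj, cov])
                p_site = _softmax(y)
                for stype in design.sample_types:
                    p = p_site
                    if stype == "mucosa":
                        shifts = {
                            taxon_index[t]: eff.beta
                            for t, eff in config.enrichment_effects.items()
                            if site in eff.sites
                        }
                        p = _apply_enrichment(p_site, shifts)
                    depth = int(rng.integers(lo, hi + 1))
                    counts = sample_beta_binomial(
                        config.n_taxa, depth, p, config.rho, rng
                    )
                    for contaminant in config.contaminant_taxa:
                        if rng.random() < contaminant.carryover:
                            frac = rng.uniform(0.0015, 0.005)
                            counts[taxon_index[contaminant.taxon]] += int(
                                np.ceil(frac * depth)
                            )
                    sid = f"{subj}.{organ.replace(' ', '-')}.{site}.{stype}"
                    sample_ids.append(sid)
                    count_cols.append(counts)
                    latent_cols.append(p)
                    sample_rows.append(
                        {
                            "sample_id": sid,
                            "subject_id": subj,
                            "organ": organ,
                            "site": site,
                            "sample_type": stype,
                            **covariates.loc[subj].to_dict(),
                        }
                    )

    for c in range(config.n_controls):
        depth = int(rng.integers(12_000, 20_001))
        counts = np.zeros(config.n_taxa, dtype=np.int64)
        present = [
            contaminant.taxon
            for contaminant in config.contaminant_taxa
            if rng.random() < contaminant.control_prevalence
        ]
        if present:
            share = rng.dirichlet(np.ones(len(present)))
            reads = np.maximum(1, np.round(share * depth)).astype(np.int64)
            for t, r in zip(present, reads):
                counts[taxon_index[t]] = r
        sid = f"ctrl{c + 1:02d}"
        sample_ids.append(sid)
        count_cols.append(counts)
        latent_cols.append(counts / max(counts.sum(), 1))
        sample_rows.append(
            {
                "sample_id": sid,
                "subject_id": f"control{c + 1:02d}",
                "organ": "negative_control",
                "site": "control",
                "sample_type": "control",
            }
        )

    count_table = CountTable(taxa, sample_ids, np.column_stack(count_cols))
    samples = SampleTable(pd.DataFrame(sample_rows))
    taxonomy = _simulate_taxonomy(config, rng)
    tree = simulate_tree(taxa, rng)
    bundle = StudyBundle(count_table, samples, taxonomy, tree)

    absent_members = _absent_species_members(config)
    truth = GroundTruth(
        enrichment={
            t: {"beta": eff.beta, "direction": eff.direction, "sites": list(eff.sites)}
            for t, eff in config.enrichment_effects.items()
        },
        contaminants=[c.taxon for c in config.contaminant_taxa],
        core_species=[
            {"species": s.species, "taxa": list(s.taxa), "organs": list(s.organs), "r": s.r}
            for s in config.core_species
        ]
        + [
            {"species": sp, "taxa": members, "organs": [], "r": 0.0,
             "absent_in": config.absent_species[sp]}
            for sp, members in absent_members.items()
        ],
        absent_species=dict(config.absent_species),
        networks={k: list(v) for k, v in config.network_effects.items()},
        rho=config.rho,
        latent_proportions=pd.DataFrame(
            np.column_stack(latent_cols), index=taxa, columns=sample_ids
        ),
    )
    return bundle, truth


def simulate_paired_site(
    n_pairs: int,
    depth: int,
    beta0: float,
    beta_type: float,
    rho: float,
    seed: int | np.random.Generator,
    covariates: np.ndarray | None = None,
    covariate_betas: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one taxon at one site under the paired-niche logistic model.

    Returns (C, N, R_type, X_cov) for ``n_pairs`` lumen/mucosa pairs with
    logit(p) = beta0 + beta_type * R_type (+ X_cov @ covariate_betas).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_type = np.tile([0.0, 1.0], n_pairs)
    eta = beta0 + beta_type * r_type
    if covariates is not None:
        x_cov = np.repeat(np.asarray(covariates, dtype=float), 2, axis=0)
        if covariate_betas is not None:
            eta = eta + x_cov @ np.asarray(covariate_betas, dtype=float)
    else:
        x_cov = np.empty((2 * n_pairs, 0))
    p = expit(eta)
    n_reads = np.full(2 * n_pairs, depth, dtype=np.int64)
    c = sample_beta_binomial(2 * n_pairs, n_reads, p, rho, rng)
    return c, n_reads, r_type, x_cov


def translocation_scenario(
    seed: int,
    n_taxa: int = 40,
    n_subjects: int = 30,
    frac_translocating: float = 0.3,
    r: float = 0.8,
) -> SimConfig:
    """Two-organ study for translocation-recovery experiments.

    A ``frac_translocating`` share of taxa receive a shared subject-level
    abundance effect (correlation ``r``) between esophagus and stomach; the
    rest are independent between organs. Base composition is uniform so
    every species clears the presence threshold and the tested denominator
    is the full species set.
    """
    taxa = [taxon_name(i) for i in range(n_taxa)]
    n_core = int(round(frac_translocating * n_taxa))
    core = [
        CoreSpeciesSpec(f"Trans{i:03d}", [taxa[i]], ["esophagus", "stomach"], r=r)
        for i in range(n_core)
    ]
    uniform = np.full(n_taxa, 1.0 / n_taxa)
    return SimConfig(
        n_subjects=n_subjects,
        organs={
            "esophagus": OrganDesign(["upper-eso", "lower-eso"], ["mucosa"]),
            "stomach": OrganDesign(["fundus", "antrum"], ["mucosa"]),
        },
        n_taxa=n_taxa,
        n_controls=2,
        core_species=core,
        organ_base_composition={"esophagus": uniform, "stomach": uniform},
        one_species_per_asv=True,  # denominator = taxa, so the planted fraction is exact
        seed=seed,
    )


def core_recovery_scenario(seed: int, n_subjects: int = 10) -> SimConfig:
    """Default-design study emphasizing planted core species (present across
    a whole organ group) and planted-absent species (zero abundance in at
    least one group organ), for core-call sensitivity/specificity checks."""
    config = default_config(seed)
    config.n_subjects = n_subjects
    return config


# ---------------------------------------------------------------------------
# Flat key-value config files (CLI)

_SIMPLE_KEYS = {
    "n_subjects": int,
    "n_taxa": int,
    "n_controls": int,
    "rho": float,
    "latent_noise_sd": float,
    "core_effect_sd": float,
    "network_effect_sd": float,
    "seed": int,
}


def load_config(path) -> SimConfig:
    """Parse a flat ``key = value`` config file; complex fields take inline
    JSON. Unset keys keep the default-study values."""
    config = default_config()
    text = open(path).read()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _SIMPLE_KEYS:
            setattr(config, key, _SIMPLE_KEYS[key](value))
        elif key == "library_size_range":
            lo, hi = json.loads(value)
            config.library_size_range = (int(lo), int(hi))
        elif key == "organs":
            config.organs = {
                organ: OrganDesign(d["sites"], d["sample_types"])
                for organ, d in json.loads(value).items()
            }
        elif key == "enrichment_effects":
            config.enrichment_effects = {
                t: EnrichmentEffect(d["sites"], float(d["beta"]))
                for t, d in json.loads(value).items()
            }
        elif key == "contaminant_taxa":
            config.contaminant_taxa = [
                Contaminant(d["taxon"], d.get("control_prevalence", 0.9),
                            d.get("carryover", 0.05))
                for d in json.loads(value)
            ]
        elif key == "core_species":
            config.core_species = [
                CoreSpeciesSpec(d["species"], d["taxa"], d["organs"], d.get("r", 0.8))
                for d in json.loads(value)
            ]
        elif key == "network_effects":
            config.network_effects = {
                organ: [tuple(e) for e in edges]
                for organ, edges in json.loads(value).items()
            }
        elif key == "absent_species":
            config.absent_species = json.loads(value)
        else:
            raise ValidationError(f"unknown config key {key!r}")
    return config
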