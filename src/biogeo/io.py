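"""Containers and readers/writers for ASV count tables, sample metadata,
taxonomy lineages and phylogenies.

The on-disk interchange format is UTF-8 tab-delimited text. Count tables are
taxa x samples with the first column named ``taxon_id``; BIOM 1.0 (JSON)
tables are accepted read-only. Trees are newick with branch lengths (required
for UniFrac). All loading is order-preserving and deterministic; round-trip
write-then-read is the identity for integer counts.

Identifiers are case-sensitive after trimming surrounding whitespace;
internal whitespace in identifiers is rejected to prevent silent join
failures downstream.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import FormatError, IntegrityError, ValidationError

ORGANS = frozenset(
    {
        "skin",
        "oral cavity",
        "esophagus",
        "stomach",
        "small intestine",
        "appendix",
        "large intestine",
        "negative_control",
    }
)
SAMPLE_TYPES = frozenset({"mucosa", "lumen", "gastric_juice", "surface", "control"})
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIX = re.compile(r"^[a-z]__")
REQUIRED_META_COLUMNS = ("sample_id", "subject_id", "organ", "site", "sample_type")


def _clean_id(raw: str, what: str) -> str:
    ident = str(raw).strip()
    if not ident:
        raise FormatError(f"empty {what} identifier")
    if re.search(r"\s", ident):
        raise FormatError(f"{what} identifier {ident!r} contains internal whitespace")
    return ident


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = sorted(seen[seen.duplicated()].unique())
        raise IntegrityError(f"duplicate {what} identifiers: {dups}")


@dataclass
class CountTable:
    """Non-negative integer matrix of taxa x samples.

    ``library_sizes`` are always derived as column sums and never stored
    independently, so they cannot drift out of sync with the counts.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = [_clean_id(t, "taxon") for t in self.taxon_ids]
        self.sample_ids = [_clean_id(s, "sample") for s in self.sample_ids]
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                bad = np.argwhere(counts != np.floor(counts))[0]
                raise FormatError(
                    "non-integer count at taxon "
                    f"{self.taxon_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        self.counts = counts.reshape(len(self.taxon_ids), len(self.sample_ids)).astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            bad = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample sequencing depth (column sums)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        return cls(list(map(str, frame.index)), list(map(str, frame.columns)), frame.to_numpy())

    def relative_abundance(self) -> np.ndarray:
        """Taxa x samples proportions; all-zero samples yield zero columns."""
        depth = self.library_sizes.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(depth > 0, self.counts / depth, 0.0)
        return rel

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(self.taxon_ids), list(sample_ids), self.counts[:, idx])

    def select_taxa(self, taxon_ids: Sequence[str]) -> "CountTable":
        idx = [self.taxon_ids.index(t) for t in taxon_ids]
        return CountTable(list(taxon_ids), list(self.sample_ids), self.counts[idx, :])


def _normalize_category(value: str) -> str:
    return re.sub(r"\s+", " ", str(value).strip()).lower()


@dataclass
class SampleTable:
    """Per-sample metadata driving pairing, grouping and adjustment.

    Categorical fields (organ, sample_type) are validated against the
    controlled vocabularies after whitespace normalization (surrounding
    whitespace stripped, internal runs collapsed, lowercased). Unknown
    covariate columns are retained verbatim.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in REQUIRED_META_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample table missing required columns: {missing}")
        df["sample_id"] = [_clean_id(s, "sample") for s in df["sample_id"]]
        _check_unique(list(df["sample_id"]), "sample")
        for col in ("organ", "sample_type"):
            df[col] = df[col].map(_normalize_category)
        bad_organs = sorted(set(df["organ"]) - ORGANS)
        if bad_organs:
            raise ValidationError(f"unknown organ values: {bad_organs}")
        bad_types = sorted(set(df["sample_type"]) - SAMPLE_TYPES)
        if bad_types:
            raise ValidationError(f"unknown sample_type values: {bad_types}")
        df["subject_id"] = df["subject_id"].astype(str).str.strip()
        df["site"] = df["site"].astype(str).str.strip()
        self.data = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in REQUIRED_META_COLUMNS]

    def control_mask(self) -> np.ndarray:
        return (self.data["organ"] == "negative_control").to_numpy()

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        return SampleTable(self.data.loc[list(sample_ids)].reset_index(drop=True))


@dataclass
class TaxonomyTable:
    """Mapping taxon_id -> 7-rank lineage (kingdom..species).

    Ranks may be empty strings where the taxon is unclassified. Greengenes
    rank prefixes (``g__``) are stripped on load; ``;`` separates ranks.
    """

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for taxon, lineage in self.lineages.items():
            ranks = tuple(lineage) + ("",) * (len(RANKS) - len(lineage))
            if len(ranks) > len(RANKS):
                raise FormatError(f"lineage for {taxon!r} has more than {len(RANKS)} ranks")
            clean[_clean_id(taxon, "taxon")] = ranks
        self.lineages = clean

    def lineage(self, taxon_id: str) -> tuple[str, ...]:
        return self.lineages.get(taxon_id, ("",) * len(RANKS))

    def rank_value(self, taxon_id: str, rank: str) -> str:
        return self.lineage(taxon_id)[RANKS.index(rank)]

    @classmethod
    def from_strings(cls, strings: Mapping[str, str]) -> "TaxonomyTable":
        lineages = {}
        for taxon, lineage in strings.items():
            parts = [p.strip() for p in str(lineage).split(";")] if str(lineage).strip() else []
            parts = [_RANK_PREFIX.sub("", p) for p in parts]
            lineages[taxon] = tuple(parts)
        return cls(lineages)

    def to_strings(self) -> dict[str, str]:
        return {t: ";".join(lin).rstrip(";") for t, lin in self.lineages.items()}


@dataclass
class StudyBundle:
    """A validated, cross-referenced study: counts + metadata (+ taxonomy, tree)."""

    count_table: CountTable
    samples: SampleTable
    taxonomy: TaxonomyTable = field(default_factory=lambda: TaxonomyTable({}))
    tree: TreeNode | None = None


# ---------------------------------------------------------------------------
# Readers / writers


def load_count_table(path: str | Path, dialect: str = "tsv") -> CountTable:
    """Load a taxa x samples count table (``tsv`` or read-only ``biom-json``)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
        if df.shape[1] == 0 or df.columns[0] != "taxon_id":
            raise FormatError(f"{path}: first column must be 'taxon_id'")
        sample_ids = list(df.columns[1:])
        taxon_ids = list(df["taxon_id"]) if len(df) else []
        raw = df.iloc[:, 1:].to_numpy(dtype=object) if len(df) else np.empty((0, len(sample_ids)))
        counts = np.empty(raw.shape, dtype=np.int64)
        for i in range(raw.shape[0]):
            for j in range(raw.shape[1]):
                try:
                    value = float(raw[i, j])
                except (TypeError, ValueError):
                    value = np.nan
                if not np.isfinite(value) or value != int(value) or value < 0:
                    raise FormatError(
                        f"{path}: invalid count {raw[i, j]!r} at row {taxon_ids[i]!r}, "
                        f"column {sample_ids[j]!r}"
                    )
                counts[i, j] = int(value)
        return CountTable(taxon_ids, sample_ids, counts)
    if dialect == "biom-json":
        with open(path) as handle:
            doc = json.load(handle)
        taxon_ids = [row["id"] for row in doc["rows"]]
        sample_ids = [col["id"] for col in doc["columns"]]
        counts = np.zeros((len(taxon_ids), len(sample_ids)), dtype=np.int64)
        if doc.get("matrix_type") == "sparse":
            for i, j, value in doc["data"]:
                counts[int(i), int(j)] = _as_int_count(value, path)
        else:
            for i, row in enumerate(doc["data"]):
                counts[i] = [_as_int_count(v, path) for v in row]
        return CountTable(taxon_ids, sample_ids, counts)
    raise ValueError(f"unknown dialect {dialect!r}")


def _as_int_count(value: float, path: Path) -> int:
    if value < 0 or value != int(value):
        raise FormatError(f"{path}: invalid count {value!r}")
    return int(value)


def write_count_table(table: CountTable, path: str | Path) -> None:
    frame = table.to_frame()
    frame.index.name = "taxon_id"
    frame.to_csv(path, sep="\t")


def load_sample_table(path: str | Path) -> SampleTable:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    return SampleTable(df)


def write_sample_table(samples: SampleTable, path: str | Path) -> None:
    samples.data.to_csv(path, sep="\t", index=False)


def load_taxonomy(path: str | Path) -> TaxonomyTable:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "taxon_id" not in df.columns or "lineage" not in df.columns:
        raise FormatError(f"{path}: taxonomy needs 'taxon_id' and 'lineage' columns")
    return TaxonomyTable.from_strings(dict(zip(df["taxon_id"], df["lineage"])))


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    strings = taxonomy.to_strings()
    pd.DataFrame({"taxon_id": list(strings), "lineage": list(strings.values())}).to_csv(
        path, sep="\t", index=False
    )


def load_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick phylogeny; branch lengths are mandatory (UniFrac
    is undefined without them)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise FormatError(f"{path}: newick parse error: {exc}") from exc
    missing = [node.name or "<internal>" for node in tree.traverse() if not node.is_root() and node.length is None]
    if missing:
        raise FormatError(
            f"{path}: branch lengths missing on {len(missing)} node(s); UniFrac is undefined"
        )
    if tree.length is None:
        tree.length = 0.0
    return tree


def total_branch_length(tree: TreeNode) -> float:
    return float(sum(node.length or 0.0 for node in tree.traverse()))


def assemble_bundle(
    counts: CountTable,
    samples: SampleTable,
    taxonomy: TaxonomyTable | None = None,
    tree: TreeNode | None = None,
) -> StudyBundle:
    """Cross-check all members and build a StudyBundle.

    Every mismatch is collected and reported at once. A taxon missing from
    the taxonomy is tolerated (warning, empty lineage); a sample missing from
    the metadata is not.
    """
    problems: list[str] = []
    meta_ids = set(samples.sample_ids)
    extra_samples = [s for s in counts.sample_ids if s not in meta_ids]
    if extra_samples:
        problems.append(f"samples in counts absent from metadata: {extra_samples}")
    if tree is not None:
        leaves = {leaf.name for leaf in tree.tips()}
        extra_taxa = [t for t in counts.taxon_ids if t not in leaves]
        if extra_taxa:
            problems.append(f"taxa in counts absent from tree: {extra_taxa[:10]}")
    if problems:
        raise IntegrityError("; ".join(problems))
    taxonomy = taxonomy if taxonomy is not None else TaxonomyTable({})
    unknown = [t for t in counts.taxon_ids if t not in taxonomy.lineages]
    if taxonomy.lineages and unknown:
        warnings.warn(
            f"{len(unknown)} taxa missing from taxonomy; empty lineages assigned", stacklevel=2
        )
    return StudyBundle(counts, samples, taxonomy, tree)
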