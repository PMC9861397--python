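"""Core in-memory containers for the bilayer methylation/RNA analysis.

All tabular data is held in pandas structures; the dataclasses below wrap
them with the validation rules every downstream stage relies on (β values in
[0, 1], unique identifiers, tumor/normal labels present, ...).  Probe
identifiers are normalised to lowercase ``cg...`` form on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"
VALID_GROUPS = frozenset({TUMOR, NORMAL})

RNA_TYPES = frozenset({"mRNA", "lncRNA", "miRNA", "other"})


class FormatError(ValueError):
    """Raised when an input file does not have the documented layout."""


class ValidationError(ValueError):
    """Raised when parsed data violates a container invariant."""


def normalize_site_id(site_id: str) -> str:
    """Lowercase probe IDs so 'Cg25080152' and 'cg25080152' are one site."""
    return str(site_id).strip().lower()


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dupes}")


def _check_groups(labels: pd.Series, require_both: bool = False) -> None:
    bad = set(labels) - VALID_GROUPS
    if bad:
        raise ValidationError(f"unknown group labels {sorted(bad)}; expected {sorted(VALID_GROUPS)}")
    if require_both and set(labels) != VALID_GROUPS:
        raise ValidationError("need at least one tumor and one normal sample")


@dataclass
class BetaMatrix:
    """Sites x samples methylation β values with tumor/normal sample labels.

    ``values`` is a DataFrame indexed by probe ID with sample columns; β is
    the methylated/total intensity ratio, dimensionless in [0, 1].
    """

    values: pd.DataFrame
    group_labels: pd.Series  # indexed by sample_id, values in {tumor, normal}

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = [normalize_site_id(s) for s in self.values.index]
        _check_unique(self.values.index, "site IDs")
        _check_unique(self.values.columns, "sample IDs")
        self.group_labels = self.group_labels.reindex(self.values.columns)
        if self.group_labels.isna().any():
            missing = self.group_labels.index[self.group_labels.isna()].tolist()[:5]
            raise ValidationError(f"samples without a tumor/normal label: {missing}")
        _check_groups(self.group_labels)
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            raise ValidationError("BetaMatrix may not contain missing values")
        if (arr < 0).any() or (arr > 1).any():
            i, j = np.argwhere((arr < 0) | (arr > 1))[0]
            raise ValidationError(
                f"β value {arr[i, j]!r} outside [0, 1] at site "
                f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}"
            )

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.group_labels.index[self.group_labels == group])

    def tumor_values(self) -> pd.DataFrame:
        return self.values[self.samples_in_group(TUMOR)]


@dataclass
class SiteGeneMap:
    """Many-to-many probe -> gene-symbol annotation (the inter-layer links)."""

    pairs: set[tuple[str, str]]
    _site_to_genes: dict[str, frozenset[str]] = field(init=False, repr=False)
    _gene_to_sites: dict[str, frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.pairs = {(normalize_site_id(s), str(g)) for s, g in self.pairs}
        s2g: dict[str, set[str]] = {}
        g2s: dict[str, set[str]] = {}
        for site, gene in self.pairs:
            s2g.setdefault(site, set()).add(gene)
            g2s.setdefault(gene, set()).add(site)
        self._site_to_genes = {k: frozenset(v) for k, v in s2g.items()}
        self._gene_to_sites = {k: frozenset(v) for k, v in g2s.items()}

    def genes_of(self, site_id: str) -> frozenset[str]:
        return self._site_to_genes.get(normalize_site_id(site_id), frozenset())

    def sites_of(self, gene: str) -> frozenset[str]:
        return self._gene_to_sites.get(gene, frozenset())

    @property
    def sites(self) -> frozenset[str]:
        return frozenset(self._site_to_genes)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._gene_to_sites)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class RnaInteractionTable:
    """Cleaned undirected RNA-RNA interaction rows.

    Columns: rna_a, rna_b, type_a, type_b, confidence.  Unordered duplicate
    pairs are collapsed keeping the maximum confidence; self-pairs are
    dropped at read time.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["rna_a", "rna_b", "type_a", "type_b", "confidence"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise FormatError(f"interaction table missing columns {missing}")
        conf = self.rows["confidence"].to_numpy(dtype=float)
        if len(conf) and ((conf < 0) | (conf > 1)).any():
            raise ValidationError("interaction confidence outside [0, 1]")
        if len(self.rows) and (self.rows["rna_a"] == self.rows["rna_b"]).any():
            raise ValidationError("self-interactions must be removed before construction")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def node_types(self) -> dict[str, str]:
        types: dict[str, str] = {}
        for _, r in self.rows.iterrows():
            types[r["rna_a"]] = r["type_a"]
            types[r["rna_b"]] = r["type_b"]
        return types


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression with tumor/normal labels."""

    values: pd.DataFrame
    group_labels: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene IDs")
        _check_unique(self.values.columns, "sample IDs")
        self.group_labels = self.group_labels.reindex(self.values.columns)
        if self.group_labels.isna().any():
            missing = self.group_labels.index[self.group_labels.isna()].tolist()[:5]
            raise ValidationError(f"samples without a tumor/normal label: {missing}")
        _check_groups(self.group_labels)
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.group_labels.index[self.group_labels == group])


@dataclass
class ClinicalTable:
    """Per-patient overall survival: (sample_id, time, event).

    ``event`` is 1 when death was observed and 0 for right-censoring.
    """

    rows: pd.DataFrame  # columns sample_id, time, event

    def __post_init__(self) -> None:
        required = ["sample_id", "time", "event"]
        missing = [c for c in required if c not in self.rows.columns]
        if missing:
            raise FormatError(f"clinical table missing columns {missing}")
        _check_unique(self.rows["sample_id"], "clinical sample IDs")
        if len(self.rows):
            if (self.rows["time"].to_numpy(dtype=float) < 0).any():
                raise ValidationError("survival times must be non-negative")
            if not set(self.rows["event"].astype(int)) <= {0, 1}:
                raise ValidationError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, sample_ids) -> "ClinicalTable":
        keep = self.rows["sample_id"].isin(set(sample_ids))
        return ClinicalTable(self.rows[keep].reset_index(drop=True))


@dataclass
class GeneSetCollection:
    """pathway_id -> (name, genes) plus the background gene universe."""

    sets: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        self.background = frozenset(self.background)
        clean: dict[str, tuple[str, frozenset[str]]] = {}
        for pid, (name, genes) in self.sets.items():
            genes = frozenset(genes)
            if not genes:
                raise ValidationError(f"pathway {pid!r} has an empty gene set")
            if not genes <= self.background:
                raise ValidationError(f"pathway {pid!r} contains genes outside the background")
            clean[pid] = (name, genes)
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)
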