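"""In-memory containers: abundance matrices, count tables, paired designs.

Both matrix containers wrap a features x samples :class:`pandas.DataFrame`
plus a per-sample metadata frame indexed by sample id with columns
``subject_id``, ``arm``, ``formulation``, ``timepoint`` and
``is_tech_replicate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

METADATA_COLUMNS = ("subject_id", "arm", "formulation", "timepoint",
                    "is_tech_replicate")


def _validate_metadata(values: pd.DataFrame, metadata: pd.DataFrame) -> None:
    if values.columns.duplicated().any():
        raise ValidationError("duplicate sample ids in value table")
    missing_cols = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing_cols:
        raise ValidationError(
            "metadata is missing required column(s): " + ", ".join(missing_cols))
    missing = [s for s in values.columns if s not in metadata.index]
    if missing:
        raise ValidationError(
            f"samples without metadata: {missing[:5]}{'...' if len(missing) > 5 else ''}")


@dataclass
class AbundanceMatrix:
    """Proteins x samples non-negative intensity table with sample metadata."""

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_metadata(self.values, self.metadata)
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative intensities are not allowed")
        self.metadata = self.metadata.loc[self.values.columns]

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def tech_replicate_ids(self) -> list[str]:
        flag = self.metadata["is_tech_replicate"].astype(bool)
        return list(self.metadata.index[flag])

    def study_sample_ids(self) -> list[str]:
        flag = self.metadata["is_tech_replicate"].astype(bool)
        return list(self.metadata.index[~flag])

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values[list(sample_ids)].copy(),
                               self.metadata.loc[list(sample_ids)].copy())

    def subset_features(self, feature_ids: Sequence[str]) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.loc[list(feature_ids)].copy(),
                               self.metadata.copy())

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.metadata.copy())


@dataclass
class TaxonCountTable:
    """Taxa x samples integer read-count table with sample metadata."""

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_metadata(self.counts, self.metadata)
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("negative counts are not allowed")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.metadata = self.metadata.loc[self.counts.columns]

    @property
    def taxon_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def depths(self) -> pd.Series:
        """Per-sample total read count."""
        return self.counts.sum(axis=0)

    def relative_abundance(self, pseudocount: float = 0.0) -> pd.DataFrame:
        num = self.counts + pseudocount
        return num / num.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "TaxonCountTable":
        return TaxonCountTable(self.counts[list(sample_ids)].copy(),
                               self.metadata.loc[list(sample_ids)].copy())

    def subset_taxa(self, taxon_ids: Sequence[str]) -> "TaxonCountTable":
        return TaxonCountTable(self.counts.loc[list(taxon_ids)].copy(),
                               self.metadata.copy())

    def pool_samples(self, sample_ids: Sequence[str], new_id: str,
                     template_meta: dict | None = None) -> "TaxonCountTable":
        """Sum counts of ``sample_ids`` into one pooled sample (reads pooled)."""
        pooled = self.counts[list(sample_ids)].sum(axis=1).rename(new_id)
        meta_row = self.metadata.loc[sample_ids[0]].to_dict()
        if template_meta:
            meta_row.update(template_meta)
        counts = pd.concat([self.counts, pooled], axis=1)
        metadata = pd.concat(
            [self.metadata, pd.DataFrame([meta_row], index=[new_id])])
        return TaxonCountTable(counts, metadata)


@dataclass(frozen=True)
class SamplePair:
    subject_id: str
    treatment: str
    control: str

    def __post_init__(self) -> None:
        if self.treatment == self.control:
            raise ValidationError(
                f"subject {self.subject_id}: treatment and control sample coincide")


@dataclass
class PairedDesign:
    """Per-subject (treatment, control) sample pairs for one comparison."""

    label: str
    pairs: list[SamplePair] = field(default_factory=list)

    def __post_init__(self) -> None:
        subjects = [p.subject_id for p in self.pairs]
        if len(subjects) != len(set(subjects)):
            raise ValidationError(f"{self.label}: duplicate subject in design")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def treatment_ids(self) -> list[str]:
        return [p.treatment for p in self.pairs]

    @property
    def control_ids(self) -> list[str]:
        return [p.control for p in self.pairs]

    def all_sample_ids(self) -> list[str]:
        out: list[str] = []
        for p in self.pairs:
            out.extend([p.treatment, p.control])
        return out

    @classmethod
    def from_tuples(cls, label: str,
                    tuples: Iterable[tuple[str, str, str]]) -> "PairedDesign":
        return cls(label, [SamplePair(*t) for t in tuples])
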