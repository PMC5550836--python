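"""Core in-memory containers.

The pipeline works on plain pandas objects wherever possible; the only
structured container is :class:`ExpressionMatrix`, which pairs a probe x sample
matrix of log2 intensities with its sample sheet (tissue, group, subject).
Contrast results, Ct tables and verdict tables are ordinary DataFrames whose
required columns are declared here as constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

#: Columns of a contrast table (index = gene/probe id).
CONTRAST_COLUMNS = ("mean_a", "mean_b", "t", "p", "fc", "sign")

#: Smallest p-value ever reported; keeps -log10(p) finite downstream.
MIN_P = float(np.finfo(float).tiny)


@dataclass
class ExpressionMatrix:
    """Probe/gene x sample matrix of log2 intensities plus a sample sheet.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, rows indexed by probe/gene id and
        columns by sample id.
    samples
        Sample sheet indexed by sample id with columns ``tissue``, ``group``
        and ``subject``.  Blood and brain matrices are kept separate, so the
        tissue must be uniform within one matrix.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise DataError(f"duplicate sample ids: {dupes}")
        missing = [c for c in ("tissue", "group", "subject") if c not in self.samples.columns]
        if missing:
            raise DataError(f"sample sheet lacks columns: {missing}")
        if set(self.values.columns) != set(self.samples.index):
            extra = set(self.values.columns) ^ set(self.samples.index)
            raise DataError(f"matrix columns and sample sheet disagree on: {sorted(extra)}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[:10]
            cells = [(self.values.index[i], self.values.columns[j]) for i, j in bad]
            raise DataError(f"non-finite values at cells (first 10): {cells}")
        tissues = self.samples["tissue"].unique()
        if len(tissues) > 1:
            raise DataError(f"matrix mixes tissues {sorted(tissues)}; normalize tissues separately")

    # -- convenience -----------------------------------------------------

    @property
    def tissue(self) -> str:
        return str(self.samples["tissue"].iloc[0])

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_samples(self, group: str) -> list[str]:
        """Sample ids belonging to one design group."""
        return self.samples.index[self.samples["group"] == group].tolist()

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.group_samples(group)]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        unknown = [s for s in sample_ids if s not in self.samples.index]
        if unknown:
            raise DataError(f"unknown sample ids: {unknown}")
        return ExpressionMatrix(
            values=self.values[sample_ids].copy(),
            samples=self.samples.loc[sample_ids].copy(),
        )

    def with_groups(self, relabel: pd.Series) -> "ExpressionMatrix":
        """Return a copy whose sample sheet ``group`` column follows ``relabel``
        (indexed by subject id); subjects not present keep their label."""
        samples = self.samples.copy()
        mapped = samples["subject"].map(relabel)
        samples["group"] = mapped.where(mapped.notna(), samples["group"])
        return ExpressionMatrix(values=self.values.copy(), samples=samples)


def validate_contrast_table(table: pd.DataFrame, name: str = "contrast") -> None:
    """Check the ContrastTable invariants (FC > 0, p in (0,1], sign in {-1,+1})."""
    missing = [c for c in CONTRAST_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"{name} table lacks columns {missing}")
    if (table["fc"] <= 0).any():
        raise DataError(f"{name} table has non-positive fold changes")
    if ((table["p"] <= 0) | (table["p"] > 1)).any():
        raise DataError(f"{name} table has p-values outside (0, 1]")
    if (~table["sign"].isin([-1, 1])).any():
        raise DataError(f"{name} table has signs outside {{-1,+1}}")


@dataclass
class PlantedTruth:
    """Ground-truth labels attached to a simulated dataset.

    ``gene_classes`` maps gene id to one of {null, stress_only, stress_reversal,
    flx_only, concordant_up, concordant_down, discordant_blood_brain};
    ``mouse_status`` maps mouse id to {susceptible, resilient, responder,
    nonresponder}; ``human_gene_classes`` maps gene symbol to {null, trait,
    state, prediction}.
    """

    gene_classes: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    mouse_status: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    human_gene_classes: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def genes_of_class(self, label: str) -> list[str]:
        return self.gene_classes.index[self.gene_classes == label].tolist()

    def human_genes_of_class(self, label: str) -> list[str]:
        return self.human_gene_classes.index[self.human_gene_classes == label].tolist()
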