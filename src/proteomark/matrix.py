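"""Protein abundance matrix with a two-group sample annotation.

The universal input of the pipeline: a nonnegative proteins x samples table
(label-free abundances, arbitrary units) whose columns are annotated as
``case`` or ``control``. Rows are identified by UniProt proteoform accessions
(isoforms carry a dash suffix, e.g. ``P14618-2``). Non-detected proteins are
encoded as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError

CASE = "case"
CONTROL = "control"
VALID_GROUPS = frozenset({CASE, CONTROL})


@dataclass
class AbundanceMatrix:
    """Nonnegative abundance table (proteins x samples) plus group labels.

    Parameters
    ----------
    values
        DataFrame indexed by proteoform accession, one column per sample.
    groups
        Maps each sample ID to ``"case"`` or ``"control"``. Both groups must
        be non-empty and every sample column must be annotated.
    """

    values: pd.DataFrame
    groups: pd.Series = field()

    def __init__(self, values: pd.DataFrame, groups: Mapping[str, str] | pd.Series):
        values = pd.DataFrame(values)
        groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise InputError(f"duplicate accession {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise InputError(f"duplicate sample ID {dup!r}")
        missing = [s for s in values.columns if s not in groups.index]
        if missing:
            raise InputError(f"samples without group annotation: {missing[:5]}")
        groups = groups.reindex(values.columns)
        bad = set(groups.unique()) - VALID_GROUPS
        if bad:
            raise InputError(f"unknown group labels {sorted(bad)}; expected case/control")
        if (groups == CASE).sum() == 0 or (groups == CONTROL).sum() == 0:
            raise InputError("both groups (case, control) must be non-empty")
        arr = values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise InputError("abundance values must be finite")
        if (arr < 0).any():
            raise InputError("abundance values must be nonnegative")
        self.values = values.astype(float)
        self.groups = groups

    # -- convenience accessors -------------------------------------------------

    @property
    def accessions(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CONTROL])

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def case_array(self) -> np.ndarray:
        """Abundances of the case samples, proteins x n_cases."""
        return self.values[self.case_samples].to_numpy(dtype=float)

    def control_array(self) -> np.ndarray:
        """Abundances of the control samples, proteins x n_controls."""
        return self.values[self.control_samples].to_numpy(dtype=float)

    def group_indicator(self) -> np.ndarray:
        """0/1 vector over samples (1 = case), the PLS-DA response coding."""
        return (self.groups.to_numpy() == CASE).astype(float)

    # -- I/O -------------------------------------------------------------------

    @classmethod
    def from_tsv(cls, abundance_path: str | Path, annotation_path: str | Path) -> "AbundanceMatrix":
        """Read the abundance TSV (first column ``accession``) and the
        two-column sample annotation TSV (``sample_id``, ``group``)."""
        values = pd.read_csv(abundance_path, sep="\t", index_col="accession")
        ann = pd.read_csv(annotation_path, sep="\t")
        groups = pd.Series(ann["group"].to_numpy(), index=ann["sample_id"].to_numpy())
        return cls(values, groups)

    def to_tsv(self, abundance_path: str | Path, annotation_path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "accession"
        out.to_csv(abundance_path, sep="\t", float_format="%.10g")
        ann = pd.DataFrame({"sample_id": self.sample_ids, "group": self.groups.to_numpy()})
        ann.to_csv(annotation_path, sep="\t", index=False)
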