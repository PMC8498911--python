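"""Shared in-memory containers for expression data and regulons.

Expression values are log2-scale, genes in rows and samples in columns,
held in a :class:`pandas.DataFrame` with an accompanying per-sample
metadata table (``group``, ``batch``, ``cohort``).  Regulons pair a
transcription factor with a signed mode of regulation (``mor``) and a
confidence weight (``likelihood``) per target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_TREATED = "treated"
GROUP_CONTROL = "control"
GROUP_UNLABELED = "unlabeled"

META_COLUMNS = ("group", "batch", "cohort")


def _default_meta(sample_ids) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": GROUP_UNLABELED,
            "batch": "batch0",
            "cohort": "cohort0",
        },
        index=pd.Index(sample_ids, name="sample"),
    )


@dataclass
class ExpressionMatrix:
    """Log2 expression, genes x samples, with per-sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with one column per sample.
    sample_meta
        DataFrame indexed by sample ID with columns ``group``
        (``treated`` / ``control`` / ``unlabeled``), ``batch`` and
        ``cohort``.  Defaults to unlabeled single-batch metadata.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite (apply a missingness policy at load)")
        if self.sample_meta is None:
            self.sample_meta = _default_meta(self.values.columns)
        else:
            missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
            if missing:
                raise ValueError(f"sample_meta missing columns: {missing}")
            if set(self.sample_meta.index) != set(self.values.columns):
                raise ValueError("sample_meta index must match expression columns")
            self.sample_meta = self.sample_meta.loc[self.values.columns, list(META_COLUMNS)]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        mask = self.sample_meta["group"] == group
        return list(self.sample_meta.index[mask])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(
            self.values[sample_ids].copy(), self.sample_meta.loc[sample_ids].copy()
        )


@dataclass
class Regulon:
    """A TF and its targets with mode of regulation and confidence.

    ``targets`` is indexed by target gene ID with columns ``mor``
    (signed, in [-1, 1]) and ``likelihood`` (in (0, 1]).
    """

    tf: str
    targets: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.targets.empty:
            self.targets = pd.DataFrame(columns=["mor", "likelihood"])
            return
        if self.tf in self.targets.index:
            raise ValueError(f"regulon for {self.tf} contains the TF itself as a target")
        if self.targets.index.has_duplicates:
            raise ValueError(f"duplicate targets in regulon {self.tf}")
        mor = self.targets["mor"].to_numpy(dtype=float)
        lik = self.targets["likelihood"].to_numpy(dtype=float)
        if np.any(np.abs(mor) > 1 + 1e-12):
            raise ValueError(f"mor outside [-1, 1] in regulon {self.tf}")
        if np.any(lik <= 0) or np.any(lik > 1 + 1e-12):
            raise ValueError(f"likelihood outside (0, 1] in regulon {self.tf}")

    @property
    def size(self) -> int:
        return len(self.targets)
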