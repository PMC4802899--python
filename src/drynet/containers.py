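"""Core in-memory containers for omics matrices and their sample metadata.

The central object is :class:`OmicsMatrix`, a features x samples table of
strictly positive abundances together with per-sample design metadata
(treatment C/D, developmental stage in days after anthesis, replicate index).
It deliberately mirrors a minimal SummarizedExperiment: a values frame plus a
column-annotation frame, kept in lock-step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

TREATMENTS = ("C", "D")

METADATA_COLUMNS = ("treatment", "stage_daa", "replicate")


class OmicsMatrixError(ValueError):
    """Raised when a matrix violates its structural invariants."""


@dataclass
class OmicsMatrix:
    """Features x samples positive abundance matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns are sample ids. All entries
        must be finite and strictly positive.
    metadata
        DataFrame indexed by sample id with columns ``treatment`` (``C`` or
        ``D``), ``stage_daa`` (int) and ``replicate`` (int). Must cover every
        sample column of ``values``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise OmicsMatrixError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise OmicsMatrixError("duplicate sample ids")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
            raise OmicsMatrixError("abundances must be finite and > 0")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise OmicsMatrixError(f"metadata missing for samples: {sorted(missing)[:5]}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise OmicsMatrixError(f"metadata lacks column {col!r}")
        bad = set(self.metadata["treatment"]) - set(TREATMENTS)
        if bad:
            raise OmicsMatrixError(f"unknown treatments: {sorted(bad)}")

    # ------------------------------------------------------------------ views
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_for(self, treatment: str | None = None, stage_daa: int | None = None) -> list[str]:
        """Sample ids matching a treatment and/or a stage, in column order."""
        meta = self.metadata.loc[self.sample_ids]
        mask = pd.Series(True, index=meta.index)
        if treatment is not None:
            mask &= meta["treatment"] == treatment
        if stage_daa is not None:
            mask &= meta["stage_daa"] == stage_daa
        return list(meta.index[mask])

    def stages(self) -> list[int]:
        meta = self.metadata.loc[self.sample_ids]
        return sorted(int(s) for s in meta["stage_daa"].unique())

    def subset_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        return OmicsMatrix(
            values=self.values.loc[:, sample_ids].copy(),
            metadata=self.metadata.loc[sample_ids].copy(),
        )

    def feature(self, feature_id: str) -> np.ndarray:
        if feature_id not in self.values.index:
            raise KeyError(f"unknown feature {feature_id!r}")
        return self.values.loc[feature_id].to_numpy(dtype=float)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, values_path: str | Path, metadata_path: str | Path) -> None:
        vp, mp = Path(values_path), Path(metadata_path)
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(vp, sep="\t", lineterminator="\n")
        meta = self.metadata.loc[self.sample_ids].copy()
        meta.index.name = "sample_id"
        meta.to_csv(mp, sep="\t", lineterminator="\n")

    @classmethod
    def read_tsv(cls, values_path: str | Path, metadata_path: str | Path) -> "OmicsMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0,
                             float_precision="round_trip")
        values.index = values.index.astype(str)
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
        metadata.index = metadata.index.astype(str)
        return cls(values=values, metadata=metadata)
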