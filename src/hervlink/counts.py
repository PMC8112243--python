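"""Feature-by-sample count matrices with case/control sample metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("case", "control")


@dataclass
class CountMatrix:
    """Non-negative integer counts, features x samples.

    ``sample_meta`` is indexed by sample id and carries at least a
    ``condition`` column ({case, control}) and a ``dataset`` label.
    """

    counts: pd.DataFrame  # index: feature ids, columns: sample ids
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.sample_meta.empty:
            self.sample_meta = pd.DataFrame(
                {"condition": "case", "dataset": "d1"}, index=self.counts.columns
            )
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        bad = set(self.sample_meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        self.sample_meta = self.sample_meta.loc[self.counts.columns]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def condition_mask(self, condition: str) -> np.ndarray:
        return (self.sample_meta["condition"] == condition).to_numpy()

    def subset_features(self, feature_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(feature_ids)], self.sample_meta.copy())

    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=np.float64)


def read_counts(tsv_path, meta_path, na_token: str = "NA") -> CountMatrix:
    """Read a counts TSV (first column feature ids, header sample ids) plus a
    metadata TSV (sample id, condition, dataset).

    Cells equal to ``na_token`` become zero. Any other non-numeric cell and
    any counts sample absent from the metadata are hard errors.
    """
    raw = pd.read_csv(tsv_path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw = raw.replace(na_token, "0")
    try:
        counts = raw.astype(np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric count cell in {tsv_path}: {exc}") from exc
    if not np.allclose(counts.to_numpy(), np.round(counts.to_numpy())):
        raise ValueError(f"non-integer counts in {tsv_path}")
    counts = counts.round().astype(np.int64)
    counts.index.name = None
    counts.columns.name = None

    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    missing = set(counts.columns) - set(meta.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    return CountMatrix(counts, meta.loc[counts.columns])


def write_counts(cm: CountMatrix, tsv_path, meta_path=None) -> None:
    cm.counts.to_csv(tsv_path, sep="\t", index_label="feature_id")
    if meta_path is not None:
        cm.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")
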