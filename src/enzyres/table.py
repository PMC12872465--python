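"""Samples-by-features tables with input metadata.

A :class:`FeatureTable` is a thin wrapper around a pandas DataFrame in
which metadata columns carry a ``meta_`` prefix (``meta_s1_uM``,
``meta_T_C``, ``meta_pH``, ``meta_light_period_s``, ...) and every other
column is a measured feature named by its fragment sequence.  Round-trips
through delimited text exactly for metadata and to full float precision
for features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

META_PREFIX = "meta_"


@dataclass
class FeatureTable:
    data: pd.DataFrame

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if not c.startswith(META_PREFIX)]

    @property
    def meta_names(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith(META_PREFIX)]

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def metadata(self) -> pd.DataFrame:
        return self.data[self.meta_names]

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_samples(cls, rows: list[tuple[dict, pd.Series]]) -> "FeatureTable":
        """Build from (metadata dict, feature Series) pairs."""
        records = []
        for meta, feats in rows:
            rec = {f"{META_PREFIX}{k}" if not k.startswith(META_PREFIX) else k: v
                   for k, v in meta.items()}
            rec.update(feats.to_dict())
            records.append(rec)
        return cls(pd.DataFrame.from_records(records))

    def select_features(self, names: list[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return FeatureTable(self.data[self.meta_names + list(names)])

    def write_csv(self, path, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path, sep: str = "\t") -> "FeatureTable":
        return cls(pd.read_csv(path, sep=sep))
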