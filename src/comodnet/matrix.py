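"""Expression-matrix container shared by all stages.

Rows are spots (replicate probes) or features, columns are samples. The
container records the measurement scale ("intensity" or "log2"), optional
per-spot flags (bad spots excluded from replicate medians) and an optional
replicate map from spot IDs to feature IDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InputError

SCALES = ("intensity", "log2")


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame
    scale: str = "intensity"
    flags: pd.DataFrame | None = None
    replicate_map: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise InputError(f"scale must be one of {SCALES}, got {self.scale!r}")
        cols = self.values.columns
        if cols.duplicated().any():
            raise InputError("duplicate sample IDs")
        if self.values.index.duplicated().any():
            raise InputError("duplicate spot/feature IDs")
        if self.flags is not None:
            if self.flags.shape != self.values.shape:
                raise InputError("flags shape does not match values shape")
            self.flags = self.flags.astype(bool)
            self.flags.index = self.values.index
            self.flags.columns = self.values.columns
            unflagged = self.values.values[~self.flags.values]
        else:
            unflagged = self.values.values
        # NaN marks a missing value (e.g. all replicates flagged); infinities
        # are always data errors
        if np.isinf(np.asarray(unflagged, dtype=float)).any():
            raise InputError("infinite values in unflagged entries")
        if self.replicate_map is not None:
            missing = set(self.values.index) - set(self.replicate_map.index)
            if missing:
                raise InputError(f"spots missing from replicate map: {sorted(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, **kwargs) -> "ExpressionMatrix":
        """Copy with new values (and optionally new scale/flags/replicate_map)."""
        return replace(self, values=values, **kwargs)
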