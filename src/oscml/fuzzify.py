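"""Triangular three-set fuzzification fitted on training data only.

Every crisp feature X gets three linguistic terms with triangular
memberships anchored at the training minimum, midpoint and maximum:

* ``X_low``    — 1 at X_min, falling linearly to 0 at the midpoint;
* ``X_medium`` — 0 at X_min, peaking at 1 on the midpoint, back to 0 at X_max;
* ``X_high``   — 0 at the midpoint, rising linearly to 1 at X_max;

with midpoint = (X_min + X_max) / 2.  Values outside the training support
are clipped to it before evaluation, so an unseen test value below X_min
fuzzifies exactly like X_min.  The three memberships always sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FuzzificationScheme", "fit_scheme", "transform", "fuzzy_column_names"]

_SUFFIXES = ("low", "medium", "high")


def fuzzy_column_names(crisp_names) -> list[str]:
    """Fuzzy column order: per crisp feature, its low/medium/high terms."""
    return [f"{name}_{suf}" for name in crisp_names for suf in _SUFFIXES]


@dataclass(frozen=True)
class FuzzificationScheme:
    """Per-feature training min/max anchoring the triangular memberships."""

    x_min: pd.Series
    x_max: pd.Series

    def __post_init__(self) -> None:
        bad = self.x_max <= self.x_min
        if bad.any():
            name = bad.idxmax()
            raise ValueError(
                f"feature {name!r} has zero-width support "
                f"[{self.x_min[name]}, {self.x_max[name]}]; cannot fuzzify a constant"
            )

    @property
    def midpoint(self) -> pd.Series:
        return (self.x_min + self.x_max) / 2.0

    @property
    def feature_names(self) -> list[str]:
        return list(self.x_min.index)


def fit_scheme(training: pd.DataFrame) -> FuzzificationScheme:
    """Learn the per-feature support from training rows only."""
    if training.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit a fuzzification scheme")
    return FuzzificationScheme(x_min=training.min(axis=0), x_max=training.max(axis=0))


def transform(scheme: FuzzificationScheme, table: pd.DataFrame) -> pd.DataFrame:
    """Fuzzify a feature table: each crisp column becomes three memberships.

    Columns of ``table`` must all be known to the scheme; output columns are
    ``<feature>_low, <feature>_medium, <feature>_high`` in the crisp column
    order.  Out-of-support values are clipped to the support first.
    """
    unknown = [c for c in table.columns if c not in scheme.x_min.index]
    if unknown:
        raise ValueError(f"features not in the fuzzification scheme: {unknown}")
    out = {}
    for name in table.columns:
        lo = float(scheme.x_min[name])
        hi = float(scheme.x_max[name])
        mid = (lo + hi) / 2.0
        x = np.clip(table[name].to_numpy(dtype=float), lo, hi)
        low = np.where(x <= mid, (mid - x) / (mid - lo), 0.0)
        high = np.where(x >= mid, (x - mid) / (hi - mid), 0.0)
        out[f"{name}_low"] = low
        out[f"{name}_medium"] = 1.0 - low - high
        out[f"{name}_high"] = high
    return pd.DataFrame(out, index=table.index)[fuzzy_column_names(table.columns)]
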