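"""Sequencing-effort-normalized spacer abundance and metadata correlations.

Two normalizations are exposed, selected by input type.  Read-level
surveys report spacer counts per Mbp of raw reads; contig-level surveys
report normalized spacer abundance (NSA): the cumulative per-spacer mean
read depth divided by mapped read Gbp, the only reading under which
"spacers per read gigabase pair" is dimensionally sensible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SampleStats:
    sample_id: str
    total_read_bases: int = 0
    mapped_read_bases: int = 0
    n_spacers: int = 0
    cumulative_spacer_coverage: float = 0.0
    mean_gc: float = float("nan")
    depth_m: float = float("nan")
    nsa: float = 0.0

    def __post_init__(self) -> None:
        if self.mapped_read_bases > self.total_read_bases > 0:
            raise ValueError("mapped_read_bases exceeds total_read_bases")


def spacers_per_mbp(n_spacers: int, total_read_bases: int) -> float:
    """Spacer count per megabase pair of sequenced reads."""
    if total_read_bases <= 0:
        raise ZeroDivisionError("total_read_bases must be positive")
    return n_spacers / (total_read_bases / 1e6)


def normalized_spacer_abundance(spacer_depths: Sequence[float],
                                mapped_read_bases: int) -> float:
    """Cumulative spacer coverage divided by mapped read Gbp."""
    if mapped_read_bases <= 0:
        raise ZeroDivisionError("mapped_read_bases must be positive")
    return float(sum(spacer_depths)) / (mapped_read_bases / 1e9)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata table: sample_id, lat, lon, depth_m, total_read_bases."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "lat", "lon", "depth_m", "total_read_bases"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns {sorted(missing)}")
    return df


def sample_stats_table(stats_list: Iterable[SampleStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in stats_list])


def write_sample_stats(stats_list: Iterable[SampleStats],
                       path: str | Path) -> None:
    sample_stats_table(stats_list).to_csv(path, sep="\t", index=False)
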