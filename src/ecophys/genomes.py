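"""Genome-cohort bookkeeping for partial genomes (isolates, SAGs, MAGs).

Estimated complete genome size extrapolates an assembly length by its
completeness (consumed from upstream CheckM-style output, never computed
here); cohort summaries report medians and ranges of estimated size, GC
content, and coding density.  Base pairs are kept as exact integers
internally; megabase rounding happens only at report time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenomeRecord", "estimated_complete_size", "cohort_summary"]


def estimated_complete_size(length: int, completeness: float) -> int:
    """Estimated complete genome size in bp: length / (completeness/100).

    ``completeness`` is a percentage in (0, 100]; the result is rounded to
    the nearest bp and is never smaller than the assembly length.
    """
    if not 0 < completeness <= 100:
        raise ValueError("completeness must be in (0, 100]")
    if length <= 0:
        raise ValueError("assembly length must be positive")
    return int(round(length / (completeness / 100.0)))


@dataclass(frozen=True)
class GenomeRecord:
    """One genome's assembly and quality metrics."""

    name: str
    assembly_length: int    # bp
    completeness: float     # %
    contamination: float = 0.0  # %
    gc: float = float("nan")             # %
    coding_density: float = float("nan")  # %
    subclade: str = ""

    def __post_init__(self):
        if not 0 < self.completeness <= 100:
            raise ValueError(f"{self.name}: completeness must be in (0, 100]")
        if self.assembly_length <= 0:
            raise ValueError(f"{self.name}: assembly length must be positive")

    @property
    def estimated_size(self) -> int:
        return estimated_complete_size(self.assembly_length, self.completeness)


def cohort_summary(records) -> pd.DataFrame:
    """Medians and ranges of estimated size, GC, and coding density.

    ``records`` is a list of :class:`GenomeRecord` or a DataFrame with the
    corresponding columns.  Median is the usual order statistic (mean of the
    central pair for even n).  Returns a metric × (median, min, max) frame;
    estimated size rows are in Mbp (exact bp arithmetic underneath, 2-decimal
    rounding left to the caller/report).
    """
    if isinstance(records, pd.DataFrame):
        records = [
            GenomeRecord(
                name=str(r.get("name", i)),
                assembly_length=int(r["assembly_length"]),
                completeness=float(r["completeness"]),
                contamination=float(r.get("contamination", 0.0)),
                gc=float(r.get("gc", float("nan"))),
                coding_density=float(r.get("coding_density", float("nan"))),
                subclade=str(r.get("subclade", "")),
            )
            for i, r in records.iterrows()
        ]
    if len(records) == 0:
        raise ValueError("empty genome cohort")
    est_mbp = np.array([r.estimated_size for r in records], dtype=float) / 1e6
    gc = np.array([r.gc for r in records], dtype=float)
    cd = np.array([r.coding_density for r in records], dtype=float)
    rows = {}
    for metric, values in [
        ("estimated_size_mbp", est_mbp),
        ("gc_percent", gc),
        ("coding_density_percent", cd),
    ]:
        ok = values[~np.isnan(values)]
        if ok.size:
            rows[metric] = {
                "median": float(np.median(ok)),
                "min": float(ok.min()),
                "max": float(ok.max()),
                "n": int(ok.size),
            }
        else:
            rows[metric] = {
                "median": float("nan"),
                "min": float("nan"),
                "max": float("nan"),
                "n": 0,
            }
    return pd.DataFrame(rows).T[["median", "min", "max", "n"]]
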