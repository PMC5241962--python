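"""Self-self FDR calibration of the detection operating point.

On a self-self hybridization both channels carry the same genome, so every
CNV call is a false positive by construction.  The FDR of a candidate
(tau, frac) cell is the fraction of tested genes called CNV, averaged over
the self-self arrays.  The grid search picks the most sensitive admissible
cell: smallest tau, then smallest frac, among cells whose pooled FDR stays
at or below the ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calling import min_significant
from .model import ArrayExperiment, DetectionParams, GeneTarget, RatioTable

__all__ = ["CalibrationGrid", "CalibrationError", "estimate_fdr", "grid_search"]


def _default_taus() -> Tuple[float, ...]:
    return tuple(sorted(abs(math.log2(k / 4)) for k in (3, 2, 1)))


def _default_fracs() -> Tuple[float, ...]:
    return (0.75, 0.83, 0.85, 0.90, 1.0)


@dataclass
class CalibrationGrid:
    """Candidate (tau, frac) cells for the self-self grid search."""

    taus: Tuple[float, ...] = field(default_factory=_default_taus)
    fracs: Tuple[float, ...] = field(default_factory=_default_fracs)

    def __post_init__(self) -> None:
        if not self.taus or not self.fracs:
            raise ValueError("calibration grid must be non-empty")
        if any(t < 0 for t in self.taus):
            raise ValueError("tau candidates must be non-negative")
        if any(not (0 <= f <= 1) for f in self.fracs):
            raise ValueError("frac candidates must lie in [0, 1]")
        self.taus = tuple(sorted(set(self.taus)))
        self.fracs = tuple(sorted(set(self.fracs)))


class CalibrationError(RuntimeError):
    """No grid cell met the FDR ceiling; carries the full report."""

    def __init__(self, message: str, report: pd.DataFrame):
        super().__init__(message)
        self.report = report


def _gene_vote_counts(
    table: RatioTable, genes: Sequence[GeneTarget], min_probes: int,
) -> pd.DataFrame:
    """Per testable gene: probe M arrays grouped once, reused per grid cell."""
    probe_gene = pd.Series(
        {p.probe_id: g.gene_id for g in genes for p in g.probes}, name="gene_id"
    )
    df = table.data.join(probe_gene, how="inner")
    sizes = df.groupby("gene_id").size()
    testable = sizes.index[sizes >= min_probes]
    return df[df["gene_id"].isin(testable)]


def _fdr_cell(
    grouped_tables: Sequence[pd.DataFrame], tau: float, frac: float,
) -> Tuple[float, List[int], List[int]]:
    """Pooled FDR of one (tau, frac) cell; returns (fdr, called, tested)."""
    called_counts, tested_counts = [], []
    for df in grouped_tables:
        m = df["M"].to_numpy()
        gains = pd.Series(m > tau).groupby(df["gene_id"].to_numpy()).sum()
        losses = pd.Series(m < -tau).groupby(df["gene_id"].to_numpy()).sum()
        sizes = df.groupby("gene_id").size()
        n_sig = np.maximum(gains.to_numpy(), losses.to_numpy())
        need = np.array([min_significant(n, frac) for n in sizes.to_numpy()])
        called_counts.append(int((n_sig >= need).sum()))
        tested_counts.append(int(len(sizes)))
    per_array = [c / t if t else 0.0 for c, t in zip(called_counts, tested_counts)]
    pooled = float(np.mean(per_array)) if per_array else 0.0
    return pooled, called_counts, tested_counts


def estimate_fdr(
    tables: Sequence[RatioTable], experiments: Sequence[ArrayExperiment],
    genes: Sequence[GeneTarget], params: DetectionParams,
) -> Dict:
    """Estimate per-array and pooled FDR of ``params`` on self-self arrays.

    Every input array must be flagged self-self; any other array raises.
    The denominator is genes tested per array; the pooled estimate is the
    mean of the per-array rates.
    """
    by_id = {e.array_id: e for e in experiments}
    for t in tables:
        exp = by_id.get(t.array_id)
        if exp is None:
            raise ValueError(f"no metadata for array {t.array_id}")
        if not exp.self_self:
            raise ValueError(
                f"array {t.array_id} is not a self-self hybridization"
            )
    grouped = [_gene_vote_counts(t, genes, params.min_probes) for t in tables]
    pooled, called, tested = _fdr_cell(grouped, params.tau, params.frac)
    return {
        "pooled": pooled,
        "per_array": {
            t.array_id: (c / n if n else 0.0)
            for t, c, n in zip(tables, called, tested)
        },
        "called": dict(zip((t.array_id for t in tables), called)),
        "tested": dict(zip((t.array_id for t in tables), tested)),
    }


def grid_search(
    tables: Sequence[RatioTable], experiments: Sequence[ArrayExperiment],
    genes: Sequence[GeneTarget], grid: Optional[CalibrationGrid] = None,
    fdr_ceiling: float = 0.01, min_probes: int = 6,
) -> Tuple[DetectionParams, pd.DataFrame]:
    """Evaluate the FDR of every grid cell and choose the operating point.

    Among admissible cells (pooled FDR <= ceiling) the smallest tau wins,
    ties broken by the smallest frac — the most sensitive admissible point.
    Raises :class:`CalibrationError` (with the full report attached) when no
    cell is admissible.
    """
    grid = grid or CalibrationGrid()
    by_id = {e.array_id: e for e in experiments}
    for t in tables:
        exp = by_id.get(t.array_id)
        if exp is None or not exp.self_self:
            raise ValueError(f"array {t.array_id} is not a self-self hybridization")
    grouped = [_gene_vote_counts(t, genes, min_probes) for t in tables]
    rows = []
    for tau in grid.taus:
        for frac in grid.fracs:
            pooled, called, tested = _fdr_cell(grouped, tau, frac)
            rows.append(
                {
                    "tau": tau,
                    "frac": frac,
                    "fdr": pooled,
                    "called_total": int(sum(called)),
                    "tested_total": int(sum(tested)),
                    "admissible": pooled <= fdr_ceiling,
                }
            )
    report = pd.DataFrame(rows)
    admissible = report[report["admissible"]]
    if admissible.empty:
        best = report.sort_values(["fdr", "tau", "frac"]).iloc[0]
        raise CalibrationError(
            f"no grid cell achieved FDR <= {fdr_ceiling}; best was "
            f"(tau={best['tau']:.4g}, frac={best['frac']:.4g}) "
            f"with FDR {best['fdr']:.4g}",
            report,
        )
    chosen = admissible.sort_values(["tau", "frac"]).iloc[0]
    params = DetectionParams(
        tau=float(chosen["tau"]), frac=float(chosen["frac"]),
        min_probes=min_probes,
    )
    return params, report
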