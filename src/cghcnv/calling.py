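"""Probe-threshold + gene-voting CNV calls on corrected log2 ratios.

A probe is significant when its |M| strictly exceeds tau.  A gene is called
a CNV when the count of significant probes of the majority sign reaches
``ceil(frac * n_probes)``; mixed-sign genes therefore need a consistent
majority to be called.  Called genes whose |median M| strictly exceeds
``pav_tau`` are flagged as presence/absence variations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import DetectionParams, GeneCall, GeneTarget, RatioTable

__all__ = [
    "probe_significant",
    "min_significant",
    "call_gene",
    "call_array",
    "UntestedGene",
]

_CEIL_EPS = 1e-9


class UntestedGene(ValueError):
    """Raised when a gene has too few probes to be tested."""


def probe_significant(m: float, tau: float) -> str:
    """Classify one probe ratio: 'gain' (m > tau), 'loss' (m < -tau), 'none'.

    Both inequalities are strict; m equal to tau is not significant.
    """
    if m > tau:
        return "gain"
    if m < -tau:
        return "loss"
    return "none"


def min_significant(n_probes: int, frac: float) -> int:
    """Minimum consistent-sign significant probe count: ``ceil(frac * n)``.

    A small epsilon guards against float products like 0.83 * 100
    landing epsilon above the true integer.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    return max(0, math.ceil(frac * n_probes - _CEIL_EPS))


def call_gene(
    array_id: str, gene_id: str, probe_ms: Sequence[float],
    params: DetectionParams,
) -> GeneCall:
    """Vote probe-level significances into a per-gene CNV decision."""
    m = np.asarray(probe_ms, dtype=float)
    n = len(m)
    if n < params.min_probes:
        raise UntestedGene(
            f"gene {gene_id} on {array_id}: {n} probes < min {params.min_probes}"
        )
    gains = int((m > params.tau).sum())
    losses = int((m < -params.tau).sum())
    n_significant = max(gains, losses)
    majority = "gain" if gains >= losses else "loss"
    is_cnv = n_significant >= min_significant(n, params.frac)
    median_m = float(np.median(m))
    is_pav = bool(is_cnv and abs(median_m) > params.pav_tau)
    return GeneCall(
        array_id=array_id,
        gene_id=gene_id,
        n_probes=n,
        n_significant=n_significant,
        direction=majority if is_cnv else "none",
        median_m=median_m,
        is_cnv=is_cnv,
        is_pav=is_pav,
    )


def call_array(
    table: RatioTable, genes: Sequence[GeneTarget], params: DetectionParams,
) -> Tuple[List[GeneCall], List[str]]:
    """Call every testable gene on one array.

    Returns ``(calls, untested)`` where ``untested`` lists gene ids whose
    retained probe count fell below ``params.min_probes`` (these are not
    negatives).  Genes without a single retained probe are also untested.
    """
    probe_gene = pd.Series(
        {p.probe_id: g.gene_id for g in genes for p in g.probes}, name="gene_id"
    )
    df = table.data.join(probe_gene, how="inner")
    calls: List[GeneCall] = []
    untested: List[str] = []
    grouped: Dict[str, np.ndarray] = {
        gid: sub["M"].to_numpy() for gid, sub in df.groupby("gene_id", sort=True)
    }
    for g in genes:
        m = grouped.get(g.gene_id)
        if m is None or len(m) < params.min_probes:
            untested.append(g.gene_id)
            continue
        calls.append(call_gene(table.array_id, g.gene_id, m, params))
    return calls, untested
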