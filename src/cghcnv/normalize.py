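"""Two-channel normalization: M/A computation and per-array bias corrections.

Stages: ``raw`` (background-subtracted M/A) -> ``loess`` (intensity-dependent
dye bias removed on the M-A plot) -> ``gc`` (GC-content wave removed) ->
``composition`` (linear probe-composition effect removed).  All fits are
per array; biases are array-specific.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .model import ArrayExperiment, GeneTarget, InvariantError, RatioTable

__all__ = [
    "compute_ma",
    "loess_dye_correct",
    "gc_correct",
    "composition_correct",
    "normalize_experiment",
]

logger = logging.getLogger(__name__)

DEFAULT_SPAN = 0.3
DEFAULT_ROBUST_ITERS = 3
DEFAULT_ORDER = ("loess", "gc", "composition")


def compute_ma(experiment: ArrayExperiment) -> RatioTable:
    """Background-subtract both channels and compute per-probe M and A.

    ``M = log2(I1/I2)`` and ``A = log2(sqrt(I1*I2))`` with I1 the test and
    I2 the reference channel.  Probes with a non-positive
    background-subtracted intensity in either channel are dropped (their
    count is logged and recorded on the table).  On dye-swap arrays M is
    sign-flipped back to the test-vs-reference convention.
    """
    probe_ids = list(experiment.measurements)
    vals = np.array([experiment.measurements[p] for p in probe_ids], dtype=float)
    i1 = vals[:, 0] - vals[:, 1]
    i2 = vals[:, 2] - vals[:, 3]
    ok = (i1 > 0) & (i2 > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info(
            "array %s: dropped %d probes with non-positive background-"
            "subtracted intensity", experiment.array_id, n_dropped,
        )
    i1, i2 = i1[ok], i2[ok]
    m = np.log2(i1 / i2)
    if experiment.dye_swap:
        m = -m
    a = 0.5 * np.log2(i1 * i2)
    data = pd.DataFrame(
        {"M": m, "A": a},
        index=pd.Index(np.asarray(probe_ids, dtype=object)[ok], name="probe_id"),
    )
    return RatioTable(experiment.array_id, data, stage="raw", n_dropped=n_dropped)


def _lowess_fit(y: np.ndarray, x: np.ndarray, span: float, iters: int) -> np.ndarray:
    """Robust locally weighted regression of y on x, evaluated at x."""
    span_eff = span
    # lowess needs a handful of points per window
    if len(x) * span_eff < 10:
        span_eff = min(1.0, 10 / len(x))
    delta = 0.01 * (float(np.max(x)) - float(np.min(x)))
    return lowess(
        y, x, frac=span_eff, it=iters, delta=delta, return_sorted=False,
    )


def loess_dye_correct(
    table: RatioTable, span: float = DEFAULT_SPAN,
    robust_iters: int = DEFAULT_ROBUST_ITERS,
) -> RatioTable:
    """Remove the intensity-dependent dye bias: ``M' = M - f(A)``.

    ``f`` is a robust LOESS fit of M on A for this array.
    """
    if not (0 < span <= 1):
        raise ValueError(f"span must be in (0, 1], got {span}")
    if len(table) < 100:
        raise ValueError(
            f"array {table.array_id}: LOESS normalization needs >= 100 probes, "
            f"got {len(table)}"
        )
    m = table.data["M"].to_numpy()
    a = table.data["A"].to_numpy()
    fitted = _lowess_fit(m, a, span, robust_iters)
    return table.with_m(m - fitted, stage="loess")


def gc_correct(
    table: RatioTable, genes: Sequence[GeneTarget], level: str = "probe",
    span: float = DEFAULT_SPAN, robust_iters: int = DEFAULT_ROBUST_ITERS,
) -> RatioTable:
    """Remove the GC-content wave: ``M'' = M' - g(gc)``.

    ``g`` is a robust LOESS fit of M on GC fraction.  With
    ``level="gene"`` the covariate is the mean probe GC of the gene
    (tests the wave at the gene/contig scale); the default is per probe.
    Degenerate (constant) GC skips the correction with a warning.
    """
    if level not in ("probe", "gene"):
        raise ValueError(f"gc level must be 'probe' or 'gene', got {level!r}")
    probe_gc = {p.probe_id: p.gc for g in genes for p in g.probes}
    if level == "gene":
        gene_gc = {
            g.gene_id: float(np.mean([p.gc for p in g.probes]))
            for g in genes if g.probes
        }
        probe_gene = {p.probe_id: p.gene_id for g in genes for p in g.probes}
        probe_gc = {pid: gene_gc[gid] for pid, gid in probe_gene.items()}
    gc = table.data.index.map(probe_gc).to_numpy(float)
    if np.isnan(gc).any():
        missing = table.data.index[np.isnan(gc)][:3]
        raise InvariantError(f"no GC annotation for probes {list(missing)}")
    if np.ptp(gc) == 0:
        warnings.warn(
            f"array {table.array_id}: constant GC; skipping GC correction",
            stacklevel=2,
        )
        return table.with_m(table.data["M"].to_numpy(), stage="gc")
    m = table.data["M"].to_numpy()
    fitted = _lowess_fit(m, gc, span, robust_iters)
    return table.with_m(m - fitted, stage="gc")


def composition_correct(
    table: RatioTable, genes: Sequence[GeneTarget],
) -> RatioTable:
    """Remove linear probe-composition effects.

    Fits ordinary least squares of M on the probe base fractions
    (fA, fC, fG; fT is the omitted complement) with an intercept and keeps
    the residuals.  Collinear covariates are dropped with a warning.
    """
    lookup = {p.probe_id: p.base_fractions for g in genes for p in g.probes}
    try:
        bf = np.array([lookup[pid] for pid in table.data.index], dtype=float)
    except KeyError as exc:
        raise InvariantError(f"no composition annotation for probe {exc}") from None
    m = table.data["M"].to_numpy()

    names = ["intercept", "frac_a", "frac_c", "frac_g"]
    cols = [np.ones(len(m)), bf[:, 0], bf[:, 1], bf[:, 2]]
    kept_names: List[str] = []
    kept_cols: List[np.ndarray] = []
    for name, col in zip(names, cols):
        candidate = np.column_stack(kept_cols + [col]) if kept_cols else col[:, None]
        if np.linalg.matrix_rank(candidate) > len(kept_cols):
            kept_names.append(name)
            kept_cols.append(col)
        else:
            warnings.warn(
                f"array {table.array_id}: dropping collinear composition "
                f"covariate {name!r}", stacklevel=2,
            )
    x = np.column_stack(kept_cols)
    beta, *_ = np.linalg.lstsq(x, m, rcond=None)
    residuals = m - x @ beta
    out = table.with_m(residuals, stage="composition")
    out.composition_coefficients = dict(zip(kept_names, beta.tolist()))
    return out


def normalize_experiment(
    experiment: ArrayExperiment, genes: Sequence[GeneTarget],
    span: float = DEFAULT_SPAN, robust_iters: int = DEFAULT_ROBUST_ITERS,
    gc_level: str = "probe", order: Sequence[str] = DEFAULT_ORDER,
) -> RatioTable:
    """Run the full per-array correction pipeline in the configured order."""
    unknown = set(order) - {"loess", "gc", "composition"}
    if unknown:
        raise ValueError(f"unknown correction steps {sorted(unknown)}")
    table = compute_ma(experiment)
    for step in order:
        if step == "loess":
            table = loess_dye_correct(table, span=span, robust_iters=robust_iters)
        elif step == "gc":
            table = gc_correct(table, genes, level=gc_level, span=span,
                               robust_iters=robust_iters)
        else:
            table = composition_correct(table, genes)
    return table
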