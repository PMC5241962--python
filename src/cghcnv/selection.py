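"""Probe quality and gene eligibility filters used to finalize an array design.

Filter chain (in this order): per-probe intensity quality across pilot
datasets, sense/antisense deduplication at shared positions, per-gene
eligibility (probe count and covered length), and greedy spacing
enforcement.  All filters are idempotent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .model import GeneTarget, ProbeDef

__all__ = [
    "filter_probe_quality",
    "dedup_orientation",
    "filter_gene_eligibility",
    "enforce_spacing",
    "select_probes",
    "pilot_datasets_from_intensities",
]

MIN_PROBES = 6
MIN_COVERED = 500       # strict: covered length must exceed this
SPACING_WIDE = 200
SPACING_NARROW = 100
SPACING_CUTOFF = 16     # genes with fewer probes use the narrow spacing


def pilot_datasets_from_intensities(intensities: pd.DataFrame) -> pd.DataFrame:
    """Reshape an intensities table into long pilot-dataset form.

    Each pilot hybridization contributes two datasets (one per channel), so
    five pilot arrays yield the canonical ten datasets per probe.  Output
    columns: ``probe_id, dataset, raw, bg``.
    """
    frames = []
    for channel, raw_col, bg_col in (
        ("test", "i_test_raw", "i_test_bg"),
        ("ref", "i_ref_raw", "i_ref_bg"),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": intensities["probe_id"].astype(str),
                    "dataset": intensities["array_id"].astype(str) + ":" + channel,
                    "raw": intensities[raw_col].to_numpy(float),
                    "bg": intensities[bg_col].to_numpy(float),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def filter_probe_quality(
    pilot: pd.DataFrame, min_pass: int = 6, n_datasets: int = 10,
    ratio: float = 2.0,
) -> Set[str]:
    """Keep probes whose raw intensity is at least ``ratio`` times background
    in ``min_pass`` of ``n_datasets`` pilot datasets.

    The boundary is inclusive (raw exactly twice background passes).  If the
    observed dataset count per probe differs from ``n_datasets``, the rule
    generalizes to ``ceil(min_pass / n_datasets * observed)`` with a warning.
    """
    passing = pilot["raw"] >= ratio * pilot["bg"]
    grouped = pd.DataFrame(
        {"n_pass": passing.groupby(pilot["probe_id"]).sum(),
         "n_obs": pilot.groupby("probe_id").size()}
    )
    required = pd.Series(min_pass, index=grouped.index, dtype=int)
    off = grouped["n_obs"] != n_datasets
    if off.any():
        warnings.warn(
            f"{int(off.sum())} probes observed in != {n_datasets} datasets; "
            f"generalizing the {min_pass}-of-{n_datasets} rule proportionally",
            stacklevel=2,
        )
        required[off] = np.ceil(
            min_pass / n_datasets * grouped.loc[off, "n_obs"]
        ).astype(int)
    kept = grouped.index[grouped["n_pass"] >= required]
    return set(kept.astype(str))


def dedup_orientation(
    genes: Sequence[GeneTarget], mean_intensity: Dict[str, float]
) -> List[GeneTarget]:
    """Resolve sense/antisense probes tiling the same position.

    Among probes of a gene sharing a start position, the one with the lower
    mean intensity across the pilot datasets is removed.  Ties keep the
    sense probe.  Unpaired probes pass through unchanged.
    """
    out = []
    for gene in genes:
        by_pos: Dict[int, List[ProbeDef]] = {}
        for p in gene.probes:
            by_pos.setdefault(p.start, []).append(p)
        kept: List[ProbeDef] = []
        for start in sorted(by_pos):
            group = by_pos[start]
            if len(group) == 1:
                kept.append(group[0])
                continue

            def rank(p: ProbeDef) -> tuple:
                # higher intensity wins; on ties, sense wins
                return (mean_intensity.get(p.probe_id, float("-inf")),
                        p.orientation == "sense")

            kept.append(max(group, key=rank))
        out.append(GeneTarget(gene.gene_id, gene.seq_length, tuple(kept)))
    return out


def filter_gene_eligibility(gene: GeneTarget) -> bool:
    """Eligible iff the gene retains >= 6 probes and covers > 500 bp (strict)."""
    return gene.n_probes >= MIN_PROBES and gene.covered_length > MIN_COVERED


def enforce_spacing(gene: GeneTarget) -> GeneTarget:
    """Greedy left-to-right thinning to a minimum start-to-start spacing.

    The spacing is 200 bp, reduced to 100 bp when the incoming probe count
    (before thinning) is below 16.  The leftmost probe is always kept.
    """
    s = SPACING_WIDE if gene.n_probes >= SPACING_CUTOFF else SPACING_NARROW
    kept: List[ProbeDef] = []
    last_start: Optional[int] = None
    for p in gene.probes:
        if last_start is None or p.start >= last_start + s:
            kept.append(p)
            last_start = p.start
    return GeneTarget(gene.gene_id, gene.seq_length, tuple(kept))


def select_probes(
    genes: Sequence[GeneTarget], pilot: pd.DataFrame,
    min_pass: int = 6, n_datasets: int = 10,
) -> Tuple[List[GeneTarget], dict]:
    """Full design filter chain: quality -> dedup -> eligibility -> spacing.

    Returns the retained panel plus a report of counts at each step.
    """
    report = {
        "input_genes": len(genes),
        "input_probes": int(sum(g.n_probes for g in genes)),
    }
    quality = filter_probe_quality(pilot, min_pass=min_pass, n_datasets=n_datasets)
    trimmed = []
    for g in genes:
        kept = tuple(p for p in g.probes if p.probe_id in quality)
        trimmed.append(GeneTarget(g.gene_id, g.seq_length, kept))
    report["probes_after_quality"] = int(sum(g.n_probes for g in trimmed))

    mean_intensity = pilot.groupby("probe_id")["raw"].mean().to_dict()
    trimmed = dedup_orientation(trimmed, mean_intensity)
    report["probes_after_dedup"] = int(sum(g.n_probes for g in trimmed))

    eligible = [g for g in trimmed if filter_gene_eligibility(g)]
    report["genes_after_eligibility"] = len(eligible)

    final = [enforce_spacing(g) for g in eligible]
    # spacing can drop a gene below the probe floor; re-check eligibility
    final = [g for g in final if filter_gene_eligibility(g)]
    report["genes_final"] = len(final)
    report["probes_final"] = int(sum(g.n_probes for g in final))
    return final, report
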