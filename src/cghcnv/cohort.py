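"""Family- and cross-family summaries of gene CNV calls.

Covers: boolean call matrices per family, common/infrequent frequency
classes, sharing and core sets across families, one-way ANOVA with Tukey
HSD on per-individual CNV counts, and genetic-map distribution reports
(per-LG counts, adjacent distances, 1-cM clusters, KS density comparison).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .model import ArrayExperiment, CallMatrix, GeneCall, GeneticMap

__all__ = [
    "build_call_matrix",
    "classify_frequency",
    "share_sets",
    "compare_family_counts",
    "flag_outliers",
    "map_report",
    "percent",
]


def percent(numerator: float, denominator: float, ndigits: Optional[int] = 1) -> float:
    """Percentage ``100 * numerator / denominator`` rounded to ``ndigits``
    (``ndigits=None`` rounds to the nearest integer)."""
    value = 100.0 * numerator / denominator
    return round(value) if ndigits is None else round(value, ndigits)


def build_call_matrix(
    calls: Sequence[GeneCall], experiments: Sequence[ArrayExperiment],
) -> CallMatrix:
    """Assemble the genes x individuals boolean CNV matrix for one family.

    All calls must come from arrays of a single family.  Rows cover the
    union of genes called (is_cnv) in at least one individual; columns
    cover every test individual of the family present in ``experiments``,
    so individuals without any call still contribute zero columns.
    """
    by_id = {e.array_id: e for e in experiments}
    families = set()
    for c in calls:
        exp = by_id.get(c.array_id)
        if exp is None:
            raise ValueError(f"no array metadata for call on {c.array_id}")
        families.add(exp.family_id)
    if len(families) > 1:
        raise ValueError(f"calls span multiple families: {sorted(map(str, families))}")
    if families:
        family_id = families.pop()
    else:
        # no calls: fall back to the (unique) family in the metadata
        meta_families = {e.family_id for e in experiments if not e.self_self}
        family_id = meta_families.pop() if len(meta_families) == 1 else None

    individuals = sorted(
        {
            e.test_sample
            for e in experiments
            if e.family_id == family_id and not e.self_self
        }
    )
    called_genes = sorted({c.gene_id for c in calls if c.is_cnv})
    matrix = pd.DataFrame(
        False, index=pd.Index(called_genes, name="gene_id"),
        columns=pd.Index(individuals, name="individual"),
    )
    for c in calls:
        if c.is_cnv:
            matrix.loc[c.gene_id, by_id[c.array_id].test_sample] = True
    return CallMatrix(family_id=str(family_id), calls=matrix)


def classify_frequency(
    matrix: CallMatrix, calls: Optional[Sequence[GeneCall]] = None,
) -> Tuple[pd.Series, Dict[str, float]]:
    """Split genes into frequency classes and summarize Table-style columns.

    A gene is ``infrequent`` when carried by exactly one individual and
    ``common`` when carried by two or more.  The summary reports class
    percentages (they sum to 100) and, when calls are supplied, the
    percentage of called genes flagged PAV in at least one individual.
    """
    if matrix.calls.shape[1] < 1:
        raise ValueError("classify_frequency requires >= 1 individual")
    carriers = matrix.carrier_counts
    classes = pd.Series(
        np.where(carriers == 1, "infrequent", "common"),
        index=carriers.index, name="class",
    )
    n = len(classes)
    summary: Dict[str, float] = {
        "n_genes": float(n),
        "pct_infrequent": 100.0 * (classes == "infrequent").sum() / n if n else 0.0,
        "pct_common": 100.0 * (classes == "common").sum() / n if n else 0.0,
    }
    if calls is not None:
        pav_genes = {c.gene_id for c in calls if c.is_pav}
        summary["pct_pav"] = (
            100.0 * len(pav_genes & set(classes.index)) / n if n else 0.0
        )
    return classes, summary


def share_sets(matrices: Mapping[str, CallMatrix]) -> Dict:
    """Pairwise shared CNV-gene counts, core and union across families.

    A gene belongs to a family's set when called in at least one of its
    individuals.
    """
    if len(matrices) < 2:
        raise ValueError("share_sets requires >= 2 families")
    sets: Dict[str, Set[str]] = {fam: m.gene_set() for fam, m in matrices.items()}
    families = sorted(sets)
    pairwise = {
        (a, b): len(sets[a] & sets[b])
        for a, b in itertools.combinations(families, 2)
    }
    core = set.intersection(*sets.values())
    union = set.union(*sets.values())
    exclusive = {
        fam: sets[fam] - set.union(*(sets[o] for o in families if o != fam))
        for fam in families
    }
    return {
        "per_family": {fam: len(sets[fam]) for fam in families},
        "pairwise": pairwise,
        "core": core,
        "n_core": len(core),
        "union": union,
        "n_union": len(union),
        "exclusive": {fam: len(exclusive[fam]) for fam in families},
    }


def compare_family_counts(counts_by_family: Mapping[str, Sequence[float]]) -> Dict:
    """One-way ANOVA plus Tukey HSD on per-individual CNV counts.

    Returns the F statistic, its p-value, and a DataFrame of pairwise Tukey
    comparisons with adjusted p-values.  Degenerate inputs with zero
    between-group variance yield F = 0 and no significant pairs.
    """
    families = sorted(counts_by_family)
    if len(families) < 2:
        raise ValueError("need >= 2 families")
    groups = [np.asarray(counts_by_family[f], dtype=float) for f in families]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each family needs >= 2 individuals")

    grand = np.concatenate(groups)
    n_total, k = len(grand), len(groups)
    ssb = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    pairs_index = list(itertools.combinations(families, 2))
    if ssb <= 1e-12:
        f_stat, p_value = 0.0, 1.0
        tukey = pd.DataFrame(
            {
                "family_a": [a for a, _ in pairs_index],
                "family_b": [b for _, b in pairs_index],
                "meandiff": 0.0,
                "p_adj": 1.0,
                "reject": False,
            }
        )
        return {"F": f_stat, "p_value": p_value, "tukey": tukey}
    if ssw <= 1e-12:
        f_stat, p_value = float("inf"), 0.0
    else:
        msb = ssb / (k - 1)
        msw = ssw / (n_total - k)
        f_stat = msb / msw
        p_value = float(stats.f.sf(f_stat, k - 1, n_total - k))

    labels = np.concatenate([[f] * len(g) for f, g in zip(families, groups)])
    res = pairwise_tukeyhsd(grand, labels, alpha=0.05)
    tukey = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    tukey = tukey.rename(
        columns={"group1": "family_a", "group2": "family_b", "p-adj": "p_adj"}
    )
    # summary() rounds p-values; replace with full precision
    tukey["p_adj"] = res.pvalues
    tukey["reject"] = res.reject
    return {"F": float(f_stat), "p_value": p_value, "tukey": tukey}


def flag_outliers(matrix: CallMatrix, n_sd: float = 2.0) -> List[str]:
    """Individuals whose CNV count exceeds the family mean by > ``n_sd`` SD."""
    counts = matrix.individual_counts
    if len(counts) < 2:
        return []
    threshold = counts.mean() + n_sd * counts.std(ddof=1)
    return sorted(counts.index[counts > threshold])


def _scaled_positions(gmap: GeneticMap, gene_ids: Iterable[str]) -> np.ndarray:
    """cM positions min-max scaled to [0, 1] within each linkage group
    (scaling bounds come from the full map), pooled across groups."""
    pos = gmap.positions
    bounds = pos.groupby("linkage_group")["position"].agg(["min", "max"])
    subset = pos.loc[pos.index.intersection(pd.Index(list(gene_ids)))]
    lo = bounds.loc[subset["linkage_group"], "min"].to_numpy()
    hi = bounds.loc[subset["linkage_group"], "max"].to_numpy()
    span = np.where(hi > lo, hi - lo, 1.0)
    return (subset["position"].to_numpy() - lo) / span


def map_report(
    matrices: Mapping[str, CallMatrix], gmap: GeneticMap,
    cluster_window: float = 1.0,
) -> Dict:
    """Genetic-map distribution report for CNV genes.

    Produces per-linkage-group CNV counts over the union of families,
    per-family mean adjacent distances (consecutive mapped CNV genes within
    a linkage group, gaps pooled across groups), clusters (maximal runs of
    >= 2 mapped CNV genes with consecutive gaps <= ``cluster_window`` cM),
    and a two-sample KS comparison of CNV-gene positions against all mapped
    genes (positions min-max scaled within each linkage group).
    """
    union_genes = set().union(*(m.gene_set() for m in matrices.values()))
    mapped_union = sorted(g for g in union_genes if g in gmap)
    n_unmapped = len(union_genes) - len(mapped_union)
    if len(mapped_union) < 2:
        raise ValueError("map_report needs >= 2 mapped CNV genes")

    pos = gmap.positions
    per_lg = (
        pos.loc[mapped_union].groupby("linkage_group").size().sort_index()
    )

    mean_adjacent: Dict[str, float] = {}
    for fam, m in matrices.items():
        fam_mapped = pos.loc[[g for g in sorted(m.gene_set()) if g in gmap]]
        gaps: List[float] = []
        for _, sub in fam_mapped.groupby("linkage_group"):
            p = np.sort(sub["position"].to_numpy())
            if len(p) >= 2:
                gaps.extend(np.diff(p))
        mean_adjacent[fam] = float(np.mean(gaps)) if gaps else float("nan")

    clusters: List[Dict] = []
    union_pos = pos.loc[mapped_union]
    for lg, sub in union_pos.groupby("linkage_group"):
        sub = sub.sort_values("position")
        run = [sub.index[0]]
        for prev, cur in zip(range(len(sub) - 1), range(1, len(sub))):
            gap = sub["position"].iloc[cur] - sub["position"].iloc[prev]
            if gap <= cluster_window:
                run.append(sub.index[cur])
            else:
                if len(run) >= 2:
                    clusters.append({"linkage_group": lg, "genes": list(run)})
                run = [sub.index[cur]]
        if len(run) >= 2:
            clusters.append({"linkage_group": lg, "genes": list(run)})

    cnv_scaled = _scaled_positions(gmap, mapped_union)
    all_scaled = _scaled_positions(gmap, gmap.positions.index)
    ks = stats.ks_2samp(cnv_scaled, all_scaled)

    return {
        "per_lg_counts": per_lg,
        "mean_adjacent_cm": mean_adjacent,
        "clusters": clusters,
        "n_clusters": len(clusters),
        "ks_statistic": float(ks.statistic),
        "ks_p_value": float(ks.pvalue),
        "n_mapped": len(mapped_union),
        "n_unmapped": n_unmapped,
    }
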