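"""Synthetic aCGH data with known copy-number truth.

Generates probe panels, full-sib families with Mendelian transmission of CNV
alleles, and two-channel intensities carrying an intensity-dependent dye
bias, a GC-content wave, and Gaussian probe noise.  Every downstream stage
of the pipeline can therefore be exercised against ground truth.

Determinism: each operation derives its own `numpy` generator from
``cfg.seed`` with a fixed per-operation stream key, so panels, genotypes
and intensities are independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import ArrayExperiment, GeneTarget, InvariantError, ProbeDef

__all__ = ["SimConfig", "simulate_panel", "simulate_family", "simulate_arrays",
           "simulate_self_self"]

_PANEL_STREAM = 11
_FAMILY_STREAM = 23
_ARRAY_STREAM = 37


@dataclass
class SimConfig:
    """Parameters of the generative model.

    Copy ratio enters the probe signal as a shift of M only: channel
    intensities are ``I_test = 2**(A + M/2)`` and ``I_ref = 2**(A - M/2)``,
    keeping A independent of copy state.  A zero-copy test genome produces
    ``M = pav_floor`` instead of -inf (signal floor of the instrument).
    """

    n_genes: int = 1000
    probe_min: int = 6
    probe_mean: float = 12.6
    probe_max: int = 114
    probe_length: int = 60
    min_covered: int = 500          # covered length must strictly exceed this
    n_offspring: int = 19
    p_cnv: float = 0.05
    allele_copy_states: Tuple[int, ...] = (0, 2)  # copies carried by a CNV allele
    p_shared_allele: float = 0.0    # chance the second parent carries it too
    sigma: float = 0.15             # per-probe noise SD on M
    dye_bias: Tuple[float, float] = (0.0, 0.0)    # intercept, slope vs (A - a_mean)
    gc_amplitude: float = 0.0       # M offset = gc_amplitude * 2 * (gc - 0.5)
    a_mean: float = 10.0            # baseline log2 intensity
    a_sd: float = 1.0
    bg_level: float = 16.0          # mean background, small vs 2**a_mean
    pav_floor: float = -4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_offspring < 1:
            raise InvariantError("n_offspring must be >= 1")
        if not (0.0 <= self.p_cnv <= 1.0):
            raise InvariantError("p_cnv must be in [0, 1]")
        if not (0.0 <= self.p_shared_allele <= 1.0):
            raise InvariantError("p_shared_allele must be in [0, 1]")
        if self.sigma <= 0:
            raise InvariantError("sigma must be > 0")
        if self.probe_min < 6:
            raise InvariantError("probe_min must be >= 6 (mirrors design filters)")
        if self.probe_mean < self.probe_min or self.probe_max < self.probe_min:
            raise InvariantError("probe count distribution is infeasible")
        if any(a < 0 for a in self.allele_copy_states):
            raise InvariantError("allele copy states must be non-negative")
        if self.min_covered < 500:
            raise InvariantError("min_covered must be >= 500 (design filter)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


def _gene_id(i: int) -> str:
    return f"g{i:05d}"


def simulate_panel(cfg: SimConfig) -> List[GeneTarget]:
    """Draw a probe panel satisfying the design filters.

    Probe counts are ``probe_min + Poisson(probe_mean - probe_min)`` capped
    at ``probe_max``; probes are evenly spaced with a per-gene spacing drawn
    wide enough that covered length strictly exceeds ``min_covered``.
    Probe GC is unimodal on (0.2, 0.8).
    """
    rng = cfg.rng(_PANEL_STREAM)
    genes: List[GeneTarget] = []
    for i in range(cfg.n_genes):
        n = int(min(cfg.probe_max, cfg.probe_min + rng.poisson(cfg.probe_mean - cfg.probe_min)))
        # smallest spacing s with (n-1)*s + probe_length > min_covered,
        # bounded below by the design spacing rules so the selection-filter
        # chain is a no-op on clean simulated panels
        s_lo = (cfg.min_covered - cfg.probe_length) // (n - 1) + 1
        s_lo = max(s_lo, cfg.probe_length, 200 if n >= 16 else 100)
        spacing = int(rng.integers(s_lo, s_lo + 80))
        starts = np.arange(n) * spacing
        covered = int(starts[-1]) + cfg.probe_length
        if covered <= cfg.min_covered:
            raise InvariantError(
                f"gene {_gene_id(i)}: probes do not fit the length constraint"
            )
        seq_length = covered + int(rng.integers(0, 200))
        gc = 0.2 + 0.6 * rng.beta(2.0, 2.0, size=n)
        split_cg = rng.uniform(0.35, 0.65, size=n)
        split_at = rng.uniform(0.35, 0.65, size=n)
        probes = []
        for j in range(n):
            c = gc[j] * split_cg[j]
            g = gc[j] - c
            a = (1.0 - gc[j]) * split_at[j]
            t = (1.0 - gc[j]) - a
            probes.append(
                ProbeDef(
                    probe_id=f"{_gene_id(i)}_p{j:03d}",
                    gene_id=_gene_id(i),
                    start=int(starts[j]),
                    length=cfg.probe_length,
                    orientation="sense",
                    gc=float(gc[j]),
                    base_fractions=(float(a), float(c), float(g), float(t)),
                )
            )
        genes.append(GeneTarget(gene_id=_gene_id(i), seq_length=seq_length,
                                probes=tuple(probes)))
    return genes


Genotype = Dict[str, Tuple[int, int]]  # gene_id -> (allele1 copies, allele2 copies)

REF_PARENT = "P1"
TEST_PARENT = "P2"


def simulate_family(
    cfg: SimConfig, panel: Sequence[GeneTarget]
) -> Tuple[Dict[str, Genotype], Dict[str, Genotype], pd.DataFrame]:
    """Simulate two diploid parents and ``n_offspring`` full sibs.

    A normal allele carries one gene copy.  With probability ``p_cnv`` a
    gene segregates a CNV allele (copies drawn from
    ``cfg.allele_copy_states``) in one randomly chosen, heterozygous
    parent; with probability ``p_shared_allele`` the other parent carries
    the same allele too (needed e.g. for zero-copy offspring).  Each
    offspring inherits one allele from each parent uniformly at random.
    The reference individual is parent ``P1``; ``cn_ref`` is its genotype
    total.

    Returns ``(parents, offspring, truth)`` where truth has one row per
    (individual, gene) with columns ``individual, gene_id, cn_test,
    cn_ref, expected_m``; ``expected_m = log2(cn_test / cn_ref)`` or
    ``cfg.pav_floor`` when ``cn_test == 0``.
    """
    rng = cfg.rng(_FAMILY_STREAM)
    gene_ids = [g.gene_id for g in panel]
    n_genes = len(gene_ids)

    is_cnv_gene = rng.random(n_genes) < cfg.p_cnv
    carrier_is_ref = rng.random(n_genes) < 0.5
    shared = rng.random(n_genes) < cfg.p_shared_allele
    cnv_allele = rng.choice(cfg.allele_copy_states, size=n_genes)

    parents: Dict[str, Genotype] = {REF_PARENT: {}, TEST_PARENT: {}}
    for k, gid in enumerate(gene_ids):
        g1 = (1, 1)
        g2 = (1, 1)
        if is_cnv_gene[k]:
            a = int(cnv_allele[k])
            if carrier_is_ref[k] or shared[k]:
                g1 = (1, a)
            if not carrier_is_ref[k] or shared[k]:
                g2 = (1, a)
        parents[REF_PARENT][gid] = g1
        parents[TEST_PARENT][gid] = g2

    p1_alleles = np.array([parents[REF_PARENT][g] for g in gene_ids])
    p2_alleles = np.array([parents[TEST_PARENT][g] for g in gene_ids])
    cn_ref = p1_alleles.sum(axis=1)

    offspring: Dict[str, Genotype] = {}
    rows = []
    for o in range(cfg.n_offspring):
        name = f"off{o + 1:02d}"
        pick1 = rng.integers(0, 2, size=n_genes)
        pick2 = rng.integers(0, 2, size=n_genes)
        a1 = p1_alleles[np.arange(n_genes), pick1]
        a2 = p2_alleles[np.arange(n_genes), pick2]
        cn_test = a1 + a2
        offspring[name] = {
            gid: (int(a1[k]), int(a2[k])) for k, gid in enumerate(gene_ids)
        }
        with np.errstate(divide="ignore"):
            em = np.where(
                cn_test == 0,
                cfg.pav_floor,
                np.log2(np.maximum(cn_test, 1) / cn_ref),
            )
        rows.append(
            pd.DataFrame(
                {
                    "individual": name,
                    "gene_id": gene_ids,
                    "cn_test": cn_test.astype(int),
                    "cn_ref": cn_ref.astype(int),
                    "expected_m": em,
                }
            )
        )
    truth = pd.concat(rows, ignore_index=True)
    return parents, offspring, truth


def _probe_frame(panel: Sequence[GeneTarget]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [p.probe_id for g in panel for p in g.probes],
            "gene_id": [p.gene_id for g in panel for p in g.probes],
            "gc": [p.gc for g in panel for p in g.probes],
        }
    )


def _make_measurements(
    cfg: SimConfig, rng: np.random.Generator, probes: pd.DataFrame,
    expected_m: np.ndarray,
) -> Dict[str, Tuple[float, float, float, float]]:
    n = len(probes)
    a = rng.normal(cfg.a_mean, cfg.a_sd, size=n)
    m = (
        expected_m
        + cfg.dye_bias[0]
        + cfg.dye_bias[1] * (a - cfg.a_mean)
        + cfg.gc_amplitude * 2.0 * (probes["gc"].to_numpy() - 0.5)
        + rng.normal(0.0, cfg.sigma, size=n)
    )
    i_test = np.exp2(a + m / 2.0)
    i_ref = np.exp2(a - m / 2.0)
    bg_test = cfg.bg_level * rng.uniform(0.5, 1.5, size=n)
    bg_ref = cfg.bg_level * rng.uniform(0.5, 1.5, size=n)
    raw_test = i_test + bg_test
    raw_ref = i_ref + bg_ref
    return {
        pid: (float(rt), float(bt), float(rr), float(br))
        for pid, rt, bt, rr, br in zip(
            probes["probe_id"], raw_test, bg_test, raw_ref, bg_ref
        )
    }


def simulate_arrays(
    cfg: SimConfig, panel: Sequence[GeneTarget], truth: pd.DataFrame,
    family_id: str = "F1",
) -> List[ArrayExperiment]:
    """One test-vs-reference hybridization per offspring in ``truth``."""
    rng = cfg.rng(_ARRAY_STREAM)
    probes = _probe_frame(panel)
    experiments = []
    for individual in truth["individual"].unique():
        sub = truth[truth["individual"] == individual]
        em_by_gene = dict(zip(sub["gene_id"], sub["expected_m"]))
        missing = set(probes["gene_id"]) - set(em_by_gene)
        if missing:
            raise InvariantError(
                f"truth table does not cover genes {sorted(missing)[:3]}..."
            )
        expected = probes["gene_id"].map(em_by_gene).to_numpy(float)
        experiments.append(
            ArrayExperiment(
                array_id=f"arr_{individual}",
                test_sample=str(individual),
                ref_sample=REF_PARENT,
                family_id=family_id,
                self_self=False,
                dye_swap=False,
                measurements=_make_measurements(cfg, rng, probes, expected),
            )
        )
    return experiments


def simulate_self_self(
    cfg: SimConfig, panel: Sequence[GeneTarget], n_arrays: int = 1,
    sample: str = REF_PARENT,
) -> List[ArrayExperiment]:
    """Null hybridizations: the same genome in both channels (expected M = 0)."""
    rng = cfg.rng(_ARRAY_STREAM + 1)
    probes = _probe_frame(panel)
    zeros = np.zeros(len(probes))
    return [
        ArrayExperiment(
            array_id=f"selfself_{i + 1:02d}",
            test_sample=sample,
            ref_sample=sample,
            family_id=None,
            self_self=True,
            dye_swap=False,
            measurements=_make_measurements(cfg, rng, probes, zeros),
        )
        for i in range(n_arrays)
    ]
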