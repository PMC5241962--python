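"""Domain types shared by every pipeline stage.

All invariants are enforced at construction time: an instance that exists is
valid.  Tabular payloads (ratio tables, call matrices) are thin wrappers
around :class:`pandas.DataFrame` so that downstream numeric code can stay
vectorised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "TAU_43",
    "ORIENTATIONS",
    "STAGES",
    "DIRECTIONS",
    "InvariantError",
    "ProbeDef",
    "GeneTarget",
    "ArrayExperiment",
    "RatioTable",
    "GeneCall",
    "CallMatrix",
    "GeneticMap",
    "DetectionParams",
]

#: Exact probe-level log2-ratio threshold for a 4:3 (or 3:4) copy change.
TAU_43: float = abs(math.log2(4.0 / 3.0))

ORIENTATIONS = ("sense", "antisense")
STAGES = ("raw", "loess", "gc", "composition")
DIRECTIONS = ("gain", "loss", "none")

_ATOL = 1e-9


class InvariantError(ValueError):
    """A domain invariant was violated at construction time."""


@dataclass(frozen=True)
class ProbeDef:
    """One oligonucleotide probe within a gene sequence.

    Coordinates are 0-based, half-open: the probe covers
    ``[start, start + length)`` within its gene's sequence.
    """

    probe_id: str
    gene_id: str
    start: int
    gc: float
    base_fractions: Tuple[float, float, float, float]  # A, C, G, T
    length: int = 60
    orientation: str = "sense"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InvariantError(f"probe {self.probe_id}: length must be > 0")
        if self.start < 0:
            raise InvariantError(f"probe {self.probe_id}: start must be >= 0")
        if not (0.0 <= self.gc <= 1.0):
            raise InvariantError(f"probe {self.probe_id}: gc={self.gc} outside [0, 1]")
        if self.orientation not in ORIENTATIONS:
            raise InvariantError(
                f"probe {self.probe_id}: orientation {self.orientation!r} "
                f"not in {ORIENTATIONS}"
            )
        bf = self.base_fractions
        if len(bf) != 4 or any(f < -_ATOL for f in bf):
            raise InvariantError(
                f"probe {self.probe_id}: base_fractions must be 4 non-negative values"
            )
        if abs(sum(bf) - 1.0) > _ATOL:
            raise InvariantError(
                f"probe {self.probe_id}: base_fractions sum to {sum(bf)}, expected 1"
            )
        if abs((bf[1] + bf[2]) - self.gc) > _ATOL:
            raise InvariantError(
                f"probe {self.probe_id}: gc={self.gc} does not equal "
                f"fraction C + fraction G = {bf[1] + bf[2]}"
            )

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class GeneTarget:
    """A gene sequence with its ordered probe tiling."""

    gene_id: str
    seq_length: int
    probes: Tuple[ProbeDef, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "probes", tuple(self.probes))
        starts = [p.start for p in self.probes]
        if starts != sorted(starts):
            raise InvariantError(f"gene {self.gene_id}: probes not sorted by start")
        for p in self.probes:
            if p.gene_id != self.gene_id:
                raise InvariantError(
                    f"gene {self.gene_id}: probe {p.probe_id} belongs to {p.gene_id}"
                )
            if p.end > self.seq_length:
                raise InvariantError(
                    f"gene {self.gene_id}: probe {p.probe_id} extends to {p.end} "
                    f"beyond seq_length {self.seq_length}"
                )
        if self.covered_length > self.seq_length:
            raise InvariantError(
                f"gene {self.gene_id}: covered_length exceeds seq_length"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def covered_length(self) -> int:
        """Distance from the start of the first probe to the end of the last."""
        if not self.probes:
            return 0
        return self.probes[-1].end - self.probes[0].start


Measurement = Tuple[float, float, float, float]  # test_raw, test_bg, ref_raw, ref_bg


@dataclass(frozen=True)
class ArrayExperiment:
    """One two-channel hybridization: per-probe raw and background intensities."""

    array_id: str
    test_sample: str
    ref_sample: str
    measurements: Mapping[str, Measurement]
    family_id: Optional[str] = None
    self_self: bool = False
    dye_swap: bool = False

    def __post_init__(self) -> None:
        if self.self_self and self.test_sample != self.ref_sample:
            raise InvariantError(
                f"array {self.array_id}: self_self requires test_sample == "
                f"ref_sample, got {self.test_sample!r} vs {self.ref_sample!r}"
            )
        for probe_id, m in self.measurements.items():
            if len(m) != 4:
                raise InvariantError(
                    f"array {self.array_id}: probe {probe_id} needs 4 intensities"
                )
            if any(v < 0 for v in m):
                raise InvariantError(
                    f"array {self.array_id}: negative intensity for probe {probe_id}"
                )

    def check_probes(self, known_probe_ids: set) -> None:
        """Verify every measured probe resolves to a known probe definition."""
        unknown = set(self.measurements) - known_probe_ids
        if unknown:
            sample = sorted(unknown)[:5]
            raise InvariantError(
                f"array {self.array_id}: {len(unknown)} probes not in the panel "
                f"(e.g. {sample})"
            )


@dataclass
class RatioTable:
    """Per-probe log2 ratio (M) and average log2 intensity (A) for one array.

    ``data`` is indexed by probe_id with float columns ``M`` and ``A``.
    Probes whose background-subtracted intensity was non-positive are absent;
    their number is kept in ``n_dropped``.
    """

    array_id: str
    data: pd.DataFrame
    stage: str = "raw"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise InvariantError(f"unknown stage {self.stage!r}; expected {STAGES}")
        missing = {"M", "A"} - set(self.data.columns)
        if missing:
            raise InvariantError(f"ratio table missing columns {sorted(missing)}")
        if len(self.data) and not np.isfinite(self.data[["M", "A"]].to_numpy()).all():
            raise InvariantError(
                f"array {self.array_id}: non-finite M or A in ratio table"
            )

    def __len__(self) -> int:
        return len(self.data)

    def with_m(self, new_m: np.ndarray, stage: str) -> "RatioTable":
        """Return a copy with corrected M values and an updated stage tag."""
        data = self.data.copy()
        data["M"] = np.asarray(new_m, dtype=float)
        return RatioTable(self.array_id, data, stage=stage, n_dropped=self.n_dropped)


@dataclass(frozen=True)
class GeneCall:
    """Per-gene, per-array CNV decision produced by probe voting."""

    array_id: str
    gene_id: str
    n_probes: int
    n_significant: int
    direction: str
    median_m: float
    is_cnv: bool
    is_pav: bool

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise InvariantError(f"{self.gene_id}: n_probes must be >= 1")
        if not (0 <= self.n_significant <= self.n_probes):
            raise InvariantError(
                f"{self.gene_id}: n_significant outside [0, n_probes]"
            )
        if self.direction not in DIRECTIONS:
            raise InvariantError(f"{self.gene_id}: bad direction {self.direction!r}")
        if self.is_pav and not self.is_cnv:
            raise InvariantError(f"{self.gene_id}: is_pav requires is_cnv")
        if (self.direction == "none") == self.is_cnv:
            raise InvariantError(
                f"{self.gene_id}: direction must be 'none' exactly when not a CNV"
            )

    @property
    def frac_significant(self) -> float:
        return self.n_significant / self.n_probes


@dataclass
class CallMatrix:
    """Boolean genes x individuals CNV matrix for one family."""

    family_id: str
    calls: pd.DataFrame  # bool, index gene_id, columns individual ids

    def __post_init__(self) -> None:
        if len(self.calls) and not all(
            self.calls.dtypes == bool
        ):
            raise InvariantError("call matrix must be boolean")
        if self.calls.index.has_duplicates or self.calls.columns.has_duplicates:
            raise InvariantError("duplicate gene or individual in call matrix")

    @property
    def genes(self) -> pd.Index:
        return self.calls.index

    @property
    def individuals(self) -> pd.Index:
        return self.calls.columns

    @property
    def carrier_counts(self) -> pd.Series:
        """Number of individuals carrying each gene CNV (row sums)."""
        return self.calls.sum(axis=1)

    @property
    def individual_counts(self) -> pd.Series:
        """Number of gene CNVs per individual (column sums)."""
        return self.calls.sum(axis=0)

    def gene_set(self) -> set:
        """Genes called in at least one individual."""
        return set(self.calls.index[self.calls.any(axis=1)])


@dataclass
class GeneticMap:
    """gene_id -> (linkage group, position in cM)."""

    positions: pd.DataFrame  # index gene_id, columns linkage_group, position

    def __post_init__(self) -> None:
        missing = {"linkage_group", "position"} - set(self.positions.columns)
        if missing:
            raise InvariantError(f"genetic map missing columns {sorted(missing)}")
        if self.positions.index.has_duplicates:
            dups = self.positions.index[self.positions.index.duplicated()][:3]
            raise InvariantError(f"duplicate map entries for genes {list(dups)}")
        if (self.positions["position"] < 0).any():
            raise InvariantError("map positions must be non-negative")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.positions.index

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class DetectionParams:
    """Operating point of the probe-threshold / gene-voting detector.

    tau
        probe-level |log2 ratio| threshold (strict inequality).
    frac
        minimum fraction of consistent-sign significant probes per gene.
    pav_tau
        |median M| above which a called gene is flagged presence/absence.
    min_probes
        minimum probes for a gene to be testable at all.
    """

    tau: float = TAU_43
    frac: float = 0.83
    pav_tau: float = 3.0
    min_probes: int = 6

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise InvariantError("tau must be > 0")
        if not (0 < self.frac <= 1):
            raise InvariantError("frac must be in (0, 1]")
        if self.pav_tau <= self.tau:
            raise InvariantError("pav_tau must exceed tau")
        if self.min_probes < 1:
            raise InvariantError("min_probes must be >= 1")
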