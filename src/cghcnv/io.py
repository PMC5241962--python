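"""Readers and writers for the pipeline's tab-separated table formats.

All files are UTF-8 TSV with a mandatory header row; lines starting with
``#`` are comments.  Every writer/reader pair round-trips losslessly.

Schemas
-------
probes.tsv       probe_id  gene_id  start  length  orientation
                 plus either a ``sequence`` column or a ``gc`` column
                 (optionally with ``frac_a frac_c frac_g frac_t``), and an
                 optional ``gene_length`` column.
intensities.tsv  array_id  probe_id  i_test_raw  i_test_bg  i_ref_raw  i_ref_bg
arrays.tsv       array_id  test_sample  ref_sample  family_id  self_self  dye_swap
ratios.tsv       array_id  probe_id  m  a  stage
calls.tsv        array_id  gene_id  n_probes  n_significant  frac_significant
                 direction  median_m  is_cnv  is_pav
map.tsv          gene_id  linkage_group  position
truth.tsv        individual  gene_id  cn_test  cn_ref  expected_m
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

from .model import (
    ArrayExperiment,
    GeneCall,
    GeneTarget,
    GeneticMap,
    InvariantError,
    ProbeDef,
    RatioTable,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_READ_KW = dict(sep="\t", comment="#", dtype={"probe_id": str, "gene_id": str},
                float_precision="round_trip")


def _read_tsv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, **_READ_KW)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return df


def _base_fractions_from_sequence(seq: str) -> tuple:
    seq = seq.upper()
    n = len(seq)
    counts = Counter(seq)
    bad = set(counts) - set("ACGT")
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters {sorted(bad)}")
    return tuple(counts[b] / n for b in "ACGT")


def read_probes(path: PathLike) -> List[GeneTarget]:
    """Read a probe table and group probes into :class:`GeneTarget` objects.

    GC fraction and base composition are computed from the ``sequence``
    column when present; otherwise a ``gc`` column is required and base
    fractions are taken from ``frac_a``..``frac_t`` columns, or split evenly
    between C/G and A/T when those are absent.
    """
    df = _read_tsv(path, ["probe_id", "gene_id", "start"])
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate probe_id {dup.iloc[0]!r}")
    if "length" not in df.columns:
        df["length"] = 60
    if "orientation" not in df.columns:
        df["orientation"] = "sense"

    has_seq = "sequence" in df.columns
    has_frac = all(f"frac_{b}" in df.columns for b in "acgt")

    genes: List[GeneTarget] = []
    for gene_id, sub in df.groupby("gene_id", sort=True):
        sub = sub.sort_values("start", kind="stable")
        probes = []
        for row in sub.itertuples(index=False):
            if has_seq:
                bf = _base_fractions_from_sequence(row.sequence)
                gc = bf[1] + bf[2]
            else:
                gc = float(row.gc)
                if has_frac:
                    bf = (
                        float(row.frac_a),
                        float(row.frac_c),
                        float(row.frac_g),
                        float(row.frac_t),
                    )
                else:
                    bf = ((1 - gc) / 2, gc / 2, gc - gc / 2, (1 - gc) - (1 - gc) / 2)
            probes.append(
                ProbeDef(
                    probe_id=str(row.probe_id),
                    gene_id=str(gene_id),
                    start=int(row.start),
                    length=int(row.length),
                    orientation=str(row.orientation),
                    gc=gc,
                    base_fractions=bf,
                )
            )
        if "gene_length" in df.columns:
            seq_length = int(sub["gene_length"].iloc[0])
            over = [p for p in probes if p.end > seq_length]
            if over:
                raise ValueError(
                    f"{path}: probe {over[0].probe_id} extends beyond "
                    f"gene_length {seq_length} of gene {gene_id}"
                )
        else:
            seq_length = max(p.end for p in probes)
        genes.append(GeneTarget(gene_id=str(gene_id), seq_length=seq_length, probes=tuple(probes)))
    return genes


def write_probes(genes: Iterable[GeneTarget], path: PathLike) -> None:
    rows = []
    for g in genes:
        for p in g.probes:
            rows.append(
                {
                    "probe_id": p.probe_id,
                    "gene_id": p.gene_id,
                    "start": p.start,
                    "length": p.length,
                    "orientation": p.orientation,
                    "gc": p.gc,
                    "frac_a": p.base_fractions[0],
                    "frac_c": p.base_fractions[1],
                    "frac_g": p.base_fractions[2],
                    "frac_t": p.base_fractions[3],
                    "gene_length": g.seq_length,
                }
            )
    cols = [
        "probe_id", "gene_id", "start", "length", "orientation",
        "gc", "frac_a", "frac_c", "frac_g", "frac_t", "gene_length",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False,
}


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    try:
        return _BOOL_MAP[str(value).strip().lower()]
    except KeyError:
        raise ValueError(f"cannot parse boolean value {value!r}") from None


def read_arrays(intensity_path: PathLike, metadata_path: PathLike) -> List[ArrayExperiment]:
    """Read intensity and array-metadata tables into experiments.

    Raises on arrays present in only one of the two files and on negative
    intensities.  Probes missing from an array relative to the union over
    all arrays are reported (logged), not errors.
    """
    intensities = _read_tsv(
        intensity_path,
        ["array_id", "probe_id", "i_test_raw", "i_test_bg", "i_ref_raw", "i_ref_bg"],
    )
    meta = _read_tsv(
        metadata_path,
        ["array_id", "test_sample", "ref_sample", "family_id", "self_self", "dye_swap"],
    )
    icols = ["i_test_raw", "i_test_bg", "i_ref_raw", "i_ref_bg"]
    neg = intensities[(intensities[icols] < 0).any(axis=1)]
    if len(neg):
        row = neg.iloc[0]
        raise ValueError(
            f"{intensity_path}: negative intensity for array {row['array_id']!r} "
            f"probe {row['probe_id']!r}"
        )
    int_arrays = set(intensities["array_id"].astype(str))
    meta_arrays = set(meta["array_id"].astype(str))
    only_int = sorted(int_arrays - meta_arrays)
    if only_int:
        raise ValueError(
            f"arrays present in intensities but not metadata: {only_int}"
        )
    only_meta = sorted(meta_arrays - int_arrays)
    if only_meta:
        raise ValueError(
            f"metadata rows without matching intensities: {only_meta}"
        )

    all_probes = set(intensities["probe_id"].astype(str))
    experiments: List[ArrayExperiment] = []
    grouped = dict(tuple(intensities.groupby("array_id", sort=False)))
    for row in meta.itertuples(index=False):
        array_id = str(row.array_id)
        sub = grouped[array_id] if array_id in grouped else grouped[row.array_id]
        measurements = {
            str(p): (float(a), float(b), float(c), float(d))
            for p, a, b, c, d in zip(
                sub["probe_id"], sub["i_test_raw"], sub["i_test_bg"],
                sub["i_ref_raw"], sub["i_ref_bg"],
            )
        }
        n_missing = len(all_probes) - len(measurements)
        if n_missing:
            logger.warning("array %s: %d probes missing", array_id, n_missing)
        family = None if pd.isna(row.family_id) or str(row.family_id) == "" else str(row.family_id)
        experiments.append(
            ArrayExperiment(
                array_id=array_id,
                test_sample=str(row.test_sample),
                ref_sample=str(row.ref_sample),
                family_id=family,
                self_self=_parse_bool(row.self_self),
                dye_swap=_parse_bool(row.dye_swap),
                measurements=measurements,
            )
        )
    return experiments


def write_arrays(experiments: Iterable[ArrayExperiment], intensity_path: PathLike,
                 metadata_path: PathLike) -> None:
    """Inverse of :func:`read_arrays`."""
    meta_rows, int_frames = [], []
    for exp in experiments:
        meta_rows.append(
            {
                "array_id": exp.array_id,
                "test_sample": exp.test_sample,
                "ref_sample": exp.ref_sample,
                "family_id": "" if exp.family_id is None else exp.family_id,
                "self_self": exp.self_self,
                "dye_swap": exp.dye_swap,
            }
        )
        probe_ids = list(exp.measurements)
        vals = np.array([exp.measurements[p] for p in probe_ids], dtype=float)
        int_frames.append(
            pd.DataFrame(
                {
                    "array_id": exp.array_id,
                    "probe_id": probe_ids,
                    "i_test_raw": vals[:, 0],
                    "i_test_bg": vals[:, 1],
                    "i_ref_raw": vals[:, 2],
                    "i_ref_bg": vals[:, 3],
                }
            )
        )
    pd.DataFrame(meta_rows).to_csv(metadata_path, sep="\t", index=False)
    pd.concat(int_frames, ignore_index=True).to_csv(intensity_path, sep="\t", index=False)


CALL_COLUMNS = [
    "array_id", "gene_id", "n_probes", "n_significant", "frac_significant",
    "direction", "median_m", "is_cnv", "is_pav",
]


def write_calls(calls: Sequence[GeneCall], path: PathLike) -> None:
    """Write gene calls as TSV; one row per (array_id, gene_id)."""
    rows = [
        {
            "array_id": c.array_id,
            "gene_id": c.gene_id,
            "n_probes": c.n_probes,
            "n_significant": c.n_significant,
            "frac_significant": c.frac_significant,
            "direction": c.direction,
            "median_m": c.median_m,
            "is_cnv": c.is_cnv,
            "is_pav": c.is_pav,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_calls(path: PathLike) -> List[GeneCall]:
    df = _read_tsv(path, [c for c in CALL_COLUMNS if c != "frac_significant"])
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            GeneCall(
                array_id=str(row.array_id),
                gene_id=str(row.gene_id),
                n_probes=int(row.n_probes),
                n_significant=int(row.n_significant),
                direction=str(row.direction),
                median_m=float(row.median_m),
                is_cnv=_parse_bool(row.is_cnv),
                is_pav=_parse_bool(row.is_pav),
            )
        )
    return calls


def write_ratios(tables: Iterable[RatioTable], path: PathLike) -> None:
    frames = []
    for t in tables:
        frames.append(
            pd.DataFrame(
                {
                    "array_id": t.array_id,
                    "probe_id": t.data.index,
                    "m": t.data["M"].to_numpy(),
                    "a": t.data["A"].to_numpy(),
                    "stage": t.stage,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_ratios(path: PathLike) -> List[RatioTable]:
    df = _read_tsv(path, ["array_id", "probe_id", "m", "a", "stage"])
    tables = []
    for array_id, sub in df.groupby("array_id", sort=False):
        stages = sub["stage"].unique()
        if len(stages) != 1:
            raise ValueError(f"{path}: array {array_id} mixes stages {list(stages)}")
        data = pd.DataFrame(
            {"M": sub["m"].to_numpy(float), "A": sub["a"].to_numpy(float)},
            index=pd.Index(sub["probe_id"].astype(str), name="probe_id"),
        )
        tables.append(RatioTable(str(array_id), data, stage=str(stages[0])))
    return tables


def read_map(path: PathLike) -> GeneticMap:
    df = _read_tsv(path, ["gene_id", "linkage_group", "position"])
    positions = pd.DataFrame(
        {
            "linkage_group": df["linkage_group"].astype(str).to_numpy(),
            "position": df["position"].to_numpy(float),
        },
        index=pd.Index(df["gene_id"].astype(str), name="gene_id"),
    )
    return GeneticMap(positions)


def write_map(gmap: GeneticMap, path: PathLike) -> None:
    out = gmap.positions.reset_index()
    out.columns = ["gene_id", "linkage_group", "position"]
    out.to_csv(path, sep="\t", index=False)


def write_truth(truth: pd.DataFrame, path: PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: PathLike) -> pd.DataFrame:
    return _read_tsv(path, ["individual", "gene_id", "cn_test", "cn_ref", "expected_m"])
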