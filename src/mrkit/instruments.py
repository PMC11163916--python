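"""Instrumental-variable selection for one exposure.

Pipeline: genome-wide p-value thresholding (5e-8, relaxed to 5e-6 when too
few variants pass), greedy LD clumping (window 10,000 kb, r^2 < 0.001),
per-variant variance explained R^2 = 2*MAF*(1-MAF)*beta^2, the instrument
strength F = [R^2/(1-R^2)] * [(n-k-1)/k], and exclusion of weak instruments
with F < 10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import SumStatRecord

__all__ = [
    "LDMatrix",
    "InstrumentSet",
    "select_by_pvalue",
    "clump",
    "variance_explained",
    "f_statistic",
    "filter_weak",
    "build_instrument_set",
]

P_PRIMARY = 5e-8
P_FALLBACK = 5e-6
CLUMP_WINDOW_KB = 10_000
CLUMP_R2_MAX = 0.001
F_MIN = 10.0


@dataclass
class LDMatrix:
    """Squared-correlation (r^2) matrix over an ordered set of variants.

    Pairs absent from the matrix are treated as unlinked (r^2 = 0) with a
    warning, so a partial matrix degrades gracefully.
    """

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 matrix shape {self.r2.shape} does not match {k} variant ids")
        if k:
            if not np.allclose(self.r2, self.r2.T):
                raise ValueError("r2 matrix is not symmetric")
            if not np.allclose(np.diag(self.r2), 1.0):
                raise ValueError("r2 matrix diagonal is not 1")
            if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
                raise ValueError("r2 entries outside [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def lookup(self, id1: str, id2: str, warn_missing: bool = True) -> float:
        """r^2 between two variants; 0 (with a warning) if either is absent."""
        i = self._index.get(id1)
        j = self._index.get(id2)
        if i is None or j is None:
            if warn_missing:
                warnings.warn(
                    f"LD pair ({id1}, {id2}) not in matrix; assuming r2=0", stacklevel=2
                )
            return 0.0
        return float(self.r2[i, j])

    @classmethod
    def empty(cls) -> "LDMatrix":
        return cls([], np.zeros((0, 0)))

    @classmethod
    def from_file(cls, path: str | Path, sep: str = "\t") -> "LDMatrix":
        """Read a square matrix (header row/column of ids) or long-format
        ``id1, id2, r2`` triplets; the format is sniffed from the header."""
        df = pd.read_csv(path, sep=sep)
        if list(df.columns[:3]) == ["id1", "id2", "r2"]:
            ids = sorted(set(df["id1"]).union(df["id2"]))
            idx = {v: i for i, v in enumerate(ids)}
            mat = np.eye(len(ids))
            for _, row in df.iterrows():
                i, j = idx[row["id1"]], idx[row["id2"]]
                mat[i, j] = mat[j, i] = float(row["r2"])
            return cls(ids, mat)
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def to_file(self, path: str | Path, sep: str = "\t") -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep=sep
        )


@dataclass
class InstrumentSet:
    """Post-selection instruments for one exposure with strength statistics."""

    exposure_id: str
    records: list[SumStatRecord]
    threshold_used: Optional[float]
    r2_explained: dict = field(default_factory=dict)  # variant_id -> R^2
    f_stat: dict = field(default_factory=dict)  # variant_id -> per-variant F (k=1)
    aggregate_f: Optional[float] = None
    selection_log: list = field(default_factory=list)  # (variant_id, stage, action, detail)

    def __len__(self) -> int:
        return len(self.records)

    def log_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.selection_log, columns=["variant_id", "stage", "action", "detail"]
        )


def select_by_pvalue(
    records: Sequence[SumStatRecord],
    p_primary: float = P_PRIMARY,
    p_fallback: float = P_FALLBACK,
    min_count: int = 3,
) -> tuple[list[SumStatRecord], Optional[float]]:
    """Threshold at ``p_primary``; if fewer than ``min_count`` variants pass,
    relax to ``p_fallback``. Returns ``(records, threshold_used)`` with
    ``threshold_used=None`` when nothing passes either threshold."""
    primary = [r for r in records if r.pval < p_primary]
    if len(primary) >= min_count:
        return primary, p_primary
    fallback = [r for r in records if r.pval < p_fallback]
    if fallback:
        return fallback, p_fallback
    warnings.warn("no variants pass either significance threshold", stacklevel=2)
    return [], None


def clump(
    records: Sequence[SumStatRecord],
    ld: Optional[LDMatrix] = None,
    window_kb: float = CLUMP_WINDOW_KB,
    r2_max: float = CLUMP_R2_MAX,
) -> list[SumStatRecord]:
    """Greedy LD clumping.

    Repeatedly take the remaining variant with the smallest p-value as an
    index (ties broken by lexicographic variant_id) and remove every other
    variant on the same chromosome within ``window_kb`` kilobases whose r^2
    with the index is at least ``r2_max``. The retained index variants are
    returned sorted by (chrom, pos).
    """
    missing = [r.variant_id for r in records if r.chrom is None or r.pos is None]
    if missing:
        raise ValueError(f"records lack chrom/pos required for clumping: {missing}")
    if ld is None:
        warnings.warn("no LD matrix supplied; clumping assumes r2=0 everywhere", stacklevel=2)
        ld = LDMatrix.empty()
    remaining = sorted(records, key=lambda r: (r.pval, r.variant_id))
    kept: list[SumStatRecord] = []
    window_bp = window_kb * 1000.0
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for r in remaining:
            if (
                r.chrom == index.chrom
                and abs(r.pos - index.pos) <= window_bp
                and ld.lookup(index.variant_id, r.variant_id, warn_missing=False) >= r2_max
            ):
                continue  # clumped away
            survivors.append(r)
        remaining = survivors
    return sorted(kept, key=lambda r: (r.chrom, r.pos))


def variance_explained(eaf: float, beta: float) -> float:
    """Proportion of phenotypic variance explained: 2*MAF*(1-MAF)*beta^2."""
    if not (0 < eaf < 1):
        raise ValueError(f"eaf must be in (0, 1), got {eaf}")
    maf = min(eaf, 1.0 - eaf)
    r2 = 2.0 * maf * (1.0 - maf) * beta * beta
    if r2 >= 1.0:
        warnings.warn(f"R^2 formula gave {r2}; capping below 1", stacklevel=2)
        r2 = 1.0 - 1e-12
    return r2


def f_statistic(r2: float, n: float, k: int = 1) -> float:
    """Instrument-strength F = [R^2/(1-R^2)] * [(n-k-1)/k].

    Per-variant usage takes ``k=1`` with that variant's R^2; aggregate usage
    takes ``k`` = number of instruments with the summed R^2.
    """
    if not (0 <= r2 < 1):
        raise ValueError(f"r2 must be in [0, 1), got {r2}")
    if n <= k + 1:
        raise ValueError(f"need n > k+1 (n={n}, k={k})")
    return (r2 / (1.0 - r2)) * ((n - k - 1.0) / k)


def filter_weak(instrument_set: InstrumentSet, f_min: float = F_MIN) -> InstrumentSet:
    """Drop instruments whose per-variant F is below ``f_min`` (removals logged)."""
    kept, log = [], list(instrument_set.selection_log)
    for rec in instrument_set.records:
        f = instrument_set.f_stat.get(rec.variant_id)
        if f is not None and f < f_min:
            log.append((rec.variant_id, "f_filter", "removed", f"F={f:.4g} < {f_min}"))
        else:
            kept.append(rec)
    if not kept and instrument_set.records:
        warnings.warn(
            f"all instruments for {instrument_set.exposure_id} are weak (F < {f_min})",
            stacklevel=2,
        )
    out = InstrumentSet(
        exposure_id=instrument_set.exposure_id,
        records=kept,
        threshold_used=instrument_set.threshold_used,
        r2_explained={r.variant_id: instrument_set.r2_explained[r.variant_id] for r in kept if r.variant_id in instrument_set.r2_explained},
        f_stat={r.variant_id: instrument_set.f_stat[r.variant_id] for r in kept if r.variant_id in instrument_set.f_stat},
        selection_log=log,
    )
    _set_aggregate_f(out)
    return out


def _set_aggregate_f(iset: InstrumentSet) -> None:
    ns = [r.n for r in iset.records if r.n is not None]
    if not ns or not iset.r2_explained or len(iset.records) == 0:
        iset.aggregate_f = None
        return
    total_r2 = min(sum(iset.r2_explained.values()), 1.0 - 1e-12)
    n = float(np.median(ns))
    k = len(iset.records)
    if n > k + 1:
        iset.aggregate_f = f_statistic(total_r2, n, k)
    else:
        iset.aggregate_f = None


def build_instrument_set(
    exposure_id: str,
    records: Sequence[SumStatRecord],
    ld: Optional[LDMatrix] = None,
    p_primary: float = P_PRIMARY,
    p_fallback: float = P_FALLBACK,
    min_count: int = 3,
    window_kb: float = CLUMP_WINDOW_KB,
    r2_max: float = CLUMP_R2_MAX,
    f_min: float = F_MIN,
) -> InstrumentSet:
    """Full selection pipeline: threshold -> clump -> R^2/F -> weak filter.

    Clumping is skipped (with a warning) when positions are unavailable;
    the F computation and filter are skipped when ``eaf`` or ``n`` is
    missing, each with a warning, mirroring how incomplete public summary
    files degrade the analysis.
    """
    log: list = []
    selected, threshold = select_by_pvalue(records, p_primary, p_fallback, min_count)
    selected_ids = {r.variant_id for r in selected}
    for r in records:
        if r.variant_id not in selected_ids:
            log.append((r.variant_id, "pvalue", "removed", f"p={r.pval:.3g}"))
    if threshold is not None and threshold != p_primary:
        log.append(("*", "pvalue", "fallback", f"threshold relaxed to {threshold:g}"))

    if selected and all(r.chrom is not None and r.pos is not None for r in selected):
        clumped = clump(selected, ld, window_kb, r2_max)
        dropped = {r.variant_id for r in selected} - {r.variant_id for r in clumped}
        for v in sorted(dropped):
            log.append((v, "clump", "removed", "in LD with a better index variant"))
    else:
        if selected:
            warnings.warn("positions unavailable; clumping skipped", stacklevel=2)
        clumped = list(selected)

    r2_map: dict = {}
    f_map: dict = {}
    for r in clumped:
        if r.eaf is None:
            continue
        r2 = variance_explained(r.eaf, r.beta)
        r2_map[r.variant_id] = r2
        if r.n is not None and r.n > 2:
            f_map[r.variant_id] = f_statistic(r2, r.n, k=1)
    if clumped and not f_map:
        warnings.warn("eaf or n unavailable; F-statistic filter skipped", stacklevel=2)

    iset = InstrumentSet(
        exposure_id=exposure_id,
        records=clumped,
        threshold_used=threshold,
        r2_explained=r2_map,
        f_stat=f_map,
        selection_log=log,
    )
    return filter_weak(iset, f_min)
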