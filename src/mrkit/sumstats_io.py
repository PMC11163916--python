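"""Reading and writing GWAS summary-statistic tables.

Files are delimited text (TSV by default, CSV accepted, gzip transparently)
whose column names are declared by a :class:`Dialect` mapping logical field
names (``variant_id``, ``beta``, ...) to the physical column headers of a
particular source. Validation is total: every input row either becomes a
valid :class:`~mrkit.records.SumStatRecord` or lands in the reject log with
a reason, so row counts always reconcile.
"""

from __future__ import annotations

import json
import math
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .records import SumStatRecord, validate_record

__all__ = [
    "Dialect",
    "RejectedRow",
    "read_sumstats",
    "write_sumstats",
    "write_reject_log",
    "deduplicate",
    "REQUIRED_FIELDS",
    "OPTIONAL_FIELDS",
]

REQUIRED_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")
OPTIONAL_FIELDS = ("chrom", "pos", "eaf", "n")

#: smallest positive double, used when a dialect opts into p-value clamping
_P_FLOOR = sys.float_info.min


@dataclass
class Dialect:
    """Column-name mapping plus parsing options for one summary-stat source.

    ``columns`` maps logical field names to physical column headers. All six
    required fields must be mapped; optional fields may be omitted, which
    disables the downstream steps that need them (clumping needs ``pos``,
    palindrome resolution needs ``eaf``, the F-statistic needs ``n``).
    """

    columns: dict = field(default_factory=lambda: {f: f for f in REQUIRED_FIELDS + OPTIONAL_FIELDS})
    sep: str = "\t"
    missing: str = "NA"
    pval_floor: bool = False

    def __post_init__(self) -> None:
        missing_cols = [f for f in REQUIRED_FIELDS if f not in self.columns]
        if missing_cols:
            raise ValueError(f"dialect does not map required columns: {missing_cols}")

    @classmethod
    def from_file(cls, path: str | Path) -> "Dialect":
        """Load a dialect from a YAML or JSON config file."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**data)

    def mapped_optional(self) -> list[str]:
        return [f for f in OPTIONAL_FIELDS if f in self.columns]


@dataclass(frozen=True)
class RejectedRow:
    row_number: int  # 1-based data-row index
    reason: str


def _parse_float(value, missing: str) -> Optional[float]:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s == missing or s.lower() in ("nan", "na", "none", "."):
        return None
    return float(s)


def read_sumstats(
    path: str | Path,
    dialect: Optional[Dialect] = None,
) -> tuple[list[SumStatRecord], list[RejectedRow]]:
    """Read a summary-statistics table into validated records.

    Returns ``(records, rejects)``; row order is preserved and
    ``rows_in == len(records) + len(rejects)``.

    Raises
    ------
    ValueError
        If a required column declared in the dialect is absent from the file.
    OSError
        If the file cannot be read.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    phys_required = [dialect.columns[f] for f in REQUIRED_FIELDS]
    absent = [c for c in phys_required if c not in df.columns]
    if absent:
        raise ValueError(f"required columns missing from {path}: {absent}")
    present_optional = [f for f in dialect.mapped_optional() if dialect.columns[f] in df.columns]

    records: list[SumStatRecord] = []
    rejects: list[RejectedRow] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        try:
            kwargs = {
                "variant_id": str(row_d[dialect.columns["variant_id"]]).strip(),
                "effect_allele": str(row_d[dialect.columns["effect_allele"]]).strip().upper(),
                "other_allele": str(row_d[dialect.columns["other_allele"]]).strip().upper(),
                "beta": _parse_float(row_d[dialect.columns["beta"]], dialect.missing),
                "se": _parse_float(row_d[dialect.columns["se"]], dialect.missing),
                "pval": _parse_float(row_d[dialect.columns["pval"]], dialect.missing),
            }
            for f in present_optional:
                raw = row_d[dialect.columns[f]]
                if f == "chrom":
                    s = str(raw).strip()
                    kwargs["chrom"] = s if s and s != dialect.missing else None
                elif f == "pos":
                    v = _parse_float(raw, dialect.missing)
                    kwargs["pos"] = None if v is None else int(v)
                else:
                    kwargs[f] = _parse_float(raw, dialect.missing)
        except (ValueError, TypeError) as exc:
            rejects.append(RejectedRow(i, f"unparseable value: {exc}"))
            continue
        if kwargs["beta"] is None or kwargs["se"] is None or kwargs["pval"] is None:
            rejects.append(RejectedRow(i, "missing required value"))
            continue
        if kwargs["pval"] == 0.0:
            if dialect.pval_floor:
                kwargs["pval"] = _P_FLOOR
            else:
                rejects.append(RejectedRow(i, "p-value of zero (enable pval_floor to clamp)"))
                continue
        rec = SumStatRecord(**kwargs)
        problems = validate_record(rec)
        if problems:
            rejects.append(RejectedRow(i, "; ".join(problems)))
        else:
            records.append(rec)
    return records, rejects


def _fmt(value, missing: str) -> str:
    if value is None:
        return missing
    if isinstance(value, float) and math.isnan(value):
        return missing
    return str(value)


def write_sumstats(
    records: Iterable[SumStatRecord],
    path: str | Path,
    dialect: Optional[Dialect] = None,
) -> None:
    """Write records to a delimited file; round-trips through :func:`read_sumstats`."""
    dialect = dialect or Dialect()
    fields = list(REQUIRED_FIELDS) + dialect.mapped_optional()
    header = [dialect.columns[f] for f in fields]
    rows = [{dialect.columns[f]: _fmt(getattr(r, f), dialect.missing) for f in fields} for r in records]
    df = pd.DataFrame(rows, columns=header)
    df.to_csv(path, sep=dialect.sep, index=False)


def write_reject_log(rejects: Sequence[RejectedRow], path: str | Path) -> None:
    pd.DataFrame(
        [(r.row_number, r.reason) for r in rejects], columns=["row_number", "reason"]
    ).to_csv(path, sep="\t", index=False)


def deduplicate(
    records: Sequence[SumStatRecord],
) -> tuple[list[SumStatRecord], list[tuple[str, str]]]:
    """Keep one record per variant_id: the smallest p-value wins, ties go to
    the first-encountered record.

    Returns ``(records, log)`` where the log lists ``(variant_id, action)``
    entries for every dropped duplicate.
    """
    best: dict[str, SumStatRecord] = {}
    order: list[str] = []
    log: list[tuple[str, str]] = []
    for rec in records:
        cur = best.get(rec.variant_id)
        if cur is None:
            best[rec.variant_id] = rec
            order.append(rec.variant_id)
        elif rec.pval < cur.pval:
            log.append((rec.variant_id, f"dropped duplicate with pval {cur.pval}"))
            best[rec.variant_id] = rec
        elif rec.pval == cur.pval:
            log.append((rec.variant_id, "dropped tied duplicate (first kept)"))
        else:
            log.append((rec.variant_id, f"dropped duplicate with pval {rec.pval}"))
    return [best[v] for v in order], log
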