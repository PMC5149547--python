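"""Readers and writers for summary-statistics and pairwise-LD tables.

Summary statistics are tab-delimited with a header; required columns are
SNP, CHR, BP plus an association column — either P (p-values, converted to
traditional 1-df chi-squares downstream) or CHISQ (an optional CONVENTION
column marks doubled-scale values, default traditional).  When both P and
CHISQ are present, CHISQ wins.

LD input follows the PLINK ``.ld`` pair dialect: whitespace-delimited
columns CHR_A BP_A SNP_A CHR_B BP_B SNP_B R2; only pairs involving the
index variant are used.

All outputs are UTF-8, LF-terminated, 1-based coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .screen import MarkerRecord
from .twosite import AssociationStat, Convention

__all__ = [
    "RunConfig",
    "read_sumstats",
    "read_ld",
    "build_records",
    "write_sumstats",
    "write_ld",
]

logger = logging.getLogger(__name__)

_SUMSTATS_REQUIRED = ("SNP", "CHR", "BP")


class InputFormatError(ValueError):
    """A file is missing required structure (not just bad rows)."""


@dataclass
class RunConfig:
    """Declarative run parameters, mergeable from a YAML config file.

    Values given on the command line take precedence over the file; every
    stochastic run records its seed in the output metadata.
    """

    seed: int = 0
    out_prefix: str = "ldfine_run"
    convention: Convention = "traditional_1df"
    verbosity: str = "INFO"
    extra: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InputFormatError(f"config {path} must be a mapping")
        known = {k: raw.pop(k) for k in ("seed", "out_prefix", "convention", "verbosity") if k in raw}
        return cls(extra=raw, **known)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read and validate a summary-statistics table.

    Returns a frame with columns SNP, CHR, BP, CHISQ, CONVENTION, with
    every statistic already on the scale named by its CONVENTION entry.
    Malformed rows (non-numeric or non-positive BP, missing association,
    P outside (0, 1)) are dropped with their line numbers logged; counts
    of accepted and rejected rows are logged and stored in
    ``df.attrs['n_rejected']``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SUMSTATS_REQUIRED if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing required columns {missing}; found {list(df.columns)}")
    has_p, has_chisq = "P" in df.columns, "CHISQ" in df.columns
    if not has_p and not has_chisq:
        raise InputFormatError(f"{path}: need an association column, P or CHISQ")
    if has_p and has_chisq:
        logger.info("%s: both P and CHISQ present; CHISQ takes precedence", path)

    rows, n_rejected = [], 0
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        snp, chrom = row["SNP"], row["CHR"]
        try:
            bp = int(row["BP"])
            if bp < 1:
                raise ValueError("BP must be >= 1")
            if pd.isna(snp) or not str(snp).strip():
                raise ValueError("empty SNP id")
            convention = "traditional_1df"
            if has_chisq and not pd.isna(row["CHISQ"]):
                chisq = float(row["CHISQ"])
                if not math.isfinite(chisq) or chisq < 0.0:
                    raise ValueError(f"bad CHISQ {row['CHISQ']}")
                if "CONVENTION" in df.columns and not pd.isna(row["CONVENTION"]):
                    convention = str(row["CONVENTION"])
                    if convention not in ("pp_doubled", "traditional_1df"):
                        raise ValueError(f"unknown CONVENTION {convention!r}")
            elif has_p and not pd.isna(row["P"]):
                from .inference import chi2_p_convert

                pval = float(row["P"])
                chisq = chi2_p_convert(pval, "p_to_stat", "traditional_1df")
            else:
                raise ValueError("no association value")
        except (TypeError, ValueError) as exc:
            logger.warning("%s line %d rejected: %s", path, line_no, exc)
            n_rejected += 1
            continue
        rows.append(
            {"SNP": str(snp), "CHR": str(chrom), "BP": bp, "CHISQ": chisq, "CONVENTION": convention}
        )
    out = pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "CHISQ", "CONVENTION"])
    out.attrs["n_rejected"] = n_rejected
    logger.info("%s: accepted %d rows, rejected %d", path, len(out), n_rejected)
    return out


def read_ld(path: str | Path, index_snp: str) -> dict[str, float]:
    """Map variant id -> r2 with ``index_snp`` from a PLINK-style .ld file.

    Pairs not involving the index are ignored; on duplicate pairs the last
    value wins with a warning; rows with R2 outside [0, 1] are rejected.
    The index variant itself always maps to 1.0.  A file containing no
    pair with the index is an error.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    required = ("SNP_A", "SNP_B", "R2")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputFormatError(f"{path}: missing required columns {missing}")
    out: dict[str, float] = {}
    for i, row in df.iterrows():
        a, b = str(row["SNP_A"]), str(row["SNP_B"])
        if index_snp not in (a, b):
            continue
        other = b if a == index_snp else a
        try:
            r2 = float(row["R2"])
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"R2={r2} outside [0, 1]")
        except (TypeError, ValueError) as exc:
            logger.warning("%s line %d rejected: %s", path, i + 2, exc)
            continue
        if other in out and out[other] != r2:
            logger.warning("%s: duplicate pair for %s; keeping last value %g", path, other, r2)
        out[other] = r2
    if not out:
        raise InputFormatError(f"{path}: no LD pair involves index variant {index_snp!r}")
    out[index_snp] = 1.0
    return out


def build_records(sumstats: pd.DataFrame, ld: dict[str, float]) -> list[MarkerRecord]:
    """Join validated sumstats with the index-anchored LD map.

    Markers without an LD entry are dropped (logged); the result feeds
    :func:`ldfine.screen.fit_decay` directly.
    """
    records: list[MarkerRecord] = []
    n_no_ld = 0
    for row in sumstats.itertuples(index=False):
        if row.SNP not in ld:
            n_no_ld += 1
            continue
        records.append(
            MarkerRecord(
                snp=row.SNP,
                chrom=row.CHR,
                pos=row.BP,
                chi2=AssociationStat(row.CHISQ, row.CONVENTION),
                r2=ld[row.SNP],
            )
        )
    if n_no_ld:
        logger.info("dropped %d markers without LD data for the index", n_no_ld)
    return records


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    """Write a summary-statistics table (tab-delimited, header, LF)."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_ld(df: pd.DataFrame, path: str | Path) -> None:
    """Write a PLINK-dialect .ld pair table (whitespace-delimited)."""
    cols = ["CHR_A", "BP_A", "SNP_A", "CHR_B", "BP_B", "SNP_B", "R2"]
    df.to_csv(path, sep=" ", index=False, columns=cols, lineterminator="\n")
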