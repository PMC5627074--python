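"""Readers and writers for standard bisulfite-call formats.

Coordinates are 1-based internally, matching Bismark cytosine reports; the
two cytosines of one CpG unit (plus-strand C at ``pos``, minus-strand C at
``pos + 1``) are re-keyed onto the plus-strand position so both strands of
a unit share a key. BED output converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import READ_CALL_COLUMNS

__all__ = [
    "SiteStrandCounts",
    "read_cytosine_report",
    "cytosine_report_to_units",
    "read_per_read_calls",
    "write_asymmetric_sites_bed",
]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class SiteStrandCounts:
    """Strand-resolved counts at one CpG unit key."""

    chrom: str
    pos: int  # 1-based plus-strand C of the unit
    strand: str
    M: int
    U: int

    def __post_init__(self) -> None:
        if self.M < 0 or self.U < 0:
            raise FormatError("negative read count")


_STRAND_MAP = {"+": "plus", "-": "minus", "plus": "plus", "minus": "minus"}

# Complementary bisulfite strands collapse to the ORIGINAL strand they
# report on (non-directional libraries): OT/CTOT -> plus, OB/CTOB -> minus.
_BISMARK_STRAND_MAP = {"OT": "plus", "CTOT": "plus", "OB": "minus", "CTOB": "minus"}


def read_cytosine_report(path, cpg_only: bool = True) -> list[SiteStrandCounts]:
    """Parse a Bismark-style cytosine report into per-unit strand counts.

    Expected columns (tab-separated, no header):
    chrom, pos (1-based), strand (+/-), count_methylated, count_unmethylated,
    context [, trinucleotide]. Minus-strand rows are re-keyed to ``pos - 1``
    so both strands of one CpG share the plus-strand C position.
    """
    out: list[SiteStrandCounts] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >=6 columns, got {len(fields)}")
            chrom, pos_s, strand_sym, m_s, u_s, context = fields[:6]
            if strand_sym not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand symbol {strand_sym!r}")
            if cpg_only and context.upper() not in ("CPG", "CG"):
                continue
            try:
                pos, m, u = int(pos_s), int(m_s), int(u_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field ({exc})") from None
            strand = _STRAND_MAP[strand_sym]
            unit_pos = pos - 1 if strand == "minus" else pos
            out.append(SiteStrandCounts(chrom=chrom, pos=unit_pos, strand=strand, M=m, U=u))
    return out


def cytosine_report_to_units(records: list[SiteStrandCounts]) -> pd.DataFrame:
    """Pivot strand-count records into a unit-count frame.

    Columns: chrom, pos, M_plus, U_plus, M_minus, U_minus; units missing a
    strand get zero counts there.
    """
    if not records:
        return pd.DataFrame(
            columns=["chrom", "pos", "M_plus", "U_plus", "M_minus", "U_minus"]
        )
    df = pd.DataFrame([r.__dict__ for r in records])
    df = df.groupby(["chrom", "pos", "strand"], as_index=False)[["M", "U"]].sum()
    wide = df.pivot_table(
        index=["chrom", "pos"], columns="strand", values=["M", "U"], fill_value=0
    )
    out = pd.DataFrame(
        {
            "M_plus": wide.get(("M", "plus"), 0),
            "U_plus": wide.get(("U", "plus"), 0),
            "M_minus": wide.get(("M", "minus"), 0),
            "U_minus": wide.get(("U", "minus"), 0),
        }
    ).reset_index()
    return out.astype(
        {c: int for c in ["M_plus", "U_plus", "M_minus", "U_minus"]}
    ).sort_values(["chrom", "pos"], ignore_index=True)


def read_per_read_calls(path, trim_bp: int = 0, dialect: str = "canonical") -> pd.DataFrame:
    """Read per-read CpG calls into the canonical read-call frame.

    ``dialect='canonical'`` expects the tab-separated table written by the
    simulator (header ``read_id sample replicate group locus strand cpg_pos
    state``, optionally ``read_offset``); ``dialect='bismark'`` accepts
    methylation-extractor CpG output (read_id, strand code OT/OB/CTOT/CTOB
    or +/-, chrom, pos, call letter Z/z).

    ``trim_bp > 0`` discards calls within that many bases of either read
    end and requires a ``read_offset`` column (distance of the call from
    the nearer read end); without it the trim is refused rather than
    silently skipped.
    """
    if trim_bp < 0:
        raise FormatError("trim_bp must be >= 0")
    if dialect == "canonical":
        df = pd.read_csv(path, sep="\t", dtype={"cpg_pos": "int64"}) if _nonempty(path) else None
        if df is None or df.empty:
            return pd.DataFrame(columns=READ_CALL_COLUMNS)
        missing = set(READ_CALL_COLUMNS) - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        if trim_bp > 0:
            if "read_offset" not in df.columns:
                raise FormatError(
                    "trim requested but no read_offset column is present"
                )
            df = df[df["read_offset"] >= trim_bp]
        return df[READ_CALL_COLUMNS].reset_index(drop=True)
    if dialect == "bismark":
        if not _nonempty(path):
            return pd.DataFrame(columns=READ_CALL_COLUMNS)
        with open(path) as fh:
            first = fh.readline()
        skip = 1 if first.startswith("Bismark") else 0  # version banner line
        df = pd.read_csv(
            path,
            sep="\t",
            skiprows=skip,
            header=None,
            names=["read_id", "code", "chrom", "pos", "call"],
        )
        strand = df["code"].map(lambda c: _BISMARK_STRAND_MAP.get(c, _STRAND_MAP.get(c)))
        if strand.isna().any():
            bad = df.loc[strand.isna(), "code"].iloc[0]
            raise FormatError(f"unknown strand code {bad!r}")
        if trim_bp > 0:
            raise FormatError("bismark extractor output carries no read offsets; trim upstream")
        unit_pos = df["pos"].where(strand == "plus", df["pos"] - 1)
        return pd.DataFrame(
            {
                "read_id": df["read_id"],
                "sample": "NA",
                "replicate": "NA",
                "group": "na",
                "locus": df["chrom"],
                "strand": strand,
                "cpg_pos": unit_pos.astype(int),
                "state": np.where(df["call"].str.isupper(), "M", "U"),
            }
        )
    raise FormatError(f"unknown dialect: {dialect!r}")


def _nonempty(path) -> bool:
    with open(path) as fh:
        return bool(fh.readline().strip())


def write_asymmetric_sites_bed(units: pd.DataFrame, path) -> None:
    """Write flagged CpG units as BED covering the dinucleotide.

    1-based unit pos maps to 0-based half-open [pos-1, pos+1); the score is
    ``round(|delta_b| * 1000)``.
    """
    with open(path, "w") as fh:
        for row in units.itertuples(index=False):
            delta = getattr(row, "delta_b", 0.0)
            score = int(round(abs(delta) * 1000))
            name = f"{row.chrom}:{row.pos}"
            fh.write(
                f"{row.chrom}\t{row.pos - 1}\t{row.pos + 1}\t{name}\t{score}\t.\n"
            )
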