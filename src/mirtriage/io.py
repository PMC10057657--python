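"""Tabular I/O with strict validation.

All tables are TSV with a single header row, decimal points and no
thousands separators. Lines starting with ``#`` are provenance comments
and are skipped on read. Fold changes follow the signed linear
convention used throughout: values in the open interval (-1, 1) are
illegal, and -1.5 means 1.5-fold down.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COMPARISONS = ("TvN", "F1vT")
GROUPS = ("N", "T", "F1")
FRACTIONS = ("membrane", "cytosolic")
REGIONS = ("3UTR", "5UTR", "CDS")
MRNA_STATUSES = ("absent", "discordant", "concordant")


class FormatError(ValueError):
    """A malformed table or a record violating a type invariant."""


def _check_signed_fc(fc: float, ctx: str) -> None:
    if not math.isfinite(fc):
        raise FormatError(f"{ctx}: fold_change must be finite, got {fc!r}")
    if -1.0 < fc < 1.0:
        raise FormatError(
            f"{ctx}: fold_change {fc} lies in (-1, 1); signed linear "
            "fold changes report k-fold down as -k"
        )


def _check_p(p: float, ctx: str) -> None:
    if not (0.0 < p <= 1.0):
        raise FormatError(f"{ctx}: p_value must be in (0, 1], got {p!r}")


@dataclass(frozen=True)
class TargetRecord:
    """One predicted miRNA -> gene interaction with its filter fields."""

    mirna_id: str
    gene_symbol: str
    binding_probability: float
    region: str
    validated: bool
    source: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.binding_probability <= 1.0):
            raise FormatError(
                f"target {self.mirna_id}->{self.gene_symbol}: binding_probability "
                f"{self.binding_probability} outside [0, 1]"
            )
        if self.region not in REGIONS:
            raise FormatError(
                f"target {self.mirna_id}->{self.gene_symbol}: unknown region "
                f"{self.region!r} (expected one of {REGIONS})"
            )


@dataclass(frozen=True)
class ProteinDEEntry:
    """One protein fold change in one (comparison, subcellular fraction) cell."""

    gene_symbol: str
    comparison: str
    fraction: str
    fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        ctx = f"protein {self.gene_symbol} {self.comparison}/{self.fraction}"
        if self.comparison not in COMPARISONS:
            raise FormatError(f"{ctx}: unknown comparison {self.comparison!r}")
        if self.fraction not in FRACTIONS:
            raise FormatError(f"{ctx}: unknown fraction {self.fraction!r}")
        _check_signed_fc(self.fold_change, ctx)
        _check_p(self.p_value, ctx)


@dataclass(frozen=True)
class MrnaDEEntry:
    """One mRNA fold change in one comparison (no fraction dimension)."""

    gene_symbol: str
    comparison: str
    fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        ctx = f"mRNA {self.gene_symbol} {self.comparison}"
        if self.comparison not in COMPARISONS:
            raise FormatError(f"{ctx}: unknown comparison {self.comparison!r}")
        _check_signed_fc(self.fold_change, ctx)
        _check_p(self.p_value, ctx)


@dataclass(frozen=True)
class AttributionHit:
    """One (miRNA, protein, comparison, fraction) inverse-direction match.

    ``mirna_fc`` and ``protein_fc`` always have strictly opposite signs;
    hits surviving the mRNA-concordance elimination never carry
    ``mrna_status == "concordant"``.
    """

    mirna_id: str
    gene_symbol: str
    comparison: str
    fraction: str
    mirna_fc: float
    protein_fc: float
    mrna_status: str = "absent"

    def __post_init__(self) -> None:
        ctx = f"hit {self.mirna_id}->{self.gene_symbol} {self.comparison}/{self.fraction}"
        if self.comparison not in COMPARISONS:
            raise FormatError(f"{ctx}: unknown comparison {self.comparison!r}")
        if self.fraction not in FRACTIONS:
            raise FormatError(f"{ctx}: unknown fraction {self.fraction!r}")
        if self.mrna_status not in MRNA_STATUSES:
            raise FormatError(f"{ctx}: unknown mrna_status {self.mrna_status!r}")
        if self.mirna_fc * self.protein_fc >= 0:
            raise FormatError(
                f"{ctx}: miRNA FC {self.mirna_fc} and protein FC "
                f"{self.protein_fc} are not strictly sign-opposed"
            )


@dataclass(frozen=True)
class MultiTargetSummary:
    """A miRNA associated with two or more distinct target proteins."""

    mirna_id: str
    n_distinct_proteins: int
    proteins: str  # comma-joined sorted gene symbols

    def __post_init__(self) -> None:
        if self.n_distinct_proteins < 2:
            raise FormatError(
                f"{self.mirna_id}: multi-target rows require >= 2 distinct "
                f"proteins, got {self.n_distinct_proteins}"
            )


@dataclass(frozen=True)
class PeptideEvidence:
    """One peptide supporting one protein identification."""

    protein_id: str
    peptide_sequence: str

    def __post_init__(self) -> None:
        pep = self.peptide_sequence
        if not pep:
            raise FormatError(f"protein {self.protein_id}: empty peptide")
        bad = set(pep) - set("ACDEFGHIKLMNPQRSTVWY")
        if bad:
            raise FormatError(
                f"protein {self.protein_id}: peptide {pep!r} contains "
                f"non-standard residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class OriginCall:
    """Species-of-origin call for one PDX protein identification."""

    protein_id: str
    category: str
    n_human_only: int
    n_mouse_only: int
    n_shared: int

    def __post_init__(self) -> None:
        if self.category not in ("human_not_murine", "murine_not_human", "ambiguous"):
            raise FormatError(
                f"protein {self.protein_id}: unknown category {self.category!r}"
            )
        if min(self.n_human_only, self.n_mouse_only, self.n_shared) < 0:
            raise FormatError(f"protein {self.protein_id}: negative peptide count")


class ExpressionMatrix:
    """Log2 signal intensities, features x samples, with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
    group_of
        Mapping from sample id to one of the groups ``N`` (adjacent
        normal), ``T`` (tumor), ``F1`` (first-passage xenograft).
    """

    def __init__(self, values: pd.DataFrame, group_of: dict[str, str]):
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        missing = [s for s in values.columns if s not in group_of]
        if missing:
            raise FormatError(f"samples missing from sample sheet: {missing}")
        for s, g in group_of.items():
            if g not in GROUPS:
                raise FormatError(
                    f"sample {s!r}: unknown group {g!r} (expected one of {GROUPS})"
                )
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(values.to_numpy(dtype=float, na_value=np.nan)))
            r, c = bad[0]
            raise FormatError(
                f"non-finite value at feature {values.index[r]!r}, "
                f"sample {values.columns[c]!r}"
            )
        self.values = values.astype(float)
        self.group_of = {s: group_of[s] for s in values.columns}

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.group_of.items() if g == group]

    @property
    def groups_present(self) -> list[str]:
        return [g for g in GROUPS if self.samples_in(g)]

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({len(self.feature_ids)} features x "
            f"{len(self.sample_ids)} samples, groups "
            f"{ {g: len(self.samples_in(g)) for g in self.groups_present} })"
        )


# ---------------------------------------------------------------------------
# readers


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kw)


def read_expression_matrix(path: str | Path, sample_sheet: str | Path) -> ExpressionMatrix:
    """Read a features-x-samples log2 TSV plus a sample sheet.

    The matrix file has a ``feature_id`` column followed by one column
    per sample; the sheet has columns ``sample_id`` and ``group``.
    Sample order is preserved from the matrix file.
    """
    df = _read_tsv(path)
    if df.columns[0] != "feature_id":
        raise FormatError(
            f"{path}: first column must be 'feature_id', got {df.columns[0]!r}"
        )
    feats = df["feature_id"]
    if feats.duplicated().any():
        raise FormatError(
            f"{path}: duplicate feature id {feats[feats.duplicated()].iloc[0]!r}"
        )
    body = df.set_index("feature_id")
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        raise FormatError(
            f"{path}: non-numeric value {body.iat[r, c]!r} at feature "
            f"{body.index[r]!r}, sample {body.columns[c]!r}"
        )

    sheet = _read_tsv(sample_sheet)
    for col in ("sample_id", "group"):
        if col not in sheet.columns:
            raise FormatError(f"{sample_sheet}: missing column {col!r}")
    if sheet["sample_id"].duplicated().any():
        raise FormatError(f"{sample_sheet}: duplicate sample_id")
    group_of = dict(zip(sheet["sample_id"], sheet["group"]))
    return ExpressionMatrix(numeric, group_of)


_TRUTHY = {"1": True, "true": True, "0": False, "false": False}


def _parse_bool(token: str, ctx: str) -> bool:
    try:
        return _TRUTHY[token.strip().lower()]
    except KeyError:
        raise FormatError(f"{ctx}: boolean column accepts 0/1/true/false, got {token!r}")


def _records_from_frame(df: pd.DataFrame, cls, path) -> list:
    cols = [f.name for f in fields(cls)]
    required = [c for c, f in zip(cols, fields(cls)) if f.default is dataclasses.MISSING]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out = []
    for i, row in df.iterrows():
        kwargs = {}
        for f in fields(cls):
            if f.name not in df.columns:
                continue
            tok = row[f.name]
            if f.type in ("float", float):
                try:
                    kwargs[f.name] = float(tok)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path} row {i}: column {f.name!r} is not numeric: {tok!r}"
                    )
            elif f.type in ("int", int):
                kwargs[f.name] = int(tok)
            elif f.type in ("bool", bool):
                kwargs[f.name] = _parse_bool(str(tok), f"{path} row {i}")
            else:
                kwargs[f.name] = "" if pd.isna(tok) else str(tok)
        out.append(cls(**kwargs))
    return out


def read_target_table(path: str | Path) -> list[TargetRecord]:
    """Read a target-prediction TSV into validated :class:`TargetRecord` s."""
    return _records_from_frame(_read_tsv(path), TargetRecord, path)


def read_protein_de_table(path: str | Path) -> list[ProteinDEEntry]:
    """Read a protein DE TSV; (gene, comparison, fraction) unique within the file."""
    recs = _records_from_frame(_read_tsv(path), ProteinDEEntry, path)
    seen: set[tuple] = set()
    for r in recs:
        key = (r.gene_symbol, r.comparison, r.fraction)
        if key in seen:
            raise FormatError(f"{path}: duplicate protein entry {key}")
        seen.add(key)
    return recs


def read_mrna_de_table(path: str | Path) -> list[MrnaDEEntry]:
    recs = _records_from_frame(_read_tsv(path), MrnaDEEntry, path)
    seen: set[tuple] = set()
    for r in recs:
        key = (r.gene_symbol, r.comparison)
        if key in seen:
            raise FormatError(f"{path}: duplicate mRNA entry {key}")
        seen.add(key)
    return recs


def read_hits(path: str | Path) -> list[AttributionHit]:
    return _records_from_frame(_read_tsv(path), AttributionHit, path)


def read_peptide_evidence(path: str | Path) -> list[PeptideEvidence]:
    return _records_from_frame(_read_tsv(path), PeptideEvidence, path)


def read_origin_calls(path: str | Path) -> list[OriginCall]:
    return _records_from_frame(_read_tsv(path), OriginCall, path)


# ---------------------------------------------------------------------------
# writer


def _format_cell(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)  # full precision so round-trips are exact
    return str(v)


def write_report(
    records: Sequence,
    path: str | Path,
    header_lines: Iterable[str] = (),
    cls=None,
) -> None:
    """Write records of one dataclass type as a deterministic TSV.

    Columns follow dataclass field order, rows are sorted by their
    stringified field tuple, so identical record lists always produce
    identical bytes. ``header_lines`` are emitted first, prefixed with
    ``#``. For an empty record list pass ``cls`` to still emit the
    header row.
    """
    path = Path(path)
    if records:
        cls = type(records[0])
    if cls is not None and not dataclasses.is_dataclass(cls):
        raise TypeError(f"write_report expects dataclass records, got {cls}")
    cols = [f.name for f in fields(cls)] if cls is not None else []
    rows = sorted(
        (tuple(getattr(r, c) for c in cols) for r in records),
        key=lambda t: tuple(str(x) for x in t),
    )
    lines = [f"# {h}" for h in header_lines]
    lines.append("\t".join(cols))
    lines.extend("\t".join(_format_cell(v) for v in row) for row in rows)
    path.write_text("\n".join(lines) + "\n")


def write_frame(df: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Deterministic TSV for a DataFrame (column order kept, rows pre-sorted)."""
    path = Path(path)
    lines = [f"# {h}" for h in header_lines]
    lines.append("\t".join(map(str, df.columns)))
    for row in df.itertuples(index=False):
        lines.append("\t".join(_format_cell(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
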