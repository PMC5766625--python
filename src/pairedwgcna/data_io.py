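"""Reading and writing expression matrices, paired design tables and GEO
series-matrix files.

Conventions
-----------
* Expression matrices are genes x samples.  On disk the default layout is
  genes in rows: first column = gene identifier, header row = sample
  identifiers.  Orientation is never auto-detected; the caller states it.
* Identifiers are case-sensitive and whitespace-trimmed.
* Values are parsed with a plain decimal point (locale independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ParseError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "PairedDesign",
    "read_expression",
    "write_expression",
    "read_design",
    "write_design",
    "read_geo_series_matrix",
    "drop_genes_with_missing",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of (log-scale) expression values.

    Parameters
    ----------
    gene_ids : list of str
        Unique gene (row) identifiers.
    sample_ids : list of str
        Unique sample (column) identifiers.
    values : ndarray, shape (n_genes, n_samples)
        Expression values.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g).strip() for g in self.gene_ids]
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        n_genes, n_samples = self.values.shape
        if n_genes != len(self.gene_ids) or n_samples != len(self.sample_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.sample_ids)} sample ids"
            )
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise ValidationError(f"duplicate gene ids: {sorted(dup_g)}")
        dup_s = _duplicates(self.sample_ids)
        if dup_s:
            raise ValidationError(f"duplicate sample ids: {sorted(dup_s)}")

    # -- basic container protocol ------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float))

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, cols])

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing}")
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[rows, :])

    def validate_for_network(self) -> None:
        """Check the minimal-size and finiteness invariants required before
        any network computation."""
        if self.n_samples < 3 or self.n_genes < 2:
            raise InsufficientDataError(
                f"need >=2 genes and >=3 samples, got {self.n_genes} x {self.n_samples}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite values present; apply the missing-value policy first")


@dataclass
class PairedDesign:
    """Per-sample pairing and condition information for a paired design.

    Every pair id must occur exactly twice, once with condition 0 (control)
    and once with condition 1 (case).  Covariates are subject-level and must
    be identical within a pair.
    """

    sample_ids: list[str]
    pair_ids: list[str]
    conditions: np.ndarray  # int array of 0/1
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)  # indexed by sample_id

    def __post_init__(self) -> None:
        self.sample_ids = [str(s).strip() for s in self.sample_ids]
        self.pair_ids = [str(p).strip() for p in self.pair_ids]
        self.conditions = np.asarray(self.conditions, dtype=int)
        if not (len(self.sample_ids) == len(self.pair_ids) == len(self.conditions)):
            raise ValidationError("sample_ids, pair_ids and conditions must have equal length")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValidationError(f"duplicate sample ids in design: {sorted(dup)}")
        if not np.isin(self.conditions, [0, 1]).all():
            raise ValidationError("conditions must be coded 0 (control) / 1 (case)")
        if self.covariates.empty:
            self.covariates = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        else:
            self.covariates = self.covariates.reindex(self.sample_ids)
        self._validate_pairs()

    def _validate_pairs(self) -> None:
        df = self.to_frame()
        bad: list[str] = []
        for pid, grp in df.groupby("pair_id", sort=False):
            if len(grp) != 2 or sorted(grp["condition"]) != [0, 1]:
                bad.append(str(pid))
        if bad:
            raise ValidationError(
                f"pairs must have exactly one control and one case sample; offending pair_ids: {bad}"
            )
        for col in self.covariates.columns:
            per_pair = self.covariates[col].groupby(df["pair_id"]).nunique(dropna=False)
            bad_cov = per_pair[per_pair > 1].index.tolist()
            if bad_cov:
                raise ValidationError(
                    f"covariate {col!r} differs within pairs {bad_cov}; covariates are subject-level"
                )

    @property
    def n_pairs(self) -> int:
        return len(set(self.pair_ids))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"pair_id": self.pair_ids, "condition": self.conditions},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )
        return pd.concat([df, self.covariates], axis=1)

    def subset(self, sample_ids: list[str]) -> "PairedDesign":
        keep = set(sample_ids)
        mask = [s in keep for s in self.sample_ids]
        return PairedDesign(
            [s for s, m in zip(self.sample_ids, mask) if m],
            [p for p, m in zip(self.pair_ids, mask) if m],
            self.conditions[np.asarray(mask, bool)],
            self.covariates.loc[mask].copy(),
        )

    def check_against(self, expr: ExpressionMatrix) -> None:
        """Cross-check: every design sample must exist in the matrix."""
        missing = sorted(set(self.sample_ids) - set(expr.sample_ids))
        if missing:
            raise ValidationError(f"design samples absent from expression matrix: {missing}")


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if first.count(",") > first.count("\t") else "\t"


def read_expression(path: str, orientation: str = "genes-in-rows") -> ExpressionMatrix:
    """Read a delimited expression matrix.

    ``orientation`` must be ``"genes-in-rows"`` (default) or
    ``"samples-in-rows"``; it is never guessed from the file.
    """
    if orientation not in ("genes-in-rows", "samples-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path)
    # manual parse so ragged rows can be reported with a line number
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = [c.strip() for c in lines[0].split(sep)]
    ncol = len(header)
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split(sep)
        if len(cells) != ncol:
            raise ParseError(
                f"{path}: line {lineno}: expected {ncol} fields, found {len(cells)}"
            )
        row_ids.append(cells[0].strip())
        try:
            rows.append([float(c) if c.strip() not in ("", "NA", "NaN", "nan") else np.nan
                         for c in cells[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
    col_ids = header[1:]
    values = np.asarray(rows, dtype=float)
    if orientation == "genes-in-rows":
        return ExpressionMatrix(row_ids, col_ids, values)
    return ExpressionMatrix(col_ids, row_ids, values.T)


def write_expression(expr: ExpressionMatrix, path: str, sep: str = "\t") -> None:
    """Write genes-in-rows with full double precision (round-trip safe)."""
    df = expr.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_design(path: str) -> PairedDesign:
    """Read a design table with required columns sample_id, pair_id,
    condition; any further columns are treated as subject-level covariates."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "pair_id": str})
    required = {"sample_id", "pair_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    cov_cols = [c for c in df.columns if c not in required]
    covariates = df[cov_cols].copy()
    covariates.index = pd.Index(df["sample_id"].str.strip(), name="sample_id")
    return PairedDesign(
        list(df["sample_id"]),
        list(df["pair_id"]),
        df["condition"].to_numpy(),
        covariates,
    )


def write_design(design: PairedDesign, path: str, sep: str = "\t") -> None:
    df = design.to_frame().reset_index()
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_geo_series_matrix(path: str) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Parse a GEO series-matrix text file.

    Returns the embedded expression table (probes x samples) and a mapping
    of the ``!``-prefixed metadata keys to their (dequoted) values.
    """
    metadata: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln:
                continue
            if ln.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if ln.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                table_lines.append(ln)
            elif ln.startswith("!"):
                key, _, rest = ln.partition("\t")
                vals = [_dequote(v) for v in rest.split("\t")] if rest else []
                metadata.setdefault(key.lstrip("!"), []).extend(vals)
    if not (saw_begin and saw_end):
        raise FormatError(
            f"{path}: missing !series_matrix_table_begin/!series_matrix_table_end delimiters"
        )
    if not table_lines:
        raise FormatError(f"{path}: empty series-matrix table")
    header = [_dequote(c) for c in table_lines[0].split("\t")]
    sample_ids = header[1:]
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for ln in table_lines[1:]:
        cells = ln.split("\t")
        gene_ids.append(_dequote(cells[0]))
        rows.append([float(c) if c.strip() not in ("", "null", "NA", "NaN") else np.nan
                     for c in cells[1:]])
    expr = ExpressionMatrix(gene_ids, sample_ids, np.asarray(rows, dtype=float))
    return expr, metadata


def _dequote(s: str) -> str:
    s = s.strip()
    if len(s) >= 2 and s[0] == '"' and s[-1] == '"':
        s = s[1:-1]
    return s.strip()


def drop_genes_with_missing(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Default missing-value policy: drop any gene with a non-finite value.

    Keeps all downstream matrices dense and deterministic (pairwise-complete
    correlation is deliberately not offered).
    """
    keep = np.all(np.isfinite(expr.values), axis=1)
    return ExpressionMatrix(
        [g for g, k in zip(expr.gene_ids, keep) if k],
        list(expr.sample_ids),
        expr.values[keep, :],
    )
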