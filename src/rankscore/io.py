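"""Expression-matrix and gene-signature I/O plus the low-abundance filter.

Expression tables are tab-separated text with gene identifiers in the first
column and one header row of sample identifiers.  Signatures use the GMT
format (``name<TAB>description<TAB>gene1<TAB>gene2...``); paired lines whose
names share a stem and end in ``_UP``/``_DN`` (case-insensitive, configurable)
are merged into a single bidirectional signature.

Gene identifiers are opaque, case-sensitive strings; no symbol/ID mapping is
attempted.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "filter_low_abundance",
]

SignatureMode = Literal["up", "down", "bidirectional", "undirected"]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples abundance table (RPKM/TPM/RSEM scale, or log thereof).

    Parameters
    ----------
    data:
        Numeric :class:`pandas.DataFrame` with unique gene identifiers as the
        index and unique sample identifiers as the columns.
    log_transformed:
        Whether values are on a log scale.  Rank-based scoring is invariant
        to any strictly monotone within-sample transform, so this flag is
        informational.
    """

    data: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dupes[:5]}")
        if self.data.size and not all(
            np.issubdtype(dt, np.number) for dt in self.data.dtypes
        ):
            bad = [c for c, dt in self.data.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise ValidationError(f"non-numeric columns: {bad[:5]}")
        if self.data.size and self.data.isna().any().any():
            rows = self.data.index[self.data.isna().any(axis=1)].tolist()
            raise ValidationError(f"missing values in rows: {rows[:5]}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset(
        self,
        samples: Sequence[str] | None = None,
        genes: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given samples and/or genes."""
        data = self.data
        if genes is not None:
            missing = set(genes) - set(data.index)
            if missing:
                raise KeyError(f"unknown genes: {sorted(missing)[:5]}")
            data = data.loc[list(genes)]
        if samples is not None:
            missing = set(samples) - set(data.columns)
            if missing:
                raise KeyError(f"unknown samples: {sorted(missing)[:5]}")
            data = data[list(samples)]
        return ExpressionMatrix(data, log_transformed=self.log_transformed)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set with a direction mode.

    ``up_genes`` is empty iff ``mode == "down"``; ``down_genes`` is non-empty
    iff ``mode`` is ``"down"`` or ``"bidirectional"``.  Undirected sets live
    in ``up_genes``.
    """

    name: str
    mode: SignatureMode
    up_genes: frozenset[str] = field(default_factory=frozenset)
    down_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_genes", frozenset(self.up_genes))
        object.__setattr__(self, "down_genes", frozenset(self.down_genes))
        if self.mode not in ("up", "down", "bidirectional", "undirected"):
            raise ValidationError(f"unknown signature mode: {self.mode!r}")
        if self.mode in ("up", "undirected"):
            if not self.up_genes or self.down_genes:
                raise ValidationError(
                    f"signature {self.name!r} (mode={self.mode}) must have genes in "
                    "up_genes only"
                )
        elif self.mode == "down":
            if not self.down_genes or self.up_genes:
                raise ValidationError(
                    f"signature {self.name!r} (mode=down) must have genes in "
                    "down_genes only"
                )
        else:  # bidirectional
            if not self.up_genes or not self.down_genes:
                raise ValidationError(
                    f"bidirectional signature {self.name!r} needs both up and down genes"
                )
            overlap = self.up_genes & self.down_genes
            if overlap:
                raise ValidationError(
                    f"signature {self.name!r}: up/down sets overlap: {sorted(overlap)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def read_expression(path: str | Path, log_transformed: bool = False) -> ExpressionMatrix:
    """Read a TSV expression table (genes in rows, samples in columns)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty expression file") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else df.index[df[col].isna()][0]
            raise ParseError(
                f"{path}: non-numeric value at gene {row!r}, sample {col!r}"
            )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, log_transformed=log_transformed)


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    """Write an expression matrix as TSV; inverse of :func:`read_expression`."""
    df = em.data.copy()
    df.index.name = df.index.name or "gene_id"
    df.to_csv(path, sep="\t")


def _strip_suffix(name: str, suffixes: Sequence[str]) -> tuple[str, str | None]:
    lower = name.lower()
    for suf in suffixes:
        if lower.endswith(suf.lower()) and len(name) > len(suf):
            return name[: -len(suf)], suf
    return name, None


def read_gmt(
    path: str | Path,
    pair_suffixes: tuple[str, str] = ("_UP", "_DN"),
    default_mode: SignatureMode = "up",
) -> list[GeneSignature]:
    """Read signatures from a GMT file, merging ``_UP``/``_DN`` pairs.

    Lines whose names share a stem and carry the two pairing suffixes
    (case-insensitive) are merged into one bidirectional signature named by
    the stem.  An unmatched ``_UP`` (or ``_DN``) line is kept unidirectional
    with a warning.  Other lines get ``default_mode``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"GMT file not found: {path}")
    up_suf, dn_suf = pair_suffixes
    raw: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, genes = fields[0], [g for g in fields[2:] if g.strip()]
            if not genes:
                raise ParseError(f"{path}:{lineno}: signature {name!r} has no genes")
            raw.append((name, genes))

    by_stem: dict[str, dict[str, list[str]]] = {}
    order: list[str] = []
    for name, genes in raw:
        stem, suf = _strip_suffix(name, (up_suf, dn_suf))
        key = stem if suf else name
        slot = "up" if (suf and suf.lower() == up_suf.lower()) else (
            "down" if suf else "plain"
        )
        entry = by_stem.setdefault(key, {})
        if key not in order:
            order.append(key)
        entry[slot] = genes

    sigs: list[GeneSignature] = []
    for key in order:
        entry = by_stem[key]
        if "up" in entry and "down" in entry:
            sigs.append(
                GeneSignature(key, "bidirectional", frozenset(entry["up"]),
                              frozenset(entry["down"]))
            )
        elif "up" in entry:
            warnings.warn(
                f"signature {key!r}: '{up_suf}' set without matching '{dn_suf}'; "
                "kept as unidirectional up", stacklevel=2,
            )
            sigs.append(GeneSignature(key, "up", frozenset(entry["up"])))
        elif "down" in entry:
            warnings.warn(
                f"signature {key!r}: '{dn_suf}' set without matching '{up_suf}'; "
                "kept as unidirectional down", stacklevel=2,
            )
            sigs.append(GeneSignature(key, "down", down_genes=frozenset(entry["down"])))
        else:
            genes = frozenset(entry["plain"])
            if default_mode == "down":
                sigs.append(GeneSignature(key, "down", down_genes=genes))
            else:
                sigs.append(GeneSignature(key, default_mode, genes))
    return sigs


def write_gmt(sigs: Iterable[GeneSignature], path: str | Path,
              pair_suffixes: tuple[str, str] = ("_UP", "_DN")) -> None:
    """Write signatures as GMT, splitting bidirectional ones into suffix pairs."""
    up_suf, dn_suf = pair_suffixes
    with open(path, "w") as fh:
        for sig in sigs:
            if sig.mode == "bidirectional":
                fh.write("\t".join([sig.name + up_suf, "na", *sorted(sig.up_genes)]) + "\n")
                fh.write("\t".join([sig.name + dn_suf, "na", *sorted(sig.down_genes)]) + "\n")
            elif sig.mode == "down":
                fh.write("\t".join([sig.name, "na", *sorted(sig.down_genes)]) + "\n")
            else:
                fh.write("\t".join([sig.name, "na", *sorted(sig.up_genes)]) + "\n")


def filter_low_abundance(
    em: ExpressionMatrix, threshold: float = 2.0, min_fraction: float = 0.9
) -> ExpressionMatrix:
    """Keep genes whose abundance exceeds ``threshold`` in more than
    ``min_fraction`` of samples.

    Both comparisons are strict: a gene is retained iff
    ``mean(value > threshold) > min_fraction``.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    if not 0 < min_fraction <= 1:
        raise ValidationError("min_fraction must be in (0, 1]")
    frac = (em.data > threshold).mean(axis=1)
    keep = frac > min_fraction
    if not keep.any():
        raise ValidationError(
            f"no genes exceed abundance {threshold} in more than "
            f"{min_fraction:.0%} of samples; lower the threshold or fraction"
        )
    return ExpressionMatrix(em.data.loc[keep], log_transformed=em.log_transformed)
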