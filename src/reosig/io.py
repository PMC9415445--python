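"""Reading, writing and probe-level preprocessing of expression data.

Expression matrices are plain dense TSV files: first column ``feature_id``
(probe or gene identifiers), header row of sample identifiers, numeric body
of positive processed intensities.  Within-sample orderings of these values
are the only thing downstream analysis consumes, so no between-sample
normalisation is ever applied here.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FEATURE_COL = "feature_id"

__all__ = [
    "FEATURE_COL",
    "SampleAnnotation",
    "read_expression_matrix",
    "write_expression_matrix",
    "validate_expression_matrix",
    "read_probe_map",
    "collapse_probes",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "read_ortholog_map",
]


@dataclass
class SampleAnnotation:
    """Per-sample phenotype/stage labels for one or more cohorts."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"sample_id", "phenotype"}
        missing = required - set(self.table.columns)
        if len(self.table) and missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if len(self.table) and self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id in annotation: {dup!r}")

    def phenotype_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["phenotype"].iloc[0])

    def samples_with(self, phenotype: str) -> list[str]:
        return self.table.loc[self.table["phenotype"] == phenotype, "sample_id"].tolist()


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def validate_expression_matrix(matrix: pd.DataFrame, *, allow_zero: bool = False) -> pd.DataFrame:
    """Check the invariants every expression matrix must satisfy.

    Raises ``ValueError`` on duplicate identifiers, non-finite values, or
    non-positive values (zeros allowed only when ``allow_zero``).
    """
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicate feature id: {dup!r}")
    if matrix.columns.has_duplicates:
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(~matrix.map(lambda v: isinstance(v, (int, float, np.number))).to_numpy())
        r, c = bad[0] if len(bad) else (0, 0)
        raise ValueError(
            f"non-numeric value at feature {matrix.index[r]!r}, sample {matrix.columns[c]!r}"
        )
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite value at feature {matrix.index[r]!r}, sample {matrix.columns[c]!r}"
        )
    floor = 0.0
    bad_mask = values < floor if allow_zero else values <= floor
    if bad_mask.any():
        r, c = np.argwhere(bad_mask)[0]
        raise ValueError(
            f"non-positive value {values[r, c]} at feature {matrix.index[r]!r}, "
            f"sample {matrix.columns[c]!r}; intensities must be positive"
        )
    return matrix


def read_expression_matrix(path: str | Path, *, pseudo_floor: float | None = None) -> pd.DataFrame:
    """Load a features x samples TSV into a DataFrame (features as index).

    ``pseudo_floor``, if given, is added to every value before validation so
    that matrices containing zeros can be rescued; by default zeros are
    rejected because relative orderings need strictly positive intensities.
    """
    with _open_maybe_gzip(path) as handle:
        matrix = pd.read_csv(
            handle, sep="\t", index_col=0, comment="#", float_precision="round_trip"
        )
    matrix.index = matrix.index.astype(str)
    matrix.index.name = FEATURE_COL
    matrix.columns = matrix.columns.astype(str)
    try:
        matrix = matrix.astype(float)
    except (TypeError, ValueError):
        for j, col in enumerate(matrix.columns):
            coerced = pd.to_numeric(matrix[col], errors="coerce")
            bad = coerced.isna() & matrix[col].notna()
            if bad.any():
                feat = matrix.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric cell at feature {feat!r}, sample {col!r} in {path}"
                ) from None
        matrix = matrix.apply(pd.to_numeric)
    if matrix.isna().to_numpy().any():
        r, c = np.argwhere(matrix.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at feature {matrix.index[r]!r}, sample {matrix.columns[c]!r}"
        )
    if pseudo_floor is not None:
        matrix = matrix + float(pseudo_floor)
    return validate_expression_matrix(matrix)


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix in the same TSV layout ``read_expression_matrix`` reads.

    Full ``repr`` float precision is used so write/read round-trips are
    bitwise lossless.
    """
    out = matrix.copy()
    out.index.name = FEATURE_COL
    with _open_maybe_gzip(path, "wt") as handle:
        out.to_csv(handle, sep="\t", float_format="%.17g")


def read_probe_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column probe->gene TSV into probe -> set of genes.

    A probe listed on several rows has its gene assignments unioned; the
    zero/multi-gene discard rule is applied later on this final mapping.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if table.shape[1] < 2:
        raise ValueError("probe map needs two columns: probe_id, gene_id")
    probe_col, gene_col = table.columns[:2]
    mapping: dict[str, set[str]] = {}
    for probe, gene in zip(table[probe_col], table[gene_col]):
        genes = mapping.setdefault(str(probe), set())
        if isinstance(gene, str) and gene and gene.lower() not in ("nan", "na", ""):
            genes.add(gene)
    return mapping


def collapse_probes(probes: pd.DataFrame, probe_map: dict[str, set[str]]) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level.

    Probes mapping to exactly one gene contribute; a gene measured by several
    probes gets the arithmetic mean of their values per sample.  Probes
    mapping to no gene or to more than one gene are discarded entirely.
    """
    missing = [p for p in probes.index if p not in probe_map]
    if missing:
        raise ValueError(f"{len(missing)} probes absent from map, first: {missing[0]!r}")
    gene_of = {
        probe: next(iter(genes))
        for probe, genes in probe_map.items()
        if len(genes) == 1 and probe in probes.index
    }
    kept = probes.loc[[p for p in probes.index if p in gene_of]]
    if kept.empty:
        raise ValueError("no uniquely-mapped probe; collapsed matrix would be empty")
    genes = pd.Index([gene_of[p] for p in kept.index], name=FEATURE_COL)
    collapsed = kept.groupby(genes, sort=True).mean()
    return validate_expression_matrix(collapsed)


def read_annotation(path: str | Path) -> SampleAnnotation:
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return SampleAnnotation(table)


def write_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with _open_maybe_gzip(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, desc, >=1 gene): {line[:60]!r}")
            name, _desc, *genes = parts
            sets[name] = {g for g in genes if g}
    return sets


def read_ortholog_map(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV source_gene -> target_gene; repeated sources allowed."""
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    src_col, tgt_col = table.columns[:2]
    mapping: dict[str, list[str]] = {}
    for src, tgt in zip(table[src_col], table[tgt_col]):
        targets = mapping.setdefault(str(src), [])
        if isinstance(tgt, str) and tgt and tgt not in targets:
            targets.append(tgt)
    return mapping
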