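"""Core data structures, TSV/GMT readers and writers, validation, and the
preprocessing filters applied before any statistics.

Conventions
-----------
- All matrices are tab-delimited UTF-8 text with a header row and the gene
  identifier in the first column.
- Missing protein intensities are encoded as empty cells; count matrices may
  not contain missing values.
- Time points are numeric hours so that lag arithmetic is well defined.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

MODALITY_TRANSCRIPT = "transcript"
MODALITY_PROTEIN = "protein"

VALUE_KINDS = ("raw_count", "log_intensity", "fraction", "logFC", "ratio")

SAMPLE_COLUMNS = ("sample_id", "modality", "time_h", "replicate", "plate")


class ValidationError(ValueError):
    """Raised when an input file or in-memory structure violates a contract."""


# ---------------------------------------------------------------------------
# Sample table
# ---------------------------------------------------------------------------

def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample table and return it with normalized dtypes.

    Required columns: sample_id, modality, time_h, replicate, plate.
    The plate column may contain empty values for unpaired samples, but a
    plate key may be shared by at most one sample per modality.
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample table missing columns: {missing}")
    out = samples.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    out["modality"] = out["modality"].astype(str)
    out["time_h"] = out["time_h"].astype(float)
    out["replicate"] = out["replicate"].astype(str)
    bad = ~out["modality"].isin([MODALITY_TRANSCRIPT, MODALITY_PROTEIN])
    if bad.any():
        raise ValidationError(
            f"unknown modality values: {sorted(out.loc[bad, 'modality'].unique())}"
        )
    if out["sample_id"].duplicated().any():
        dups = out.loc[out["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample_id: {dups}")
    key = out[["modality", "time_h", "replicate"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise ValidationError("(modality, time_h, replicate) must be unique")
    plated = out[out["plate"].notna() & (out["plate"].astype(str) != "")]
    pk = plated[["modality", "plate"]].apply(tuple, axis=1)
    if pk.duplicated().any():
        raise ValidationError("a plate key is shared by >1 sample of one modality")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """A gene x sample matrix with an explicit value kind.

    ``values`` is a DataFrame indexed by gene_id with sample_id columns.
    Missing entries are NaN; for ``raw_count`` matrices NaN is forbidden and
    values must be non-negative integers.
    """

    values: pd.DataFrame
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene_ids: {dups[:5]}")
        vals = self.values.to_numpy(dtype=float)
        if self.value_kind == "raw_count":
            if np.isnan(vals).any():
                raise ValidationError("raw_count matrix may not contain missing values")
            if (vals < 0).any():
                raise ValidationError("raw_count matrix contains negative values")
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("raw_count matrix contains non-integer values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[genes], self.value_kind)

    def equals(self, other: "ExpressionMatrix") -> bool:
        if self.value_kind != other.value_kind:
            return False
        if list(self.values.index) != list(other.values.index):
            return False
        if list(self.values.columns) != list(other.values.columns):
            return False
        a = self.values.to_numpy(dtype=float)
        b = other.values.to_numpy(dtype=float)
        return bool(np.all((np.isnan(a) & np.isnan(b)) | np.isclose(a, b, equal_nan=False)))


def validate_matrix_against_samples(
    matrix: ExpressionMatrix, samples: pd.DataFrame, modality: str
) -> None:
    """Check the matrix columns against the sample table for a modality."""
    expected = samples.loc[samples["modality"] == modality, "sample_id"].tolist()
    got = matrix.sample_ids
    if set(got) - set(expected):
        extra = sorted(set(got) - set(expected))
        raise ValidationError(
            f"{modality} matrix has samples absent from the sample table: {extra}"
        )
    if set(expected) - set(got):
        miss = sorted(set(expected) - set(got))
        raise ValidationError(f"{modality} matrix is missing samples: {miss}")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Per-gene annotation: coding flag and transcript->protein mapping.

    ``table`` is indexed by gene_id with columns ``is_protein_coding`` (bool)
    and ``protein_group`` (str; empty for non-coding transcripts).
    GO memberships live in separate GMT files (see :func:`read_gene_sets`).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("is_protein_coding", "protein_group"):
            if col not in self.table.columns:
                raise ValidationError(f"gene annotation missing column {col!r}")
        coding = self.table[self.table["is_protein_coding"].astype(bool)]
        empty = coding["protein_group"].isna() | (coding["protein_group"].astype(str) == "")
        if empty.any():
            raise ValidationError("protein-coding genes must have a protein_group")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class PairedOmicsDataset:
    """The full paired dataset: counts, intensities, samples, annotation."""

    counts: ExpressionMatrix
    intensities: ExpressionMatrix
    samples: pd.DataFrame
    genes: GeneAnnotation
    truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.samples = validate_samples(self.samples)
        validate_matrix_against_samples(self.counts, self.samples, MODALITY_TRANSCRIPT)
        validate_matrix_against_samples(self.intensities, self.samples, MODALITY_PROTEIN)

    @property
    def rna_samples(self) -> pd.DataFrame:
        return self.samples[self.samples["modality"] == MODALITY_TRANSCRIPT]

    @property
    def protein_samples(self) -> pd.DataFrame:
        return self.samples[self.samples["modality"] == MODALITY_PROTEIN]

    def plate_pairs(self) -> pd.DataFrame:
        """Return (plate, rna_sample, protein_sample, time_h) for paired plates."""
        s = self.samples
        plated = s[s["plate"].notna() & (s["plate"].astype(str) != "")]
        rna = plated[plated["modality"] == MODALITY_TRANSCRIPT]
        prot = plated[plated["modality"] == MODALITY_PROTEIN]
        merged = rna.merge(prot, on="plate", suffixes=("_rna", "_prot"))
        return merged[["plate", "sample_id_rna", "sample_id_prot", "time_h_rna"]].rename(
            columns={"time_h_rna": "time_h"}
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_tsv_matrix(path: str, value_kind: str) -> ExpressionMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"{path}: cannot parse TSV ({exc})") from exc
    df.index = df.index.astype(str)
    num = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        blank = raw.isna() | (raw.astype(str).str.strip() == "")
        converted = pd.to_numeric(raw.where(~blank), errors="coerce")
        bad = converted.isna() & ~blank
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
        num[col] = converted
    try:
        return ExpressionMatrix(num, value_kind)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_matrix(matrix: ExpressionMatrix, path: str) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep="")


def read_samples(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "replicate": str, "plate": str})
    try:
        return validate_samples(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_samples(samples: pd.DataFrame, path: str) -> None:
    samples.to_csv(path, sep="\t", index=False, na_rep="")


def read_genes(path: str) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df["is_protein_coding"] = df["is_protein_coding"].map(
        {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
    )
    if df["is_protein_coding"].isna().any():
        raise ValidationError(f"{path}: is_protein_coding must be boolean")
    try:
        return GeneAnnotation(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_genes(genes: GeneAnnotation, path: str) -> None:
    out = genes.table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep="")


DATASET_FILES = {
    "counts": "counts.tsv",
    "intensities": "intensities.tsv",
    "samples": "samples.tsv",
    "genes": "genes.tsv",
    "truth": "truth.tsv",
}


def read_dataset(directory: str) -> PairedOmicsDataset:
    """Read the standard dataset bundle from a directory.

    Expects counts.tsv, intensities.tsv, samples.tsv, genes.tsv and an
    optional truth.tsv. Raises :class:`ValidationError` naming the offending
    file on any contract violation.
    """
    paths = {k: os.path.join(directory, v) for k, v in DATASET_FILES.items()}
    for key in ("counts", "intensities", "samples", "genes"):
        if not os.path.exists(paths[key]):
            raise ValidationError(f"missing required file: {paths[key]}")
    counts = _read_tsv_matrix(paths["counts"], "raw_count")
    intensities = _read_tsv_matrix(paths["intensities"], "log_intensity")
    samples = read_samples(paths["samples"])
    genes = read_genes(paths["genes"])
    truth = None
    if os.path.exists(paths["truth"]):
        truth = pd.read_csv(paths["truth"], sep="\t", index_col=0)
        truth.index = truth.index.astype(str)
    return PairedOmicsDataset(counts, intensities, samples, genes, truth)


def write_dataset(dataset: PairedOmicsDataset, directory: str) -> None:
    """Write the standard bundle; write->read round-trips losslessly."""
    os.makedirs(directory, exist_ok=True)
    paths = {k: os.path.join(directory, v) for k, v in DATASET_FILES.items()}
    write_matrix(dataset.counts, paths["counts"])
    write_matrix(dataset.intensities, paths["intensities"])
    write_samples(dataset.samples, paths["samples"])
    write_genes(dataset.genes, paths["genes"])
    if dataset.truth is not None:
        out = dataset.truth.copy()
        out.index.name = "gene_id"
        out.to_csv(paths["truth"], sep="\t")


def read_gene_sets(path: str) -> dict[str, set[str]]:
    """Parse a GMT file into a term -> gene-set mapping.

    GMT lines are ``term<TAB>description<TAB>gene1<TAB>gene2...``; duplicate
    genes within a line are deduplicated and empty lines skipped.
    """
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}: GMT line needs >=3 tab-separated fields: {line[:50]!r}"
                )
            term = parts[0]
            genes = {g for g in parts[2:] if g}
            if not genes:
                raise ValidationError(f"{path}: term {term!r} has an empty gene set")
            sets[term] = genes
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term, genes in sets.items():
            fh.write("\t".join([term, term] + sorted(set(genes))) + "\n")


# ---------------------------------------------------------------------------
# Preprocessing filters
# ---------------------------------------------------------------------------

def collapse_to_protein_coding(
    counts: ExpressionMatrix, annot: GeneAnnotation
) -> ExpressionMatrix:
    """Sum counts of transcripts that encode the same protein and drop
    transcripts that do not encode a protein.

    Output rows are protein_group keys, in order of first appearance among
    the input transcripts.
    """
    table = annot.table.reindex(counts.gene_ids)
    if table["is_protein_coding"].isna().any():
        miss = table.index[table["is_protein_coding"].isna()].tolist()
        raise ValidationError(f"transcripts absent from annotation: {miss[:5]}")
    coding = table["is_protein_coding"].astype(bool)
    sub = counts.values.loc[coding[coding].index]
    groups = table.loc[coding[coding].index, "protein_group"].astype(str)
    order = groups.drop_duplicates().tolist()
    collapsed = sub.groupby(groups, sort=False).sum().reindex(order)
    collapsed.index.name = counts.values.index.name
    return ExpressionMatrix(collapsed, "raw_count")


def filter_expressed(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Keep genes with more than one read in at least one sample."""
    keep = counts.values.max(axis=1) > 1
    return ExpressionMatrix(counts.values.loc[keep], counts.value_kind)


def select_quantified_proteins(
    intensities: ExpressionMatrix, samples: pd.DataFrame
) -> tuple[set[str], set[str], set[str]]:
    """Partition proteins by quantification completeness.

    Returns ``(directly_quantified, imputable, unquantified)``:

    - directly_quantified: observed in every sample;
    - imputable: complete in all replicates of at least one time point but
      missing elsewhere;
    - unquantified: everything else (never complete at any time point).
    """
    samples = validate_samples(samples)
    prot = samples[samples["modality"] == MODALITY_PROTEIN]
    observed = ~intensities.values[prot["sample_id"].tolist()].isna()
    complete_any_tp = pd.Series(False, index=observed.index)
    for _, grp in prot.groupby("time_h"):
        cols = grp["sample_id"].tolist()
        complete_any_tp |= observed[cols].all(axis=1)
    complete_everywhere = observed.all(axis=1)
    direct = set(observed.index[complete_everywhere])
    imputable = set(observed.index[complete_any_tp & ~complete_everywhere])
    unquantified = set(observed.index) - direct - imputable
    return direct, imputable, unquantified
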