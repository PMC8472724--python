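"""Domain types and TSV readers/writers for spectral-count data.

The pipeline's spine is the :class:`SpectralCountMatrix` — an integer
proteins x runs table with per-run cohort metadata — assembled from
per-run protein identification lists (:class:`RunList`). All file
interfaces are plain UTF-8 TSV with a mandatory header; column names can
be remapped through a ``dialect`` mapping so exports from other tools can
be ingested without rewriting them.

Conventions
-----------
* A protein absent from a run's list has spectral count 0 in the matrix.
* Protein identity is the accession string; collapsing rows by gene is
  opt-in via :func:`map_accessions`.
* Cohort labels are restricted to ``Wt``, ``He`` and ``Ho``.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

logger = logging.getLogger(__name__)

COHORTS: tuple[str, ...] = ("Wt", "He", "Ho")
REPLICATE_KINDS: tuple[str, ...] = ("technical", "biological")

#: Priority used to resolve multi-valued subcellular annotations to one label.
LOCATION_PRIORITY: tuple[str, ...] = (
    "cellular",
    "organelle",
    "macromolecular complex",
    "membrane",
)
LOCATIONS: tuple[str, ...] = LOCATION_PRIORITY + ("unknown",)

RUN_LIST_COLUMNS = ("accession", "gene", "description", "spc", "mw_kda", "pi", "location")
PSM_COLUMNS = (
    "peptide",
    "charge",
    "xcorr",
    "probability",
    "consensus_score",
    "is_decoy",
    "accession",
)


def resolve_location(raw: str | None) -> str:
    """Resolve a possibly multi-valued location cell to a single label.

    Multiple labels may be separated by ``;`` or ``|``; the highest-priority
    recognised label wins. Unrecognised or empty input maps to ``unknown``.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "unknown"
    labels = {part.strip().lower() for part in str(raw).replace("|", ";").split(";")}
    for candidate in LOCATION_PRIORITY:
        if candidate in labels:
            return candidate
    return "unknown"


@dataclass(frozen=True)
class ProteinRecord:
    """Static annotation of one protein: identity, physico-chemical props, location."""

    accession: str
    gene: str = ""
    description: str = ""
    mw_kda: float = float("nan")
    pi: float = float("nan")
    location: str = "unknown"

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("accession must be non-empty")
        if not np.isnan(self.mw_kda) and self.mw_kda < 0:
            raise ValidationError(f"{self.accession}: mw_kda must be >= 0, got {self.mw_kda}")
        if not np.isnan(self.pi) and not (0.0 <= self.pi <= 14.0):
            raise ValidationError(f"{self.accession}: pi must be in [0, 14], got {self.pi}")


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match with its search-engine scores."""

    peptide: str
    charge: int
    xcorr: float
    probability: float
    consensus_score: float
    is_decoy: bool
    accession: str = ""

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValidationError(f"charge must be >= 1, got {self.charge}")
        if not (0.0 < self.probability <= 1.0):
            raise ValidationError(f"probability must be in (0, 1], got {self.probability}")
        if self.xcorr < 0:
            raise ValidationError(f"xcorr must be >= 0, got {self.xcorr}")


@dataclass
class RunList:
    """One run's identification list: accession -> spectral count (>= 1).

    ``meta`` optionally carries per-accession :class:`ProteinRecord` parsed
    from the same file; absence of an accession encodes SpC = 0.
    """

    run_id: str
    subject_id: str
    cohort: str
    replicate_kind: str = "technical"
    entries: dict[str, int] = field(default_factory=dict)
    meta: dict[str, ProteinRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"run {self.run_id!r}: cohort must be one of {COHORTS}, got {self.cohort!r}"
            )
        if self.replicate_kind not in REPLICATE_KINDS:
            raise ValidationError(
                f"run {self.run_id!r}: replicate_kind must be one of {REPLICATE_KINDS}"
            )
        for accession, spc in self.entries.items():
            if spc < 1:
                raise ValidationError(
                    f"run {self.run_id!r}: SpC must be >= 1 for listed entries, "
                    f"got {spc} for {accession!r}"
                )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class RunInfo:
    """Column metadata of a :class:`SpectralCountMatrix`."""

    run_id: str
    subject_id: str
    cohort: str
    replicate_kind: str = "technical"


class SpectralCountMatrix:
    """Integer proteins x runs spectral-count table with cohort labels.

    Parameters
    ----------
    counts
        DataFrame indexed by protein identifier with one column per run,
        non-negative integers.
    runs
        Per-column metadata in column order.
    """

    def __init__(self, counts: pd.DataFrame, runs: Sequence[RunInfo]):
        counts = counts.copy()
        run_ids = [r.run_id for r in runs]
        if list(counts.columns) != run_ids:
            raise ValidationError("counts columns must match run metadata order")
        if len(set(run_ids)) != len(run_ids):
            raise ValidationError("duplicate run_id in matrix")
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein identifiers: {dupes}")
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative spectral counts")
        self.counts = counts.astype(np.int64)
        self.runs = list(runs)

    # -- basic views ---------------------------------------------------
    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    @property
    def run_ids(self) -> list[str]:
        return [r.run_id for r in self.runs]

    @property
    def cohort_labels(self) -> list[str]:
        return [r.cohort for r in self.runs]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def cohort_run_ids(self, cohort: str) -> list[str]:
        return [r.run_id for r in self.runs if r.cohort == cohort]

    def run_info(self, run_id: str) -> RunInfo:
        for r in self.runs:
            if r.run_id == run_id:
                return r
        raise ValidationError(f"unknown run_id {run_id!r}")

    def subset_proteins(self, proteins: Sequence[str]) -> "SpectralCountMatrix":
        missing = [p for p in proteins if p not in self.counts.index]
        if missing:
            raise ValidationError(f"unknown proteins: {missing[:5]}")
        return SpectralCountMatrix(self.counts.loc[list(proteins)], self.runs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralCountMatrix):
            return NotImplemented
        return self.runs == other.runs and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"SpectralCountMatrix({self.shape[0]} proteins x {self.shape[1]} runs)"

    # -- i/o -----------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write counts TSV plus a ``<path>.runs.tsv`` metadata sidecar."""
        self.counts.rename_axis("protein").to_csv(path, sep="\t")
        meta = pd.DataFrame(
            [(r.run_id, r.subject_id, r.cohort, r.replicate_kind) for r in self.runs],
            columns=["run_id", "subject_id", "cohort", "replicate_kind"],
        )
        meta.to_csv(f"{path}.runs.tsv", sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpectralCountMatrix":
        try:
            counts = pd.read_csv(path, sep="\t", index_col=0)
            meta = pd.read_csv(f"{path}.runs.tsv", sep="\t", dtype=str)
        except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise ParseError(f"cannot read matrix at {path}: {exc}") from exc
        runs = [
            RunInfo(row.run_id, row.subject_id, row.cohort, row.replicate_kind)
            for row in meta.itertuples()
        ]
        return cls(counts, runs)


@dataclass
class AnnotationTable:
    """Accession-level annotation plus gene -> functional-term mapping.

    ``proteins`` is indexed by accession with columns ``gene``, ``mw_kda``,
    ``pi``, ``location``; ``terms`` maps gene symbols to term sets (may be
    empty).
    """

    proteins: pd.DataFrame
    terms: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.proteins.index.has_duplicates:
            dupes = self.proteins.index[self.proteins.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate accessions in annotation: {dupes}")
        for col in ("gene", "mw_kda", "pi", "location"):
            if col not in self.proteins.columns:
                raise FormatError(f"annotation table missing column {col!r}")

    @classmethod
    def from_records(cls, records: Iterable[ProteinRecord],
                     terms: Mapping[str, set[str]] | None = None) -> "AnnotationTable":
        rows = {
            r.accession: (r.gene, r.mw_kda, r.pi, r.location) for r in records
        }
        df = pd.DataFrame.from_dict(
            rows, orient="index", columns=["gene", "mw_kda", "pi", "location"]
        ).rename_axis("accession")
        return cls(df, dict(terms or {}))

    def gene_of(self, accession: str) -> str | None:
        if accession in self.proteins.index:
            gene = self.proteins.at[accession, "gene"]
            if isinstance(gene, str) and gene:
                return gene
        return None

    def record(self, accession: str) -> ProteinRecord | None:
        if accession not in self.proteins.index:
            return None
        row = self.proteins.loc[accession]
        return ProteinRecord(
            accession=accession,
            gene=row["gene"] if isinstance(row["gene"], str) else "",
            mw_kda=float(row["mw_kda"]),
            pi=float(row["pi"]),
            location=row["location"] if isinstance(row["location"], str) else "unknown",
        )

    def to_tsv(self, path) -> None:
        self.proteins.rename_axis("accession").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, term_path=None) -> "AnnotationTable":
        try:
            df = pd.read_csv(path, sep="\t", index_col="accession")
        except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
            raise ParseError(f"cannot read annotation at {path}: {exc}") from exc
        df["gene"] = df["gene"].fillna("")
        df["location"] = df["location"].fillna("unknown").map(resolve_location)
        terms = read_term_mapping(term_path) if term_path else {}
        return cls(df, terms)


def read_term_mapping(path) -> dict[str, set[str]]:
    """Read a two-column (gene, term) TSV into gene -> term-set."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot read term mapping at {path}: {exc}") from exc
    for col in ("gene", "term"):
        if col not in df.columns:
            raise FormatError(f"term mapping missing column {col!r}")
    mapping: dict[str, set[str]] = {}
    for row in df.itertuples():
        mapping.setdefault(row.gene, set()).add(row.term)
    return mapping


# ---------------------------------------------------------------------------
# Run-list i/o
# ---------------------------------------------------------------------------

def _apply_dialect(df: pd.DataFrame, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename external column names to the canonical ones via ``dialect``."""
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    return df


def read_run_list(
    path,
    run_id: str | None = None,
    subject_id: str = "",
    cohort: str = "Wt",
    replicate_kind: str = "technical",
    dialect: Mapping[str, str] | None = None,
) -> RunList:
    """Read one per-run protein list TSV into a :class:`RunList`.

    The file must carry at least ``accession`` and ``spc`` columns (after
    dialect remapping); ``gene``, ``description``, ``mw_kda``, ``pi`` and
    ``location`` are optional and populate ``RunList.meta``. Rows with
    SpC <= 0 are rejected, duplicate accessions raise.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot read run list at {path}: {exc}") from exc
    df = _apply_dialect(df, dialect)
    for col in ("accession", "spc"):
        if col not in df.columns:
            raise FormatError(f"run list {path} missing required column {col!r}")
    if df["accession"].duplicated().any():
        dupes = df.loc[df["accession"].duplicated(), "accession"].unique().tolist()
        raise ValidationError(f"run list {path}: duplicate accession(s) {dupes}")
    bad = df[df["spc"] <= 0]
    if not bad.empty:
        raise ValidationError(
            f"run list {path}: SpC must be >= 1, offending accession(s) "
            f"{bad['accession'].tolist()[:5]}"
        )
    entries = dict(zip(df["accession"].astype(str), df["spc"].astype(int)))
    meta: dict[str, ProteinRecord] = {}
    has_meta = any(c in df.columns for c in ("gene", "mw_kda", "pi", "location", "description"))
    if has_meta:
        for row in df.itertuples():
            meta[str(row.accession)] = ProteinRecord(
                accession=str(row.accession),
                gene=str(getattr(row, "gene", "") or ""),
                description=str(getattr(row, "description", "") or ""),
                mw_kda=float(getattr(row, "mw_kda", float("nan"))),
                pi=float(getattr(row, "pi", float("nan"))),
                location=resolve_location(getattr(row, "location", None)),
            )
    rid = run_id if run_id is not None else str(path)
    return RunList(rid, subject_id or rid, cohort, replicate_kind, entries, meta)


def write_run_list(run: RunList, path) -> None:
    """Write a :class:`RunList` in the canonical TSV dialect (round-trips)."""
    rows = []
    for accession in sorted(run.entries):
        rec = run.meta.get(accession, ProteinRecord(accession))
        rows.append(
            (
                accession,
                rec.gene,
                rec.description,
                run.entries[accession],
                rec.mw_kda,
                rec.pi,
                rec.location,
            )
        )
    pd.DataFrame(rows, columns=RUN_LIST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_psm_table(path, dialect: Mapping[str, str] | None = None) -> list[PsmRecord]:
    """Read a PSM-level TSV into :class:`PsmRecord` objects."""
    try:
        df = pd.read_csv(path, sep="\t")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"cannot read PSM table at {path}: {exc}") from exc
    df = _apply_dialect(df, dialect)
    for col in ("peptide", "charge", "xcorr", "probability", "consensus_score", "is_decoy"):
        if col not in df.columns:
            raise FormatError(f"PSM table {path} missing required column {col!r}")
    records = []
    for row in df.itertuples():
        records.append(
            PsmRecord(
                peptide=str(row.peptide),
                charge=int(row.charge),
                xcorr=float(row.xcorr),
                probability=float(row.probability),
                consensus_score=float(row.consensus_score),
                is_decoy=bool(row.is_decoy),
                accession=str(getattr(row, "accession", "") or ""),
            )
        )
    return records


def write_psm_table(psms: Iterable[PsmRecord], path) -> None:
    rows = [
        (p.peptide, p.charge, p.xcorr, p.probability, p.consensus_score,
         p.is_decoy, p.accession)
        for p in psms
    ]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Matrix assembly and gene-level collapse
# ---------------------------------------------------------------------------

def assemble_matrix(lists: Sequence[RunList]) -> SpectralCountMatrix:
    """Assemble per-run lists into one rectangular spectral-count matrix.

    Rows are the union of all accessions (first-appearance order), columns
    follow the input run order; a protein absent from a run gets count 0.
    """
    if len(lists) < 2:
        raise ValidationError("assemble_matrix needs at least 2 runs")
    run_ids = [r.run_id for r in lists]
    if len(set(run_ids)) != len(run_ids):
        dupes = sorted({r for r in run_ids if run_ids.count(r) > 1})
        raise ValidationError(f"duplicate run_id(s): {dupes}")
    proteins: list[str] = []
    seen: set[str] = set()
    for run in lists:
        for accession in run.entries:
            if accession not in seen:
                seen.add(accession)
                proteins.append(accession)
    data = np.zeros((len(proteins), len(lists)), dtype=np.int64)
    index = {p: i for i, p in enumerate(proteins)}
    for j, run in enumerate(lists):
        for accession, spc in run.entries.items():
            data[index[accession], j] = spc
    counts = pd.DataFrame(data, index=proteins, columns=run_ids)
    runs = [RunInfo(r.run_id, r.subject_id, r.cohort, r.replicate_kind) for r in lists]
    return SpectralCountMatrix(counts, runs)


def map_accessions(
    matrix: SpectralCountMatrix,
    ann: AnnotationTable,
    collapse_by_gene: bool = False,
) -> SpectralCountMatrix:
    """Map accessions through the annotation, optionally summing rows per gene.

    Accessions without a gene annotation pass through unchanged (and are
    logged); total count mass per run is conserved exactly.
    """
    if not collapse_by_gene:
        return SpectralCountMatrix(matrix.counts, matrix.runs)
    keys = []
    unmapped = 0
    for accession in matrix.proteins:
        gene = ann.gene_of(accession)
        if gene is None:
            unmapped += 1
            keys.append(accession)
        else:
            keys.append(gene)
    if unmapped:
        logger.info("map_accessions: %d accession(s) without gene annotation pass through",
                    unmapped)
    collapsed = matrix.counts.groupby(
        pd.Index(keys, name="protein"), sort=False
    ).sum()
    return SpectralCountMatrix(collapsed, matrix.runs)


__all__ = [
    "AnnotationTable",
    "COHORTS",
    "LOCATIONS",
    "LOCATION_PRIORITY",
    "ProteinRecord",
    "PsmRecord",
    "RunInfo",
    "RunList",
    "SpectralCountMatrix",
    "assemble_matrix",
    "map_accessions",
    "read_psm_table",
    "read_run_list",
    "read_term_mapping",
    "resolve_location",
    "write_psm_table",
    "write_run_list",
]
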