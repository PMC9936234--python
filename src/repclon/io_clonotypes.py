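"""Reading, validation, and filtering of clonotype tables and sample metadata.

The pipeline starts downstream of read alignment: its inputs are tabular
clonotype exports (one row per assembled receptor sequence) plus a per-sample
metadata table carrying the consensus molecular subtype, clinical covariates,
overall survival, somatic mutation rates, and the 22 deconvolved immune-cell
fractions used by the inflammatory score.

Two clonotype dialects are accepted:

``generic``
    Canonical column names ``sample_id, chain, v_gene, j_gene, cdr3_nt,
    read_count`` (tab-separated, header required). This is also the dialect
    the package writes, so a write/read round trip is lossless.
``mixcr_v3``
    MiXCR v3 export columns: ``cloneCount`` → read_count, the top hit of
    ``allVHitsWithScore``/``allJHitsWithScore`` (trimmed at the first ``*``)
    → v_gene/j_gene, ``nSeqCDR3`` → cdr3_nt. Sample id and chain are taken
    from ``sample_id``/``chain`` columns when present, else must be supplied
    by the caller.

Rows without a CDR3 nucleotide sequence are dropped (the analysis is
restricted to reads covering the CDR3 region) and counted in a drop log;
malformed rows (bad read counts, non-ACGT CDR3s) are hard errors because they
indicate a corrupted export rather than a biological absence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

#: Receptor chains as exported by the aligner.
ALL_CHAINS = ("IGH", "IGK", "IGL", "TRA", "TRB", "TRD", "TRG")

#: Chains kept for analysis: the gamma/delta T-cell chains (TRD, TRG) carry
#: too few reads and clones to be informative and are filtered out.
DEFAULT_CHAINS = ("IGH", "IGK", "IGL", "TRA", "TRB")

BCR_CHAINS = ("IGH", "IGK", "IGL")
TCR_CHAINS = ("TRA", "TRB")

#: Consensus muscle-invasive bladder cancer subtypes retained for analysis.
#: Neuroendocrine-like tumors are excluded from the study design and are a
#: hard error when encountered in metadata.
SUBTYPES = ("LumP", "LumNS", "LumU", "Stroma-rich", "Ba/Sq")
EXCLUDED_SUBTYPES = ("NE-like",)

REGIONS = ("USA+Canada", "Europe", "Brazil+Puerto Rico")
STAGES = ("I-II", "III", "IV")

#: The 22 immune cell types summed by the inflammatory score, named exactly
#: as in the deconvolution output (dots as word separators).
CELL_TYPES_22 = (
    "Monocytes",
    "Macrophages.M0",
    "Macrophages.M1",
    "Macrophages.M2",
    "Dendritic.cells.resting",
    "Dendritic.cells.activated",
    "Mast.cells.resting",
    "Mast.cells.activated",
    "Neutrophils",
    "Eosinophils",
    "B.cells.naive",
    "B.cells.memory",
    "T.cells.CD4.naive",
    "T.cells.CD4.memory.resting",
    "T.cells.CD4.memory.activated",
    "T.cells.follicular.helper",
    "T.cells.regulatory",
    "T.cells.gamma.delta",
    "T.cells.CD8",
    "T.helper",
    "NK.cells.resting",
    "NK.cells.activated",
)

CLONOTYPE_COLUMNS = ("sample_id", "chain", "v_gene", "j_gene", "cdr3_nt", "read_count")

_CDR3_RE = re.compile(r"^[ACGT]+$")


class ClonotypeIOError(ValueError):
    """Raised for contract violations in clonotype or metadata tables."""


@dataclass(frozen=True)
class ClonotypeRecord:
    """One assembled receptor sequence.

    Attributes
    ----------
    sample_id : str
        Opaque sample identifier.
    chain : str
        Receptor chain, one of :data:`ALL_CHAINS`.
    v_gene, j_gene : str
        Gene-level V/J identifiers (allele suffix and score annotation
        stripped at read time).
    cdr3_nt : str
        Uppercase CDR3 nucleotide sequence over A/C/G/T.
    read_count : int
        Number of reads supporting the clonotype, >= 1.
    """

    sample_id: str
    chain: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    read_count: int

    def __post_init__(self) -> None:
        if self.chain not in ALL_CHAINS:
            raise ClonotypeIOError(f"unknown chain {self.chain!r}")
        if not _CDR3_RE.match(self.cdr3_nt):
            raise ClonotypeIOError(
                f"cdr3_nt must be non-empty over A/C/G/T, got {self.cdr3_nt!r}"
            )
        if self.read_count < 1:
            raise ClonotypeIOError(f"read_count must be >= 1, got {self.read_count}")


@dataclass
class SampleMetadata:
    """Per-sample clinical and molecular annotations.

    ``os_time``/``os_event`` may be ``None`` when survival is unavailable;
    such samples are kept for every analysis except Cox model fits.
    ``cell_fractions`` carries exactly the 22 inflammatory-score cell types.
    """

    sample_id: str
    subtype: str
    total_reads: int
    age_years: float
    sex: str
    region: str
    stage: str
    histology: str
    os_time: float | None
    os_event: int | None
    nsmr: float
    smr: float
    cell_fractions: dict[str, float] = field(default_factory=dict)

    @property
    def has_survival(self) -> bool:
        return self.os_time is not None and self.os_event is not None

    def __post_init__(self) -> None:
        if self.subtype in EXCLUDED_SUBTYPES:
            raise ClonotypeIOError(
                f"subtype {self.subtype!r} is excluded from the study design"
            )
        if self.subtype not in SUBTYPES:
            raise ClonotypeIOError(f"unknown subtype label {self.subtype!r}")
        if self.total_reads <= 0:
            raise ClonotypeIOError("total_reads must be positive")
        missing = set(CELL_TYPES_22) - set(self.cell_fractions)
        if missing:
            raise ClonotypeIOError(
                f"missing cell type fraction(s): {sorted(missing)}"
            )
        for name in CELL_TYPES_22:
            v = self.cell_fractions[name]
            if not (0.0 <= v <= 1.0):
                raise ClonotypeIOError(
                    f"cell fraction {name!r} = {v} outside [0, 1]"
                )


@dataclass
class CohortTable:
    """Clonotype records joined with sample metadata.

    ``records`` is a DataFrame with columns :data:`CLONOTYPE_COLUMNS`;
    ``metadata`` maps sample_id to :class:`SampleMetadata`. Every record's
    sample must appear in the metadata.
    """

    records: pd.DataFrame
    metadata: dict[str, SampleMetadata]

    def __post_init__(self) -> None:
        unknown = set(self.records["sample_id"].unique()) - set(self.metadata)
        if unknown:
            raise ClonotypeIOError(
                f"records reference samples absent from metadata: {sorted(unknown)[:5]}"
            )

    def metadata_frame(self) -> pd.DataFrame:
        """Metadata as a tidy DataFrame (cell fractions as columns)."""
        rows = []
        for m in self.metadata.values():
            row = {
                "sample_id": m.sample_id,
                "subtype": m.subtype,
                "total_reads": m.total_reads,
                "age_years": m.age_years,
                "sex": m.sex,
                "region": m.region,
                "stage": m.stage,
                "histology": m.histology,
                "os_time": np.nan if m.os_time is None else m.os_time,
                "os_event": np.nan if m.os_event is None else m.os_event,
                "nsmr": m.nsmr,
                "smr": m.smr,
            }
            row.update({c: m.cell_fractions[c] for c in CELL_TYPES_22})
            rows.append(row)
        return pd.DataFrame(rows)


class ReadResult(NamedTuple):
    records: pd.DataFrame
    drop_log: dict[str, int]


def _strip_hit(hit: str) -> str:
    """Reduce an aligner hit string to its gene-level identifier.

    Takes the first (highest-scoring) hit of a comma-separated list and trims
    the allele suffix and score annotation: ``"IGHV1-2*00(100)"`` →
    ``"IGHV1-2"``.
    """
    first = hit.split(",")[0].strip()
    return first.split("*")[0].split("(")[0].strip()


def _validate_records(df: pd.DataFrame, source: str) -> ReadResult:
    drop_log = {"no_cdr3": 0}
    n_in = len(df)

    cdr3 = df["cdr3_nt"].fillna("").astype(str).str.strip().str.upper()
    has_cdr3 = cdr3 != ""
    drop_log["no_cdr3"] = int((~has_cdr3).sum())
    df = df.loc[has_cdr3].copy()
    df["cdr3_nt"] = cdr3[has_cdr3]

    bad_alpha = ~df["cdr3_nt"].str.match(_CDR3_RE)
    if bad_alpha.any():
        row = df.index[bad_alpha][0]
        raise ClonotypeIOError(
            f"{source}: row {row}: cdr3_nt contains characters outside A/C/G/T "
            f"({df.loc[row, 'cdr3_nt']!r})"
        )

    counts = pd.to_numeric(df["read_count"], errors="coerce")
    bad = counts.isna() | (counts < 1) | (counts != counts.round())
    if bad.any():
        row = df.index[bad][0]
        raise ClonotypeIOError(
            f"{source}: row {row}: unparseable or non-positive read count "
            f"({df.loc[row, 'read_count']!r})"
        )
    df["read_count"] = counts.astype(np.int64)

    bad_chain = ~df["chain"].isin(ALL_CHAINS)
    if bad_chain.any():
        row = df.index[bad_chain][0]
        raise ClonotypeIOError(
            f"{source}: row {row}: unknown chain {df.loc[row, 'chain']!r}"
        )

    df = df[list(CLONOTYPE_COLUMNS)].reset_index(drop=True)
    assert len(df) + drop_log["no_cdr3"] == n_in
    return ReadResult(df, drop_log)


def read_clonotype_table(
    path: str | Path,
    dialect: str = "generic",
    sample_id: str | None = None,
    chain: str | None = None,
) -> ReadResult:
    """Read a clonotype TSV in the ``generic`` or ``mixcr_v3`` dialect.

    Returns the validated record table plus a drop log counting rows removed
    for lacking a CDR3 sequence. Missing required columns and unparseable
    read counts are hard errors.

    Parameters
    ----------
    sample_id, chain
        Fallbacks for MiXCR exports that do not carry these columns
        (MiXCR writes one file per sample/chain).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)

    if dialect == "generic":
        missing = set(CLONOTYPE_COLUMNS) - set(df.columns)
        if missing:
            raise ClonotypeIOError(
                f"{path}: missing required column(s): {sorted(missing)}"
            )
    elif dialect == "mixcr_v3":
        mapping = {
            "cloneCount": "read_count",
            "allVHitsWithScore": "v_gene",
            "allJHitsWithScore": "j_gene",
            "nSeqCDR3": "cdr3_nt",
        }
        missing = set(mapping) - set(df.columns)
        if missing:
            raise ClonotypeIOError(
                f"{path}: missing required column(s): {sorted(missing)}"
            )
        df = df.rename(columns=mapping)
        df["v_gene"] = df["v_gene"].fillna("").map(_strip_hit)
        df["j_gene"] = df["j_gene"].fillna("").map(_strip_hit)
        if "sample_id" not in df.columns:
            if sample_id is None:
                raise ClonotypeIOError(
                    f"{path}: no sample_id column; pass sample_id= explicitly"
                )
            df["sample_id"] = sample_id
        if "chain" not in df.columns:
            if chain is None:
                raise ClonotypeIOError(
                    f"{path}: no chain column; pass chain= explicitly"
                )
            df["chain"] = chain
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    return _validate_records(df, str(path))


def write_clonotype_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write records in the generic dialect (lossless round trip)."""
    records[list(CLONOTYPE_COLUMNS)].to_csv(path, sep="\t", index=False)


def filter_chains(
    records: pd.DataFrame, keep: Iterable[str] = DEFAULT_CHAINS
) -> pd.DataFrame:
    """Restrict records to the given chains (default drops TRD and TRG)."""
    keep = tuple(keep)
    if not keep:
        raise ValueError("keep must be a nonempty set of chains")
    unknown = set(keep) - set(ALL_CHAINS)
    if unknown:
        raise ValueError(f"unknown chain(s): {sorted(unknown)}")
    return records[records["chain"].isin(keep)].reset_index(drop=True)


_META_REQUIRED = (
    "sample_id",
    "subtype",
    "total_reads",
    "age_years",
    "sex",
    "region",
    "stage",
    "histology",
    "nsmr",
    "smr",
)


def read_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    """Read the sample metadata table (CSV or TSV, sniffed from the header).

    Unknown subtype labels are hard errors (the excluded neuroendocrine-like
    label in particular). Rows missing survival fields are retained with
    survival marked absent; they are excluded from Cox fits only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)

    missing = set(_META_REQUIRED) - set(df.columns)
    if missing:
        raise ClonotypeIOError(f"{path}: missing metadata column(s): {sorted(missing)}")
    missing_cells = set(CELL_TYPES_22) - set(df.columns)
    if missing_cells:
        raise ClonotypeIOError(
            f"{path}: missing cell-fraction column(s): {sorted(missing_cells)}"
        )

    out: dict[str, SampleMetadata] = {}
    for _, row in df.iterrows():
        os_time = row.get("os_time", np.nan)
        os_event = row.get("os_event", np.nan)
        has_surv = pd.notna(os_time) and pd.notna(os_event)
        meta = SampleMetadata(
            sample_id=str(row["sample_id"]),
            subtype=str(row["subtype"]),
            total_reads=int(row["total_reads"]),
            age_years=float(row["age_years"]),
            sex=str(row["sex"]),
            region=str(row["region"]),
            stage=str(row["stage"]),
            histology=str(row["histology"]),
            os_time=float(os_time) if has_surv else None,
            os_event=int(os_event) if has_surv else None,
            nsmr=float(row["nsmr"]),
            smr=float(row["smr"]),
            cell_fractions={c: float(row[c]) for c in CELL_TYPES_22},
        )
        out[meta.sample_id] = meta
    return out


def write_metadata(metadata: Mapping[str, SampleMetadata], path: str | Path) -> None:
    """Write metadata as CSV (inverse of :func:`read_metadata`)."""
    CohortTable(
        records=pd.DataFrame(columns=list(CLONOTYPE_COLUMNS)), metadata=dict(metadata)
    ).metadata_frame().to_csv(path, index=False)


def load_cohort(
    clonotype_path: str | Path,
    metadata_path: str | Path,
    dialect: str = "generic",
    keep_chains: Iterable[str] = DEFAULT_CHAINS,
) -> tuple[CohortTable, dict[str, int]]:
    """Read clonotypes + metadata, apply the chain filter, and cross-check.

    The per-sample receptor read sums must not exceed the metadata's
    ``total_reads`` (the sequencing-depth denominator of the richness
    measure); a violation is a metadata inconsistency and a hard error.
    """
    records, drop_log = read_clonotype_table(clonotype_path, dialect=dialect)
    records = filter_chains(records, keep_chains)
    metadata = read_metadata(metadata_path)
    cohort = CohortTable(records=records, metadata=metadata)
    sums = records.groupby("sample_id")["read_count"].sum()
    for sid, s in sums.items():
        if s > metadata[sid].total_reads:
            raise ClonotypeIOError(
                f"sample {sid}: receptor reads ({s}) exceed total_reads "
                f"({metadata[sid].total_reads})"
            )
    return cohort, drop_log
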