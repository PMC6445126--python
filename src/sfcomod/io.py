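"""Readers and writers for the tabular and sequence formats the pipeline touches.

The canonical table dialect is TSV (tab separator, ``.`` decimal, UTF-8);
CSV is accepted via ``sep=","``.  Expression values are assumed to be
log2-normalized already; ``log2_transform=True`` applies ``log2(x + 1)``
for raw-count users.  Gene identifiers are opaque strings — no symbol
mapping is attempted.
"""

from __future__ import annotations

import io as _io
import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("sfcomod")

PROMOTER_ALPHABET = frozenset("ACGTN")
PWM_BASES = "ACGT"


class FormatError(ValueError):
    """Raised when an input stream violates its declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, genes x samples.

    ``data`` is a pandas DataFrame whose index holds gene ids and whose
    columns hold sample ids.  Identifiers must be unique and every value
    finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite expression value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.data[list(samples)])


@dataclass
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. pathway collections read from a GMT file."""

    sets: dict[str, GeneSet]

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if not gs.genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


@dataclass
class PWM:
    """Position count matrix over A,C,G,T (rows) by motif position (columns)."""

    motif_id: str
    counts: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValidationError(f"PWM {self.motif_id}: counts must be 4 x w")
        if self.counts.shape[1] < 1:
            raise ValidationError(f"PWM {self.motif_id}: width must be >= 1")
        if (self.counts < 0).any():
            raise ValidationError(f"PWM {self.motif_id}: negative counts")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValidationError(f"PWM {self.motif_id}: all-zero column")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def consensus(self) -> str:
        return "".join(PWM_BASES[i] for i in self.counts.argmax(axis=0))


@dataclass
class PromoterSet:
    """Promoter sequences anchored to the TSS.

    Position 0 of the coordinate system is the transcription start site;
    ``offset_start`` gives the coordinate of the first base of each stored
    sequence (negative = upstream), ``offset_end`` the coordinate of the
    last base inclusive.
    """

    records: dict[str, str]
    offset_start: int
    offset_end: int

    def __post_init__(self) -> None:
        declared = self.offset_end - self.offset_start + 1
        for gene, seq in self.records.items():
            bad = set(seq.upper()) - PROMOTER_ALPHABET
            if bad:
                raise ValidationError(f"promoter {gene!r}: illegal characters {bad}")
            if len(seq) < declared:
                raise ValidationError(
                    f"promoter {gene!r}: length {len(seq)} shorter than declared "
                    f"window [{self.offset_start}, {self.offset_end}]"
                )

    def window_slice(self, gene: str, start_offset: int, end_offset: int) -> str:
        """Return the subsequence covering TSS offsets [start, end] inclusive."""
        if start_offset < self.offset_start or end_offset > self.offset_end:
            raise ValidationError(
                f"window [{start_offset}, {end_offset}] exceeds stored promoter "
                f"range [{self.offset_start}, {self.offset_end}]"
            )
        seq = self.records[gene].upper()
        i = start_offset - self.offset_start
        return seq[i : i + (end_offset - start_offset + 1)]


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates; any column may be absent."""

    data: pd.DataFrame

    ORDINAL = {"grade": (1, 2, 3), "mitotic_score": (1, 2, 3), "pleomorphism_score": (1, 2, 3)}

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in clinical table")
        for col, levels in self.ORDINAL.items():
            if col in self.data.columns:
                vals = self.data[col].dropna()
                if not vals.isin(levels).all():
                    raise ValidationError(f"clinical column {col!r} outside levels {levels}")
        if "er_status" in self.data.columns:
            vals = self.data["er_status"].dropna()
            if not vals.isin(["pos", "neg"]).all():
                raise ValidationError("er_status must be 'pos' or 'neg'")


@dataclass
class SurvivalTable:
    """Time-to-event data: one row per sample with ``time`` and ``event``."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in survival table")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValidationError(f"survival table missing column {col!r}")
        if (self.data["time"] < 0).any():
            raise ValidationError("negative survival times")
        if not self.data["event"].isin([0, 1]).all():
            raise ValidationError("event must be 0 (censored) or 1 (observed)")

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_table(
    stream: IO[str] | str,
    orientation: str = "genes_in_rows",
    sep: str = "\t",
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Read a TSV/CSV expression table into genes x samples orientation.

    The first row and first column carry identifiers.  With
    ``orientation="samples_in_rows"`` the table is transposed after parsing,
    so both orientations of the same data yield identical matrices.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(stream, sep=sep, index_col=0, header=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            numeric[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0]
            raise FormatError(
                f"non-numeric cell at row {row!r}, column {col!r}: {bad.iloc[0]!r}"
            ) from None
    if numeric.isna().to_numpy().any():
        idx = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"missing value at row {numeric.index[idx[0]]!r}, "
            f"column {numeric.columns[idx[1]]!r}"
        )
    if orientation == "samples_in_rows":
        numeric = numeric.T
    numeric.index.name = None
    numeric.columns.name = None
    if log2_transform:
        if (numeric.to_numpy() < 0).any():
            raise ValidationError("log2(x+1) transform requires non-negative input")
        numeric = np.log2(numeric + 1.0)
    matrix = ExpressionMatrix(numeric)
    log.info("read expression table: %d genes x %d samples", *matrix.shape)
    return matrix


def write_expression_table(matrix: ExpressionMatrix, stream: IO[str] | str, sep: str = "\t") -> None:
    matrix.data.to_csv(stream, sep=sep, float_format="%.12g", index_label="gene_id")


def read_gmt(stream: IO[str] | str) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, genes; tab-separated).

    Duplicate genes within a line are deduplicated with a warning; duplicate
    set names are an error.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream) if "\t" in stream or "\n" in stream else open(stream)
    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line {lineno}: expected >= 3 tab-separated fields")
        name, desc, genes = fields[0], fields[1], fields[2:]
        genes = [g for g in genes if g]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) < len(genes):
            log.warning("GMT set %r: %d duplicate gene ids removed", name, len(genes) - len(deduped))
        if name in sets:
            raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
        sets[name] = GeneSet(name, desc, tuple(deduped))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, stream: IO[str] | str) -> None:
    close = False
    if isinstance(stream, str):
        stream, close = open(stream, "w"), True
    try:
        for gs in collection:
            stream.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")
    finally:
        if close:
            stream.close()


_JASPAR_ROW = re.compile(
    r"^\s*([ACGT])\s*[\[\|]?\s*([-\d.eE+\s]*?)\s*[\]\|]?\s*$"
)


def read_jaspar(stream: IO[str] | str) -> list[PWM]:
    """Read JASPAR-style text PWMs (``>ID NAME`` header, four base rows).

    Both the bracketed (``A  [ 1 2 3 ]``) and unbracketed dialects parse
    identically.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream) if "\n" in stream or stream.startswith(">") else open(stream)
    pwms: list[PWM] = []
    header: str | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        missing = [b for b in PWM_BASES if b not in rows]
        if missing:
            raise FormatError(f"motif {header!r}: missing base rows {missing}")
        lengths = {len(rows[b]) for b in PWM_BASES}
        if len(lengths) != 1:
            raise FormatError(f"motif {header!r}: unequal base-row lengths {sorted(lengths)}")
        parts = header.split(None, 1)
        motif_id = parts[0]
        name = parts[1] if len(parts) > 1 else ""
        pwms.append(PWM(motif_id, np.array([rows[b] for b in PWM_BASES]), name=name))
        header, rows = None, {}

    for line in stream:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            continue
        m = _JASPAR_ROW.match(line)
        if not m:
            raise FormatError(f"unparseable PWM row: {line!r}")
        base, body = m.group(1), m.group(2)
        if base in rows:
            raise FormatError(f"motif {header!r}: duplicate base row {base}")
        rows[base] = [float(x) for x in body.split()]
    flush()
    return pwms


def write_jaspar(pwms: Iterable[PWM], stream: IO[str] | str) -> None:
    close = False
    if isinstance(stream, str):
        stream, close = open(stream, "w"), True
    try:
        for pwm in pwms:
            stream.write(f">{pwm.motif_id} {pwm.name}".rstrip() + "\n")
            for i, base in enumerate(PWM_BASES):
                vals = " ".join(f"{v:g}" for v in pwm.counts[i])
                stream.write(f"{base} [ {vals} ]\n")
    finally:
        if close:
            stream.close()


def read_promoters_fasta(
    stream: IO[str] | str, offset_start: int, offset_end: int
) -> PromoterSet:
    """Read promoter sequences from FASTA; record ids are gene ids."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(stream, "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate promoter record {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return PromoterSet(records, offset_start, offset_end)


def write_promoters_fasta(promoters: PromoterSet, stream: IO[str] | str) -> None:
    recs = [
        SeqRecord(
            Seq(seq),
            id=gene,
            description=f"offset_start={promoters.offset_start} offset_end={promoters.offset_end}",
        )
        for gene, seq in promoters.records.items()
    ]
    SeqIO.write(recs, stream, "fasta")


def read_clinical_table(stream: IO[str] | str, sep: str = "\t") -> ClinicalTable:
    df = pd.read_csv(stream, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def read_survival_table(stream: IO[str] | str, sep: str = "\t") -> SurvivalTable:
    df = pd.read_csv(stream, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return SurvivalTable(df)


def write_result_table(records: pd.DataFrame, stream: IO[str] | str, sep: str = "\t") -> None:
    """Write a result table as TSV with >= 12 significant digits on floats.

    Reading the file back reproduces every numeric value within 1e-12
    relative tolerance (in practice exactly, via 17-digit shortest repr).
    """
    records.to_csv(stream, sep=sep, float_format="%.17g", index=False)


def read_result_table(stream: IO[str] | str, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(stream, sep=sep)


def read_yaml_config(stream: IO[str] | str) -> dict:
    if isinstance(stream, str) and "\n" not in stream:
        with open(stream) as fh:
            return yaml.safe_load(fh) or {}
    return yaml.safe_load(stream) or {}
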