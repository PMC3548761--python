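"""Validated domain types and file I/O for the encoding pipeline inputs.

Covers amino-acid pairwise contact potentials (AAPPs, AAindex flat-file
dialect or a plain residue-labelled TSV), peptide-HLA contact maps,
positional scoring matrices (PSMs), peptide tables and protein FASTA.

All positions in files are 1-based: peptide positions run 1..9 and HLA
positions 1..L, matching the crystal-structure numbering convention the
contact maps come from.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .residues import AA_TO_INDEX, AAINDEX_ORDER, ALPHABETICAL, is_canonical

logger = logging.getLogger(__name__)

PEPTIDE_LENGTH = 9
N_RESIDUES = 20


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContactPotentialMatrix:
    """A symmetric 20x20 pairwise contact potential E(a1, a2).

    ``values`` is indexed by alphabetical one-letter residue order on both
    axes. Symmetry is exact (mirroring happens at parse time), so no
    tolerance is needed to check it.
    """

    id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (N_RESIDUES, N_RESIDUES):
            raise ValidationError(f"potential {self.id!r}: shape {v.shape}, expected 20x20")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"potential {self.id!r}: non-finite entries")
        if not np.array_equal(v, v.T):
            raise ValidationError(f"potential {self.id!r}: matrix is not symmetric")

    def value(self, a1: str, a2: str) -> float:
        return float(self.values[AA_TO_INDEX[a1], AA_TO_INDEX[a2]])


@dataclass(frozen=True)
class HlaAllele:
    """An HLA protein: allele label plus its residue sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"allele {self.name!r}: empty sequence")
        if not is_canonical(self.sequence):
            bad = sorted({c for c in self.sequence if c not in AA_TO_INDEX})
            raise ValidationError(f"allele {self.name!r}: non-canonical letters {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ContactMap:
    """The indicator delta_ij: which peptide positions touch which HLA residues.

    ``pairs`` holds 1-based (peptide_pos, hla_pos) tuples. Every peptide
    position 1..9 must appear at least once so the contact-count denominator
    of the encoding score never vanishes.
    """

    allele_name: str
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", frozenset((int(i), int(j)) for i, j in self.pairs))
        seen = set()
        for i, j in self.pairs:
            if not 1 <= i <= PEPTIDE_LENGTH:
                raise ValidationError(f"contact map {self.allele_name!r}: peptide position {i} outside 1..9")
            if j < 1:
                raise ValidationError(f"contact map {self.allele_name!r}: HLA position {j} < 1")
            seen.add(i)
        missing = set(range(1, PEPTIDE_LENGTH + 1)) - seen
        if missing:
            raise ValidationError(
                f"contact map {self.allele_name!r}: peptide positions {sorted(missing)} have no contacts"
            )

    def contacts_of(self, i: int) -> list[int]:
        """Sorted HLA positions contacting peptide position ``i`` (1-based)."""
        return sorted(j for p, j in self.pairs if p == i)

    def validate_for(self, hla: HlaAllele) -> None:
        too_big = sorted(j for _, j in self.pairs if j > hla.length)
        if too_big:
            raise ValidationError(
                f"contact map {self.allele_name!r}: HLA positions {too_big[:5]} exceed "
                f"length {hla.length} of allele {hla.name!r}"
            )


@dataclass(frozen=True)
class PositionalScoringMatrix:
    """Position-specific residue scores T_i(a): 9 rows x 20 alphabetical columns.

    ``scaled`` marks a matrix that has been negated and affinely mapped into
    ``scale_range`` (default [1, 10]); both endpoints must then be attained.
    """

    values: np.ndarray
    scaled: bool = False
    scale_range: tuple[float, float] = (1.0, 10.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (PEPTIDE_LENGTH, N_RESIDUES):
            raise ValidationError(f"PSM: shape {v.shape}, expected 9x20")
        if not np.all(np.isfinite(v)):
            raise ValidationError("PSM: non-finite entries")
        if self.scaled:
            lo, hi = self.scale_range
            if v.min() < lo - 1e-9 or v.max() > hi + 1e-9:
                raise ValidationError(f"scaled PSM: entries outside [{lo}, {hi}]")
            if abs(v.min() - lo) > 1e-9 or abs(v.max() - hi) > 1e-9:
                raise ValidationError(f"scaled PSM: endpoints {lo} and {hi} not attained")

    def score(self, i: int, aa: str) -> float:
        """T_i(aa) with ``i`` 1-based."""
        return float(self.values[i - 1, AA_TO_INDEX[aa]])


@dataclass(frozen=True)
class PeptideRecord:
    """A nonapeptide with an optional IC50 (nM) and/or binary label."""

    sequence: str
    ic50_nM: float | None = None
    label: str | None = None  # "binder" | "nonbinder"

    def __post_init__(self) -> None:
        if len(self.sequence) != PEPTIDE_LENGTH:
            raise ValidationError(f"peptide {self.sequence!r}: length {len(self.sequence)}, expected 9")
        if not is_canonical(self.sequence):
            bad = sorted({c for c in self.sequence if c not in AA_TO_INDEX})
            raise ValidationError(f"peptide {self.sequence!r}: non-canonical letters {bad}")
        if self.ic50_nM is not None and not (np.isfinite(self.ic50_nM) and self.ic50_nM > 0):
            raise ValidationError(f"peptide {self.sequence!r}: IC50 must be finite and positive")
        if self.label is not None and self.label not in ("binder", "nonbinder"):
            raise ValidationError(f"peptide {self.sequence!r}: label {self.label!r} invalid")


@dataclass(frozen=True)
class DescriptorTable:
    """A 20 x d table of per-residue descriptor values (rows alphabetical)."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != N_RESIDUES or v.shape[1] < 1:
            raise ValidationError(f"descriptor {self.name!r}: shape {v.shape}, expected 20 x d (d>=1)")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"descriptor {self.name!r}: non-finite entries")

    @property
    def dim(self) -> int:
        return int(self.values.shape[1])


# ---------------------------------------------------------------------------
# AAPP parsing / writing
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def parse_aaindex_matrix(text: str) -> ContactPotentialMatrix:
    """Parse one AAindex flat-file matrix entry into a ContactPotentialMatrix.

    The matrix block starts at the ``M rows = ..., cols = ...`` line and holds
    either a lower-triangular or a full square 20x20 block in the flat-file
    residue order (ARNDCQEGHILKMFPSTWYV); the result is mirrored to a full
    symmetric matrix and re-indexed to alphabetical order. Missing cells
    (``-`` or ``NA``) are rejected.
    """
    lines = text.splitlines()
    accession = None
    m_line_idx = None
    for idx, line in enumerate(lines):
        if line.startswith("H "):
            accession = line[2:].strip()
        elif line.startswith("M "):
            m_line_idx = idx
            break
    if accession is None:
        raise ParseError("no accession line (H ...) found")
    if m_line_idx is None:
        raise ParseError(f"entry {accession}: no matrix block (M rows = ...) found")

    m = re.search(r"rows\s*=\s*([A-Z]+)\s*,\s*cols\s*=\s*([A-Z]+)", lines[m_line_idx])
    if not m:
        raise ParseError(f"entry {accession}: cannot parse alphabets from line: {lines[m_line_idx]!r}")
    rows_alpha, cols_alpha = m.group(1), m.group(2)
    if sorted(rows_alpha) != sorted(ALPHABETICAL) or sorted(cols_alpha) != sorted(ALPHABETICAL):
        raise ParseError(f"entry {accession}: row/column alphabet is not the 20 canonical residues")

    raw_rows: list[list[float]] = []
    for line in lines[m_line_idx + 1 :]:
        stripped = line.strip()
        if stripped.startswith("//"):
            break
        if not stripped:
            continue
        cells = stripped.split()
        row: list[float] = []
        for cell in cells:
            if cell in ("-", "NA", "NA."):
                raise ParseError(f"entry {accession}: missing cell {cell!r} on line: {line!r}")
            if not _NUM_RE.match(cell):
                raise ParseError(f"entry {accession}: non-numeric cell {cell!r} on line: {line!r}")
            row.append(float(cell))
        raw_rows.append(row)

    if len(raw_rows) != N_RESIDUES:
        raise ParseError(f"entry {accession}: {len(raw_rows)} matrix rows, expected 20")

    lengths = [len(r) for r in raw_rows]
    full = np.empty((N_RESIDUES, N_RESIDUES))
    if lengths == list(range(1, N_RESIDUES + 1)):
        for r, row in enumerate(raw_rows):  # lower triangle, mirror upward
            for c, val in enumerate(row):
                full[r, c] = val
                full[c, r] = val
    elif lengths == [N_RESIDUES] * N_RESIDUES:
        full = np.array(raw_rows)
        if not np.allclose(full, full.T):
            raise ParseError(f"entry {accession}: square matrix block is not symmetric")
        full = (full + full.T) / 2.0  # exact symmetry for downstream equality checks
    else:
        raise ParseError(
            f"entry {accession}: rows have lengths {lengths}; expected lower-triangular (1..20) or square (20 each)"
        )

    # re-index from the flat-file order into alphabetical order
    perm = [rows_alpha.index(aa) for aa in ALPHABETICAL]
    values = full[np.ix_(perm, [cols_alpha.index(aa) for aa in ALPHABETICAL])]
    return ContactPotentialMatrix(id=accession, values=values)


def parse_aaindex_file(text: str) -> list[ContactPotentialMatrix]:
    """Parse every entry (``//``-separated) of an AAindex flat file."""
    entries = [chunk for chunk in text.split("//") if chunk.strip()]
    out = []
    for chunk in entries:
        if any(line.startswith("H ") for line in chunk.splitlines()):
            out.append(parse_aaindex_matrix(chunk + "\n//"))
    return out


def read_potential_tsv(path: str | Path) -> ContactPotentialMatrix:
    """Read a plain residue-labelled 20x20 TSV potential (fixture dialect)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if sorted(df.index) != list(ALPHABETICAL) or sorted(df.columns) != list(ALPHABETICAL):
        raise ParseError(f"{path}: rows/columns are not the 20 canonical residues")
    ordered = df.loc[list(ALPHABETICAL), list(ALPHABETICAL)]
    if ordered.isna().any().any():
        raise ParseError(f"{path}: missing cells")
    stem = path.stem
    if stem.endswith(".potential"):
        stem = stem[: -len(".potential")]
    return ContactPotentialMatrix(id=stem, values=ordered.to_numpy(dtype=float))


def write_potential_tsv(cpm: ContactPotentialMatrix, path: str | Path) -> None:
    df = pd.DataFrame(cpm.values, index=list(ALPHABETICAL), columns=list(ALPHABETICAL))
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------


def read_contact_map(path: str | Path, allele_name: str = "") -> ContactMap:
    """Read a contact map TSV with integer columns (peptide_pos, hla_pos).

    An optional header and an optional ``allele`` column are accepted.
    Duplicate rows collapse to one pair (set semantics).
    """
    path = Path(path)
    first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    has_header = not str(first.iloc[0, 0]).lstrip("+-").isdigit()
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    if has_header:
        cols = {c.lower(): c for c in df.columns}
        pep_col = cols.get("peptide_pos", df.columns[0])
        hla_col = cols.get("hla_pos", df.columns[1])
        if "allele" in cols and not allele_name:
            alleles = df[cols["allele"]].unique()
            if len(alleles) == 1:
                allele_name = str(alleles[0])
    else:
        pep_col, hla_col = df.columns[0], df.columns[1]
    try:
        pairs = {(int(i), int(j)) for i, j in zip(df[pep_col], df[hla_col])}
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-integer position: {exc}") from exc
    for i, j in pairs:
        if not 1 <= i <= PEPTIDE_LENGTH:
            raise ValidationError(f"{path}: peptide position {i} outside 1..9")
    return ContactMap(allele_name=allele_name or path.stem, pairs=frozenset(pairs))


def write_contact_map(cm: ContactMap, path: str | Path) -> None:
    df = pd.DataFrame(sorted(cm.pairs), columns=["peptide_pos", "hla_pos"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# positional scoring matrices
# ---------------------------------------------------------------------------


def read_psm(path: str | Path) -> PositionalScoringMatrix:
    """Read a 9x20 PSM TSV (rows = peptide positions 1..9, residue-labelled columns)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.columns = [str(c) for c in df.columns]
    if sorted(df.columns) != list(ALPHABETICAL):
        unknown = sorted(set(df.columns) - set(ALPHABETICAL))
        raise ParseError(f"{path}: unexpected residue columns {unknown or df.columns.tolist()}")
    if len(df) != PEPTIDE_LENGTH:
        raise ParseError(f"{path}: {len(df)} rows, expected 9")
    ordered = df[list(ALPHABETICAL)]
    if ordered.isna().any().any():
        raise ParseError(f"{path}: non-numeric or missing cells")
    return PositionalScoringMatrix(values=ordered.to_numpy(dtype=float), scaled=False)


def write_psm(psm: PositionalScoringMatrix, path: str | Path) -> None:
    df = pd.DataFrame(psm.values, index=range(1, PEPTIDE_LENGTH + 1), columns=list(ALPHABETICAL))
    df.index.name = "position"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# peptide tables
# ---------------------------------------------------------------------------


def read_peptide_table(
    path: str | Path, rejected: list[tuple[str, str]] | None = None
) -> list[PeptideRecord]:
    """Read a peptide TSV with columns ``sequence`` + (``ic50_nM`` | ``label``).

    Invalid rows (length != 9, non-canonical letters such as B/Z/J/U/O/X,
    non-positive IC50) are rejected with a reason; the rejection count is
    logged and, if ``rejected`` is given, (sequence, reason) tuples are
    appended to it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "sequence" not in df.columns:
        raise ParseError(f"{path}: no 'sequence' column")
    if "ic50_nM" not in df.columns and "label" not in df.columns:
        raise ParseError(f"{path}: need an 'ic50_nM' or 'label' column")
    records: list[PeptideRecord] = []
    n_rejected = 0
    for _, row in df.iterrows():
        seq = str(row["sequence"])
        ic50 = row.get("ic50_nM")
        ic50 = None if ic50 is None or pd.isna(ic50) else float(ic50)
        label = row.get("label")
        label = None if label is None or (isinstance(label, float) and pd.isna(label)) else str(label)
        try:
            records.append(PeptideRecord(sequence=seq, ic50_nM=ic50, label=label))
        except ValidationError as exc:
            n_rejected += 1
            if rejected is not None:
                rejected.append((seq, str(exc)))
            logger.warning("rejected peptide row: %s", exc)
    if n_rejected:
        logger.info("%s: rejected %d of %d rows", path, n_rejected, len(df))
    return records


def write_peptide_table(records: Iterable[PeptideRecord], path: str | Path) -> None:
    rows = [
        {"sequence": r.sequence, "ic50_nM": r.ic50_nM, "label": r.label} for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_hla_fasta(path: str | Path) -> list[HlaAllele]:
    """Read HLA protein sequences; the FASTA id is the allele name."""
    return [
        HlaAllele(name=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(named_sequences: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in named_sequences:
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")
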