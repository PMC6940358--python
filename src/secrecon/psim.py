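"""Protein-specific information matrix (PSIM).

A PSIM row is the per-protein feature vector that drives secretory-pathway
costing and pathway generation: residue length (L), molecular weight (MW, Da),
signal-peptide presence (SP), disulfide-bond count (DSB), GPI-anchor flag,
N-/O-glycan counts (NG/OG), transmembrane-domain count (TMD) and subcellular
location. Features are consumed as given; this package never predicts them
from sequence.
"""

from __future__ import annotations

import io
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "AMINO_ACIDS",
    "LOCATIONS",
    "PSIMEntry",
    "SecretomeTable",
    "SequenceRecord",
    "PSIMFormatError",
    "PSIMValidationError",
    "validate_entry",
    "parse_psim_table",
    "write_psim_table",
    "amino_acid_composition",
    "read_sequences",
]

#: Canonical one-letter amino-acid alphabet (alphabetical).
AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Recognized subcellular-location labels; anything else maps to "other".
LOCATIONS = (
    "secreted",
    "plasma membrane",
    "ER lumen",
    "ER membrane",
    "Golgi membrane",
    "lysosome",
    "other",
)

PSIM_COLUMNS = (
    "protein_id",
    "length",
    "mw",
    "sp",
    "dsb",
    "gpi",
    "ng",
    "og",
    "tmd",
    "location",
    "copies",
)
_REQUIRED_COLUMNS = PSIM_COLUMNS[:9]


class PSIMFormatError(ValueError):
    """Raised for malformed PSIM files (missing columns, unparseable fields)."""


class PSIMValidationError(ValueError):
    """Raised when a PSIM row violates the entry invariants."""


@dataclass(frozen=True)
class PSIMEntry:
    """One protein's secretory feature vector.

    For assembled multimeric products (e.g. an IgG tetramer) ``length`` and
    ``molecular_weight`` refer to the total residues/mass of the assembled
    molecule; signal-peptide degradation and translocon activation are costed
    once per molecule under this convention.
    """

    protein_id: str
    length: int
    molecular_weight: float
    has_signal_peptide: bool = False
    disulfide_bonds: int = 0
    has_gpi_anchor: bool = False
    n_glycans: int = 0
    o_glycans: int = 0
    transmembrane_domains: int = 0
    location: str = "other"
    subunit_copies: int = 1

    def violations(self) -> list[str]:
        """Return human-readable invariant violations (empty if valid)."""
        v: list[str] = []
        if not self.protein_id:
            v.append("protein_id: must be non-empty")
        if self.length < 1:
            v.append(f"length: must be >= 1, got {self.length}")
        if self.molecular_weight <= 40 * max(self.length, 1):
            v.append(
                "molecular_weight: must exceed 40 Da per residue "
                f"({self.molecular_weight} <= {40 * self.length})"
            )
        for name in ("disulfide_bonds", "n_glycans", "o_glycans",
                     "transmembrane_domains"):
            if getattr(self, name) < 0:
                v.append(f"{name}: must be >= 0")
        if self.n_glycans > self.length:
            v.append(f"n_glycans: {self.n_glycans} exceeds length {self.length}")
        if self.disulfide_bonds > self.length / 2:
            v.append(
                f"disulfide_bonds: {self.disulfide_bonds} exceeds length/2 "
                f"({self.length / 2:g})"
            )
        if self.location == "secreted" and not self.has_signal_peptide:
            v.append("location: secreted protein must carry a signal peptide")
        if self.location not in LOCATIONS:
            v.append(f"location: unknown label {self.location!r}")
        if self.subunit_copies < 1:
            v.append("subunit_copies: must be >= 1")
        return v

    @property
    def is_secretory(self) -> bool:
        """Whether the protein enters the secretory pathway at all."""
        return self.has_signal_peptide

    @property
    def is_membrane_bound(self) -> bool:
        return self.transmembrane_domains > 0 or self.has_gpi_anchor or (
            self.location in ("plasma membrane", "ER membrane", "Golgi membrane")
        )


def validate_entry(entry: PSIMEntry) -> list[str]:
    """Total validation function: list of violation descriptors, empty iff valid."""
    return entry.violations()


@dataclass
class SecretomeTable:
    """Ordered collection of PSIM entries with unique protein ids."""

    entries: list[PSIMEntry] = field(default_factory=list)
    source_taxon: str = "cho"

    def __post_init__(self) -> None:
        ids = [e.protein_id for e in self.entries]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise PSIMValidationError(f"duplicate protein_id(s): {sorted(dupes)}")
        self._index = {e.protein_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PSIMEntry]:
        return iter(self.entries)

    def __getitem__(self, protein_id: str) -> PSIMEntry:
        return self._index[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def ids(self) -> list[str]:
        return [e.protein_id for e in self.entries]


_BOOL = {"0": False, "1": True, "no": False, "yes": True,
         "false": False, "true": True}


def _parse_bool(token: str, column: str, line_no: int) -> bool:
    try:
        return _BOOL[token.strip().lower()]
    except KeyError:
        raise PSIMFormatError(
            f"line {line_no}: column {column!r}: cannot parse boolean {token!r}"
        ) from None


def _parse_int(token: str, column: str, line_no: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise PSIMFormatError(
            f"line {line_no}: column {column!r}: non-numeric value {token!r}"
        ) from None


def parse_psim_table(path: str | Path | io.TextIOBase,
                     taxon: str = "cho") -> SecretomeTable:
    """Parse a tab-separated PSIM file into a validated :class:`SecretomeTable`.

    The dialect is UTF-8 TSV with ``#`` comment lines and a fixed header whose
    first nine columns are ``protein_id length mw sp dsb gpi ng og tmd``;
    ``location`` and ``copies`` are optional trailing columns. Booleans are
    serialized as 0/1. Rows violating entry invariants are rejected with
    row-addressed diagnostics; unknown location labels map to ``other`` with a
    warning.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text(encoding="utf-8").splitlines()

    rows = [(i + 1, ln) for i, ln in enumerate(lines)
            if ln.strip() and not ln.lstrip().startswith("#")]
    if not rows:
        raise PSIMFormatError("empty PSIM file (no header)")

    header_no, header_line = rows[0]
    header = [c.strip() for c in header_line.split("\t")]
    missing = [c for c in _REQUIRED_COLUMNS if c not in header]
    if missing:
        raise PSIMFormatError(f"missing required column(s): {missing}")
    col = {name: header.index(name) for name in header}

    entries: list[PSIMEntry] = []
    errors: list[str] = []
    for line_no, line in rows[1:]:
        fields = line.split("\t")
        if len(fields) < len(_REQUIRED_COLUMNS):
            errors.append(f"line {line_no}: expected >= 9 fields, got {len(fields)}")
            continue

        def get(name: str, default: str | None = None) -> str:
            idx = col.get(name)
            if idx is None or idx >= len(fields):
                if default is None:
                    raise PSIMFormatError(f"line {line_no}: missing field {name!r}")
                return default
            return fields[idx].strip()

        try:
            location = get("location", "other") or "other"
            if location not in LOCATIONS:
                warnings.warn(
                    f"line {line_no}: unknown location {location!r} mapped to 'other'",
                    stacklevel=2,
                )
                location = "other"
            mw_text = get("mw").replace(",", "")
            entry = PSIMEntry(
                protein_id=get("protein_id"),
                length=_parse_int(get("length"), "length", line_no),
                molecular_weight=float(mw_text),
                has_signal_peptide=_parse_bool(get("sp"), "sp", line_no),
                disulfide_bonds=_parse_int(get("dsb"), "dsb", line_no),
                has_gpi_anchor=_parse_bool(get("gpi"), "gpi", line_no),
                n_glycans=_parse_int(get("ng"), "ng", line_no),
                o_glycans=_parse_int(get("og"), "og", line_no),
                transmembrane_domains=_parse_int(get("tmd"), "tmd", line_no),
                location=location,
                subunit_copies=_parse_int(get("copies", "1"), "copies", line_no),
            )
        except PSIMFormatError as exc:
            errors.append(str(exc))
            continue
        except ValueError as exc:
            errors.append(f"line {line_no}: {exc}")
            continue
        bad = entry.violations()
        if bad:
            errors.append(f"line {line_no} ({entry.protein_id}): " + "; ".join(bad))
            continue
        entries.append(entry)

    if errors:
        raise PSIMValidationError(
            f"{len(errors)} invalid PSIM row(s):\n" + "\n".join(errors)
        )
    return SecretomeTable(entries=entries, source_taxon=taxon)


def write_psim_table(table: SecretomeTable, path: str | Path) -> None:
    """Serialize a table in the canonical TSV dialect (round-trips with parse)."""
    out = ["\t".join(PSIM_COLUMNS)]
    for e in table:
        mw = repr(e.molecular_weight)
        out.append("\t".join(map(str, (
            e.protein_id, e.length, mw, int(e.has_signal_peptide),
            e.disulfide_bonds, int(e.has_gpi_anchor), e.n_glycans, e.o_glycans,
            e.transmembrane_domains, e.location, e.subunit_copies,
        ))))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class SequenceRecord:
    """An amino-acid sequence linked to a PSIM entry by protein id."""

    protein_id: str
    residues: str


def amino_acid_composition(seq: SequenceRecord | str) -> dict[str, int]:
    """Count residues per amino acid over the 20-letter alphabet.

    ``X`` (unknown residue) is tolerated in the sequence but excluded from the
    returned counts, whose values then sum to the number of assignable
    residues. An all-``X`` or empty sequence yields no stoichiometry and is an
    error.
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    if not residues:
        raise ValueError("empty sequence: no composition derivable")
    residues = residues.upper()
    illegal = set(residues) - set(AMINO_ACIDS) - {"X"}
    if illegal:
        raise ValueError(f"illegal residue character(s): {sorted(illegal)}")
    counts = Counter(residues)
    counts.pop("X", None)
    if not counts:
        raise ValueError("all-X sequence: no composition derivable")
    return {aa: counts.get(aa, 0) for aa in AMINO_ACIDS}


def read_sequences(path: str | Path) -> dict[str, SequenceRecord]:
    """Read protein sequences from FASTA, keyed by record id."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = SequenceRecord(protein_id=rec.id, residues=str(rec.seq))
    return records
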