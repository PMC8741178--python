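"""Readers and writers for the external formats the pipeline touches.

Sequences arrive as FASTA (UniProt ``sp|ACC|NAME`` headers understood),
protein abundances as delimited tables from label-free LC-MS/MS
quantification, and per-residue solvent accessibility as NetSurfP 2.0 CSV
exports.  All functions are side-effect free; the CLI (:mod:`nanocorona.cli`)
is the only place modules are wired together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity / non-standard codes that are retained in sequences but
#: excluded from descriptor numerators and denominators.
AMBIGUOUS_AA = "XBZUO"
VALID_AA = set(STANDARD_AA) | set(AMBIGUOUS_AA)

BIOFLUIDS = ("plasma", "csf", "other")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession, amino-acid sequence, optional biofluid tag."""

    accession: str
    sequence: str
    biofluid: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.biofluid is not None and self.biofluid not in BIOFLUIDS:
            raise ValueError(
                f"{self.accession}: biofluid must be one of {BIOFLUIDS}, "
                f"got {self.biofluid!r}"
            )
        for i, letter in enumerate(self.sequence, start=1):
            if letter not in VALID_AA:
                raise ValueError(
                    f"{self.accession}: invalid residue {letter!r} at "
                    f"position {i}"
                )


@dataclass(frozen=True)
class AbundanceRecord:
    """Quantified abundance of one protein on the nanoparticle and in the
    biofluid-only control, in arbitrary but consistent LC-MS/MS units."""

    accession: str
    a_corona: float
    a_biofluid: float
    biofluid: str = "other"

    def __post_init__(self) -> None:
        if self.a_corona < 0 or self.a_biofluid < 0:
            raise ValueError(
                f"{self.accession}: abundances must be nonnegative "
                f"(a_corona={self.a_corona}, a_biofluid={self.a_biofluid})"
            )

    @property
    def enriched(self) -> bool:
        """Strictly more abundant on the nanoparticle than in the control."""
        return self.a_corona > self.a_biofluid


@dataclass
class ResidueExposure:
    """Solvent accessibility of one residue (1-based position)."""

    position: int
    residue: str
    rsa: float
    asa: float
    exposed: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.rsa <= 1.0:
            raise ValueError(
                f"position {self.position}: RSA {self.rsa} outside [0, 1]"
            )
        if self.asa < 0:
            raise ValueError(f"position {self.position}: negative ASA")


def _parse_header(record: SeqRecord) -> tuple[str, str | None]:
    """Accession and name from a FASTA header.

    UniProt-style ``db|ACC|NAME`` headers yield (ACC, NAME); otherwise the
    first whitespace-delimited token is the accession.
    """
    token = record.id
    parts = token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1], parts[2] or None
    return token, None


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Sequences are upper-cased and trailing ``*`` stop codons stripped.
    Raises ``ValueError`` on an empty file, a duplicate accession, or a
    residue letter outside the 20 standard codes plus X/B/Z/U/O.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession, name = _parse_header(entry)
        if accession in seen:
            raise ValueError(f"duplicate accession in FASTA: {accession}")
        seen.add(accession)
        sequence = str(entry.seq).upper().rstrip("*")
        records.append(ProteinRecord(accession=accession, sequence=sequence,
                                     name=name))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, reconstructing UniProt-style headers where a
    name is present."""
    entries = []
    for rec in records:
        header = f"sp|{rec.accession}|{rec.name}" if rec.name else rec.accession
        entries.append(SeqRecord(Seq(rec.sequence), id=header, description=""))
    SeqIO.write(entries, str(path), "fasta")


@dataclass(frozen=True)
class AbundanceDialect:
    """Column naming for an abundance table (header tokens configurable)."""

    accession: str = "accession"
    a_corona: str = "a_corona"
    a_biofluid: str = "a_biofluid"
    biofluid: str = "biofluid"
    sep: str | None = None  # None: sniff comma/tab


def read_abundance_table(
    path: str | Path, dialect: AbundanceDialect = AbundanceDialect()
) -> list[AbundanceRecord]:
    """Parse a delimited abundance table into records, order-preserving.

    Missing abundance cells are treated as 0 (protein not detected in that
    sample, the usual label-free convention).  Negative abundances and
    missing required columns raise ``ValueError``.
    """
    df = pd.read_csv(path, sep=dialect.sep, engine="python")
    required = [dialect.accession, dialect.a_corona, dialect.a_biofluid]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"abundance table {path} lacks required column(s) {missing}; "
            f"expected {required}"
        )
    has_fluid = dialect.biofluid in df.columns
    records = []
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        a_c = row_d[dialect.a_corona]
        a_b = row_d[dialect.a_biofluid]
        a_c = 0.0 if pd.isna(a_c) else float(a_c)
        a_b = 0.0 if pd.isna(a_b) else float(a_b)
        if a_c < 0 or a_b < 0:
            raise ValueError(
                f"negative abundance for {row_d[dialect.accession]}"
            )
        fluid = str(row_d[dialect.biofluid]) if has_fluid else "other"
        records.append(
            AbundanceRecord(
                accession=str(row_d[dialect.accession]),
                a_corona=a_c,
                a_biofluid=a_b,
                biofluid=fluid if fluid in BIOFLUIDS else "other",
            )
        )
    return records


def write_abundance_table(
    records: Iterable[AbundanceRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "accession": r.accession,
                "a_corona": r.a_corona,
                "a_biofluid": r.a_biofluid,
                "biofluid": r.biofluid,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


@dataclass(frozen=True)
class NetSurfPDialect:
    """Header tokens of a NetSurfP 2.0 CSV export."""

    id: str = "id"
    seq: str = "seq"
    n: str = "n"
    rsa: str = "rsa"
    asa: str = "asa"


def read_netsurfp(
    path: str | Path,
    dialect: NetSurfPDialect = NetSurfPDialect(),
    rsa_cutoff: float = 0.25,
) -> dict[str, list[ResidueExposure]]:
    """Read a NetSurfP 2.0 CSV export into per-accession residue exposures.

    Residues are grouped per accession and ordered by position; the
    ``exposed`` flag is set at *rsa_cutoff* (inclusive).  Raises
    ``ValueError`` when positions are not contiguous from 1 or an RSA value
    falls outside [0, 1].
    """
    # deferred import: solvent_exposure consumes this module's types
    from .solvent_exposure import classify_exposure

    df = pd.read_csv(path, sep=dialect.__dict__.get("sep", None) or ",",
                     skipinitialspace=True)
    required = [dialect.id, dialect.seq, dialect.n, dialect.rsa, dialect.asa]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"NetSurfP export {path} lacks column(s) {missing}; "
            f"expected {required}"
        )
    if df.empty:
        logger.warning("NetSurfP export %s has an empty body", path)
        return {}
    out: dict[str, list[ResidueExposure]] = {}
    for acc, group in df.groupby(dialect.id, sort=False):
        group = group.sort_values(dialect.n)
        positions = group[dialect.n].to_numpy()
        if list(positions) != list(range(1, len(positions) + 1)):
            raise ValueError(
                f"{acc}: residue positions not contiguous from 1"
            )
        residues = [
            ResidueExposure(
                position=int(r[dialect.n]),
                residue=str(r[dialect.seq]).upper(),
                rsa=float(r[dialect.rsa]),
                asa=float(r[dialect.asa]),
            )
            for r in group.to_dict("records")
        ]
        out[str(acc)] = classify_exposure(residues, rsa_cutoff=rsa_cutoff)
    return out


def write_netsurfp(
    exposures: dict[str, Sequence[ResidueExposure]], path: str | Path
) -> None:
    """Write per-residue exposures in the NetSurfP 2.0 CSV layout."""
    rows = [
        {"id": acc, "seq": r.residue, "n": r.position,
         "rsa": r.rsa, "asa": r.asa}
        for acc, residues in exposures.items()
        for r in residues
    ]
    pd.DataFrame(rows, columns=["id", "seq", "n", "rsa", "asa"]).to_csv(
        path, index=False
    )
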