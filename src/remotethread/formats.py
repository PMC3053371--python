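"""Readers and writers for every artifact the pipeline touches.

All coordinates are 0-based half-open in memory and 1-based inclusive in
written reports; both conventions are stated in file headers.  Readers are
strict: malformed rows raise :class:`FormatError` naming the offending line,
never silently truncate.

The profile database lives in a documented flat text format native to this
package (one header line plus ``length`` rows of 20 tab-separated per-residue
log-odds scores).  It is deliberately not a binary profile format so that
fixtures round-trip as plain text.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: Canonical residue ordering used by every per-position score table.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Mask / unknown token.  Anything outside ALPHABET normalizes to X on read.
MASK = "X"

_ALPHABET_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Human-readable tags for cross-species validation levels (0-3 species).
LEVEL_TAGS = {0: "unvalidated", 1: "1-species", 2: "2-species", 3: "3-species"}
_TAG_LEVELS = {v: k for k, v in LEVEL_TAGS.items()}
NO_DATA_TAG = "no-validation-data"

REPORT_VERSION = "remotethread-report/1"


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


def residue_index(residues: str) -> np.ndarray:
    """Map a residue string to integer indices into ALPHABET; X (and any
    other non-standard letter) maps to -1, meaning "scores as zero"."""
    return np.array([_ALPHABET_INDEX.get(c, -1) for c in residues], dtype=np.int64)


# ---------------------------------------------------------------------------
# sequences


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence over the 20 standard residues plus X."""

    id: str
    residues: str
    description: str = ""
    warning: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str, record_id: str = "?") -> str:
    """Uppercase, drop a terminal stop, and map non-standard letters to X."""
    s = raw.upper().rstrip("*")
    out = []
    replaced = 0
    for c in s:
        if c in _ALPHABET_INDEX or c == MASK:
            out.append(c)
        else:
            out.append(MASK)
            replaced += 1
    if replaced:
        logger.warning(
            "record %s: replaced %d non-standard residue(s) with %s",
            record_id, replaced, MASK,
        )
    return "".join(out)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Records come back in file order; ids must be unique within the file.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        residues = normalize_residues(str(rec.seq), rec.id)
        if not residues:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    if not records:
        raise FormatError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# domain profiles


@dataclass
class DomainProfile:
    """Per-position log-odds scoring profile for one conserved-domain family.

    ``match_scores`` has one row per match position and one column per residue
    in :data:`ALPHABET` (bits, log2 odds against the background).
    ``calibration`` is the extreme-value (location, lambda) pair used to turn
    a bit score into an E-value: ``E = db_size * exp(-lambda * (S - mu))``.
    """

    accession: str
    name: str
    length: int
    match_scores: np.ndarray
    clan: Optional[str] = None
    calibration: Optional[tuple[float, float]] = None
    db_version: str = "v1"

    def __post_init__(self):
        self.match_scores = np.asarray(self.match_scores, dtype=float)
        if self.length <= 0:
            raise FormatError(f"profile {self.accession}: non-positive length")
        if self.match_scores.shape != (self.length, len(ALPHABET)):
            raise FormatError(
                f"profile {self.accession}: match_scores shape "
                f"{self.match_scores.shape} != ({self.length}, {len(ALPHABET)})"
            )
        if self.calibration is not None:
            mu, lam = self.calibration
            if not (lam > 0 and math.isfinite(mu)):
                raise FormatError(
                    f"profile {self.accession}: calibration scale must be > 0"
                )

    @property
    def calibrated(self) -> bool:
        return self.calibration is not None

    def consensus(self) -> str:
        """Highest-scoring residue at each match position."""
        return "".join(ALPHABET[i] for i in np.argmax(self.match_scores, axis=1))


def write_profiles(profiles: Iterable[DomainProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("# remotethread profile db v1\n")
        fh.write(f"# columns: {' '.join(ALPHABET)} (bits)\n")
        for p in profiles:
            cal = ""
            if p.calibration is not None:
                cal = f" mu={p.calibration[0]:.10g} lambda={p.calibration[1]:.10g}"
            clan = f" clan={p.clan}" if p.clan else ""
            fh.write(
                f">{p.accession} name={p.name}{clan} length={p.length}"
                f"{cal} db_version={p.db_version}\n"
            )
            for row in p.match_scores:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def read_profiles(path) -> list[DomainProfile]:
    profiles: list[DomainProfile] = []
    header: Optional[dict] = None
    rows: list[list[float]] = []

    def flush(lineno: int):
        nonlocal header, rows
        if header is None:
            return
        length = header["length"]
        if len(rows) != length:
            raise FormatError(
                f"{path}:{lineno}: profile {header['accession']} declares "
                f"length {length} but has {len(rows)} score rows"
            )
        profiles.append(
            DomainProfile(
                accession=header["accession"],
                name=header["name"],
                clan=header.get("clan"),
                length=length,
                match_scores=np.array(rows),
                calibration=header.get("calibration"),
                db_version=header.get("db_version", "v1"),
            )
        )
        header, rows = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush(lineno)
                fields = line[1:].split()
                if not fields:
                    raise FormatError(f"{path}:{lineno}: empty profile header")
                meta = {"accession": fields[0], "name": fields[0]}
                kv = {}
                for tok in fields[1:]:
                    if "=" not in tok:
                        raise FormatError(
                            f"{path}:{lineno}: malformed header token {tok!r}"
                        )
                    k, v = tok.split("=", 1)
                    kv[k] = v
                meta["name"] = kv.get("name", meta["name"])
                if "clan" in kv:
                    meta["clan"] = kv["clan"]
                try:
                    meta["length"] = int(kv["length"])
                except (KeyError, ValueError):
                    raise FormatError(
                        f"{path}:{lineno}: profile header lacks a valid length="
                    ) from None
                if "mu" in kv and "lambda" in kv:
                    meta["calibration"] = (float(kv["mu"]), float(kv["lambda"]))
                meta["db_version"] = kv.get("db_version", "v1")
                header = meta
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: score row before header")
                vals = line.split("\t")
                if len(vals) != len(ALPHABET):
                    raise FormatError(
                        f"{path}:{lineno}: expected {len(ALPHABET)} scores, "
                        f"got {len(vals)}"
                    )
                rows.append([float(v) for v in vals])
        flush(lineno="EOF")
    if not profiles:
        raise FormatError(f"{path}: no profiles")
    return profiles


# ---------------------------------------------------------------------------
# structure library / maps


@dataclass(frozen=True)
class StructureEntry:
    structure_id: str
    fold_class: str
    length: int

    def __post_init__(self):
        if self.length <= 0:
            raise FormatError(f"structure {self.structure_id}: non-positive length")


def write_structure_manifest(entries: Iterable[StructureEntry], path) -> None:
    with open(path, "w") as fh:
        fh.write("# structure_id\tfold_class\tlength\n")
        for e in entries:
            fh.write(f"{e.structure_id}\t{e.fold_class}\t{e.length}\n")


def read_structure_manifest(path) -> list[StructureEntry]:
    entries: list[StructureEntry] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            sid, fold, length = parts
            if sid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate structure_id {sid!r}")
            seen.add(sid)
            try:
                entries.append(StructureEntry(sid, fold, int(length)))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad length {length!r}") from None
    if not entries:
        raise FormatError(f"{path}: no structures")
    return entries


StructureMap = dict  # profile accession -> set of structure_ids


def read_structure_map(path, library: Sequence[StructureEntry]) -> dict[str, set[str]]:
    """Read the domain-to-structure mapping (PDBMAP-style two-column table).

    Rows referencing structures absent from ``library`` are rejected with an
    error listing the offending lines; duplicate pairs deduplicate silently.
    """
    known = {e.structure_id for e in library}
    mapping: dict[str, set[str]] = {}
    bad: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            acc, sid = parts
            if sid not in known:
                bad.append(f"line {lineno}: unknown structure {sid!r}")
                continue
            mapping.setdefault(acc, set()).add(sid)
    if bad:
        raise FormatError(f"{path}: rows reference unknown structures: " + "; ".join(bad))
    return mapping


def write_structure_map(mapping: Mapping[str, set], path) -> None:
    with open(path, "w") as fh:
        fh.write("# profile_accession\tstructure_id\n")
        for acc in sorted(mapping):
            for sid in sorted(mapping[acc]):
                fh.write(f"{acc}\t{sid}\n")


def read_clan_map(path) -> dict[str, str]:
    clans: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            clans[parts[0]] = parts[1]
    return clans


def write_clan_map(clans: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("# profile_accession\tclan\n")
        for acc in sorted(clans):
            fh.write(f"{acc}\t{clans[acc]}\n")


# ---------------------------------------------------------------------------
# ortholog tables / essential residues / background samples


def read_ortholog_table(path) -> dict[str, dict[str, str]]:
    """(query protein id) -> {species_tag -> ortholog fasta id}."""
    table: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            query, species, oid = parts
            per = table.setdefault(query, {})
            if species in per:
                raise FormatError(
                    f"{path}:{lineno}: duplicate species {species!r} for {query!r}"
                )
            per[species] = oid
    return table


def write_ortholog_table(table: Mapping[str, Mapping[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("# query_protein_id\tspecies_tag\tortholog_fasta_id\n")
        for query in sorted(table):
            for species in sorted(table[query]):
                fh.write(f"{query}\t{species}\t{table[query][species]}\n")


def read_essential_residues(path) -> dict[str, list[tuple[int, str]]]:
    """Profile accession -> [(0-based consensus position, expected residue)].

    Positions are 1-based in the file, 0-based in memory.
    """
    out: dict[str, list[tuple[int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            acc, pos, res = parts
            try:
                pos1 = int(pos)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad position {pos!r}") from None
            if pos1 < 1 or len(res) != 1:
                raise FormatError(f"{path}:{lineno}: bad essential-residue row")
            out.setdefault(acc, []).append((pos1 - 1, res))
    return out


def write_essential_residues(ess: Mapping[str, list], path) -> None:
    with open(path, "w") as fh:
        fh.write("# profile_accession\tconsensus_position(1-based)\texpected_residue\n")
        for acc in sorted(ess):
            for pos0, res in ess[acc]:
                fh.write(f"{acc}\t{pos0 + 1}\t{res}\n")


def read_background_zscores(path) -> np.ndarray:
    vals: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                vals.append(float(line))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad value {line!r}") from None
    if not vals:
        raise FormatError(f"{path}: no values")
    return np.array(vals)


def write_background_zscores(values: np.ndarray, path, source: str = "synthetic") -> None:
    values = np.asarray(values)
    with open(path, "w") as fh:
        fh.write(f"# background z-scores source={source} count={values.size}\n")
        for v in values:
            fh.write(f"{v:.6f}\n")


# ---------------------------------------------------------------------------
# scored-call reports

_REPORT_COLUMNS = [
    "protein_id",
    "profile_accession",
    "start",          # 1-based inclusive
    "end",            # 1-based inclusive
    "evalue",
    "tier",
    "p_cdf",
    "p_hyper",
    "p_combined",
    "validation",
    "short_domain",
]


@dataclass(frozen=True)
class ReportRow:
    """One scored domain call as it appears in a written report."""

    protein_id: str
    profile_accession: str
    start: int  # 0-based half-open internally
    end: int
    evalue: float
    tier: str
    p_cdf: Optional[float] = None
    p_hyper: Optional[float] = None
    p_combined: Optional[float] = None
    validation_level: Optional[int] = None
    no_validation_data: bool = False
    short_domain: bool = False


def _validation_tag(row: ReportRow) -> str:
    if row.validation_level is None:
        return "-"
    if row.no_validation_data:
        return NO_DATA_TAG
    return LEVEL_TAGS[row.validation_level]


def write_hits_report(rows: Sequence[ReportRow], path) -> None:
    """Write the tab-separated report plus a JSON twin with identical content.

    Coordinates in the files are 1-based inclusive; the header says so.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {REPORT_VERSION}\n")
        fh.write("# coordinates: 1-based inclusive\n")
        fh.write("# " + "\t".join(_REPORT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.protein_id,
                        r.profile_accession,
                        str(r.start + 1),
                        str(r.end),
                        f"{r.evalue:.6g}",
                        r.tier,
                        "-" if r.p_cdf is None else f"{r.p_cdf:.6g}",
                        "-" if r.p_hyper is None else f"{r.p_hyper:.6g}",
                        "-" if r.p_combined is None else f"{r.p_combined:.6g}",
                        _validation_tag(r),
                        "yes" if r.short_domain else "no",
                    ]
                )
                + "\n"
            )
    twin = {
        "version": REPORT_VERSION,
        "coordinates": "1-based inclusive",
        "calls": [
            {
                "protein_id": r.protein_id,
                "profile_accession": r.profile_accession,
                "start": r.start + 1,
                "end": r.end,
                "evalue": r.evalue,
                "tier": r.tier,
                "p_cdf": r.p_cdf,
                "p_hyper": r.p_hyper,
                "p_combined": r.p_combined,
                "validation": _validation_tag(r),
                "short_domain": r.short_domain,
            }
            for r in rows
        ],
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(twin, fh, indent=1)


def parse_hits_report(path) -> list[ReportRow]:
    rows: list[ReportRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(_REPORT_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_REPORT_COLUMNS)} columns"
                )
            (pid, acc, start, end, ev, tier, pc, ph, pcomb, val, short) = parts
            if val == "-":
                level, nodata = None, False
            elif val == NO_DATA_TAG:
                level, nodata = 0, True
            else:
                level, nodata = _TAG_LEVELS[val], False
            rows.append(
                ReportRow(
                    protein_id=pid,
                    profile_accession=acc,
                    start=int(start) - 1,
                    end=int(end),
                    evalue=float(ev),
                    tier=tier,
                    p_cdf=None if pc == "-" else float(pc),
                    p_hyper=None if ph == "-" else float(ph),
                    p_combined=None if pcomb == "-" else float(pcomb),
                    validation_level=level,
                    no_validation_data=nodata,
                    short_domain=(short == "yes"),
                )
            )
    return rows
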