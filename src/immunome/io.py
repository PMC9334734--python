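"""Readers and writers for the external formats the pipeline consumes.

Supported formats: InterProScan 5 tabular TSV, OrthoFinder ``Orthogroups.tsv``,
protein FASTA, BLAST tabular (outfmt 6), and a two-column protein->gene map.
All readers transparently accept gzip-compressed input (``.gz`` suffix).

Coordinates are 1-based and inclusive throughout, following the InterProScan
convention; they are converted to Python half-open slices only inside
sequence-slicing code and never exposed.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_IPR_RE = re.compile(r"^IPR\d{6}$")


class ParseError(ValueError):
    """A malformed input file; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path or '<input>'}" + (f":{line}" if line else "")
        super().__init__(f"{loc}: {message}")
        self.path = path
        self.line = line


class UnmappedProteinError(KeyError):
    """A protein id queried against a GeneMap that does not contain it."""


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainHit:
    """One signature match on one protein (1-based inclusive coordinates)."""

    protein_id: str
    analysis: str
    signature_acc: str
    signature_desc: str = ""
    start: int = 1
    stop: int = 1
    score: float | None = None
    interpro_acc: str | None = None
    interpro_desc: str | None = None

    def __post_init__(self):
        if not self.signature_acc:
            raise ValueError("signature_acc must be non-empty")
        if not (1 <= self.start <= self.stop):
            raise ValueError(
                f"bad coordinates {self.start}-{self.stop} on {self.protein_id}"
            )
        if self.interpro_acc is not None and not _IPR_RE.match(self.interpro_acc):
            raise ValueError(f"malformed InterPro accession {self.interpro_acc!r}")

    @property
    def accessions(self) -> frozenset[str]:
        """All namespaces under which this hit is addressable.

        A hit is matchable by its member-database accession, its InterPro
        accession when present, and -- for PANTHER subfamily ids such as
        ``PTHR10887:SF470`` -- also the family prefix ``PTHR10887``.
        """
        accs = {self.signature_acc}
        if self.interpro_acc:
            accs.add(self.interpro_acc)
        if self.signature_acc.startswith("PTHR") and ":" in self.signature_acc:
            accs.add(self.signature_acc.split(":", 1)[0])
        return frozenset(accs)


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    gene_id: str = ""
    length: int = 0
    sequence: str | None = None

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"{self.protein_id}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"{self.protein_id}: sequence/length mismatch")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent identity outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("negative e-value")


class GeneMap:
    """Protein -> gene mapping with per-gene ordered isoform lists.

    Isoforms are ordered by descending length when lengths are known,
    otherwise lexicographically; the ordering is deterministic either way.
    """

    def __init__(
        self,
        protein_to_gene: dict[str, str],
        lengths: dict[str, int] | None = None,
    ):
        self._p2g = dict(protein_to_gene)
        self._lengths = dict(lengths or {})
        self._g2p: dict[str, list[str]] = {}
        for pid, gid in self._p2g.items():
            self._g2p.setdefault(gid, []).append(pid)
        for gid, pids in self._g2p.items():
            if self._lengths:
                pids.sort(key=lambda p: (-self._lengths.get(p, 0), p))
            else:
                pids.sort()

    def gene_of(self, protein_id: str) -> str:
        try:
            return self._p2g[protein_id]
        except KeyError:
            raise UnmappedProteinError(protein_id) from None

    def get(self, protein_id: str) -> str | None:
        return self._p2g.get(protein_id)

    def isoforms(self, gene_id: str) -> list[str]:
        return list(self._g2p.get(gene_id, []))

    @property
    def genes(self) -> list[str]:
        return sorted(self._g2p)

    @property
    def proteins(self) -> list[str]:
        return sorted(self._p2g)

    def __len__(self) -> int:
        return len(self._p2g)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._p2g


class OrthogroupTable:
    """Orthogroup id -> per-species gene-id lists (possibly empty)."""

    def __init__(self, species: list[str], rows: dict[str, dict[str, list[str]]]):
        self.species = list(species)
        self.rows = {}
        seen: dict[str, str] = {}
        for og_id, cells in rows.items():
            row = {sp: list(cells.get(sp, [])) for sp in self.species}
            for sp, ids in row.items():
                for gid in ids:
                    if gid in seen:
                        raise ValueError(
                            f"id {gid!r} appears in both {seen[gid]} and {og_id}"
                        )
                    seen[gid] = og_id
            self.rows[og_id] = row
        self._member_index = seen

    def members(self, og_id: str, species: str | None = None) -> list[str]:
        row = self.rows[og_id]
        if species is not None:
            return list(row[species])
        return [gid for sp in self.species for gid in row[sp]]

    def orthogroup_of(self, member_id: str) -> str | None:
        return self._member_index.get(member_id)

    def species_present(self, og_id: str) -> frozenset[str]:
        return frozenset(sp for sp, ids in self.rows[og_id].items() if ids)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[str]:
        return iter(self.rows)


# ---------------------------------------------------------------------------
# InterProScan tabular
# ---------------------------------------------------------------------------

def _parse_optional(value: str | None) -> str | None:
    if value is None:
        return None
    value = value.strip()
    return value if value and value != "-" else None


def parse_interproscan_tsv(path) -> tuple[list[DomainHit], dict[str, ProteinRecord]]:
    """Parse InterProScan 5 tabular output.

    Returns the list of domain hits and one sequence-less ProteinRecord per
    protein (lengths taken from column 3 and consistency-checked across rows).
    Rows may have 11-15 columns: the 11 mandatory columns, then optional
    InterPro accession, InterPro description, GO terms and pathways. Extra
    trailing columns are tolerated with a warning (InterProScan versions
    differ in column count).
    """
    hits: list[DomainHit] = []
    lengths: dict[str, int] = {}
    warned_extra = False
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise ParseError(
                    f"expected >= 11 tab-separated columns, got {len(cols)}",
                    path, lineno,
                )
            if len(cols) > 15 and not warned_extra:
                logger.warning(
                    "%s:%d: %d columns; ignoring columns beyond 15",
                    path, lineno, len(cols),
                )
                warned_extra = True
            pid, _md5, length_s, analysis, sig_acc, sig_desc, start_s, stop_s, score_s = (
                cols[0], cols[1], cols[2], cols[3], cols[4], cols[5],
                cols[6], cols[7], cols[8],
            )
            try:
                length = int(length_s)
                start = int(start_s)
                stop = int(stop_s)
            except ValueError:
                raise ParseError(
                    f"non-integer length/coordinates {length_s!r}/{start_s!r}/{stop_s!r}",
                    path, lineno,
                ) from None
            if start > stop:
                raise ParseError(f"start {start} > stop {stop}", path, lineno)
            score_raw = _parse_optional(score_s)
            try:
                score = float(score_raw) if score_raw is not None else None
            except ValueError:
                raise ParseError(f"malformed score {score_s!r}", path, lineno) from None
            ipr_acc = _parse_optional(cols[11]) if len(cols) > 11 else None
            ipr_desc = _parse_optional(cols[12]) if len(cols) > 12 else None
            prev = lengths.setdefault(pid, length)
            if prev != length:
                raise ValueError(
                    f"{path}: conflicting lengths for {pid}: {prev} vs {length} "
                    f"(line {lineno})"
                )
            if stop > length:
                raise ParseError(
                    f"stop {stop} exceeds protein length {length} for {pid}",
                    path, lineno,
                )
            try:
                hits.append(DomainHit(
                    protein_id=pid, analysis=analysis, signature_acc=sig_acc,
                    signature_desc=sig_desc, start=start, stop=stop,
                    score=score, interpro_acc=ipr_acc, interpro_desc=ipr_desc,
                ))
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from None
    records = {pid: ProteinRecord(pid, length=ln) for pid, ln in lengths.items()}
    return hits, records


def write_interproscan_tsv(hits: Iterable[DomainHit], lengths: dict[str, int], path) -> None:
    """Write hits back out in the 13-column InterProScan tabular dialect."""
    with _open_text(path, "wt") as fh:
        for h in hits:
            ipr = h.interpro_acc or "-"
            ipr_d = h.interpro_desc or "-"
            score = "-" if h.score is None else repr(h.score)
            fh.write("\t".join([
                h.protein_id, "md5", str(lengths[h.protein_id]), h.analysis,
                h.signature_acc, h.signature_desc, str(h.start), str(h.stop),
                score, "T", "01-01-2022", ipr, ipr_d,
            ]) + "\n")


def hits_by_protein(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    """Group hits per protein with a deterministic within-protein order."""
    grouped: dict[str, list[DomainHit]] = {}
    for h in hits:
        grouped.setdefault(h.protein_id, []).append(h)
    for pid in grouped:
        grouped[pid].sort(key=lambda h: (h.start, h.stop, h.signature_acc))
    return grouped


# ---------------------------------------------------------------------------
# OrthoFinder Orthogroups.tsv
# ---------------------------------------------------------------------------

def parse_orthogroups(path) -> OrthogroupTable:
    """Parse an OrthoFinder ``Orthogroups.tsv``-style table.

    First row is a header (``Orthogroup`` + species names); cells contain
    comma-separated member ids. Duplicate orthogroup ids and ragged rows are
    hard errors.
    """
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError("empty orthogroup table", path, 1)
        species = [s.strip() for s in header.split("\t")[1:]]
        if not species:
            raise ParseError("header declares no species columns", path, 1)
        rows: dict[str, dict[str, list[str]]] = {}
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != len(species) + 1:
                raise ParseError(
                    f"ragged row: {len(cols)} columns, expected {len(species) + 1}",
                    path, lineno,
                )
            og_id = cols[0].strip()
            if og_id in rows:
                raise ParseError(f"duplicate orthogroup id {og_id!r}", path, lineno)
            rows[og_id] = {
                sp: [g.strip() for g in cell.split(",") if g.strip()]
                for sp, cell in zip(species, cols[1:])
            }
    return OrthogroupTable(species, rows)


def write_orthogroups(table: OrthogroupTable, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.species) + "\n")
        for og_id in sorted(table.rows):
            cells = [", ".join(table.rows[og_id][sp]) for sp in table.species]
            fh.write(og_id + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(path, gene_map: GeneMap | None = None) -> dict[str, ProteinRecord]:
    """Read a protein FASTA into ProteinRecords (id = first header token).

    Sequences are upper-cased and terminal ``*`` stop symbols stripped;
    lengths are recomputed from the cleaned sequence.
    """
    records: dict[str, ProteinRecord] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            pid = rec.id
            if pid in records:
                raise ValueError(f"{path}: duplicate FASTA id {pid!r}")
            seq = str(rec.seq).upper().strip("*")
            if not seq:
                raise ValueError(f"{path}: empty sequence for {pid!r}")
            gid = gene_map.get(pid) if gene_map else None
            records[pid] = ProteinRecord(pid, gene_id=gid or "", length=len(seq),
                                         sequence=seq)
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    seqs = []
    for r in records:
        if r.sequence is None:
            raise ValueError(f"{r.protein_id}: no sequence to write")
        seqs.append(SeqRecord(Seq(r.sequence), id=r.protein_id, description=""))
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# gene map
# ---------------------------------------------------------------------------

def load_gene_map(path, lengths: dict[str, int] | None = None) -> GeneMap:
    """Load a two-column TSV (protein_id, gene_id)."""
    p2g: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = [c.strip() for c in line.split("\t")]
            if len(cols) < 2:
                raise ParseError("expected two tab-separated columns", path, lineno)
            pid, gid = cols[0], cols[1]
            if pid in p2g and p2g[pid] != gid:
                raise ValueError(
                    f"{path}: protein {pid!r} mapped to two genes "
                    f"({p2g[pid]!r}, {gid!r}) at line {lineno}"
                )
            p2g[pid] = gid
    return GeneMap(p2g, lengths)


def write_gene_map(gene_map: GeneMap, path) -> None:
    with _open_text(path, "wt") as fh:
        for gid in gene_map.genes:
            for pid in gene_map.isoforms(gid):
                fh.write(f"{pid}\t{gid}\n")


# ---------------------------------------------------------------------------
# BLAST outfmt 6
# ---------------------------------------------------------------------------

def parse_homology_hits(path) -> list[HomologyHit]:
    """Parse 12-column BLAST tabular (outfmt 6) homology hits."""
    hits: list[HomologyHit] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(
                    f"expected 12 columns (outfmt 6), got {len(cols)}", path, lineno
                )
            try:
                hits.append(HomologyHit(
                    query_id=cols[0].strip(),
                    subject_id=cols[1].strip(),
                    percent_identity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                ))
            except ValueError as exc:
                raise ParseError(f"malformed numeric field: {exc}", path, lineno) from None
    return hits


def best_hit_per_query(hits: Iterable[HomologyHit]) -> dict[str, HomologyHit]:
    """Best hit per query: lowest e-value, ties broken by highest bitscore."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, -h.bitscore) < (cur.evalue, -cur.bitscore):
            best[h.query_id] = h
    return best
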