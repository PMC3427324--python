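"""Readers and writers for the external formats the pipeline touches.

Covers FASTA (nucleotide and amino acid), 12-column tab-separated similarity
hit tables (the tabular dialect emitted by translated BLAST searches),
relaxed sequential PHYLIP, NEXUS with per-block charsets, RAxML-style
partition files, Newick chronograms, an INI config file, and the TSV audit
log that records every filter decision.

Coordinate convention: every file format here is 1-based inclusive; all
internal interval arithmetic is 0-based half-open.  :func:`to_file_interval`
and :func:`from_file_interval` are the two converters and compose to the
identity.
"""

from __future__ import annotations

import configparser
import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

logger = logging.getLogger("opilio")

NT_CANONICAL = set("ACGTN-?")
# IUPAC ambiguity codes other than N are normalized to N on input.
NT_AMBIGUOUS = set("RYSWKMBDHV")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX?-*")


class FormatError(ValueError):
    """Malformed input file."""


class AlphabetError(FormatError):
    """Residue outside the declared alphabet."""


class DuplicateIdError(FormatError):
    """Two records in one file share an identifier."""


class Alphabet(enum.Enum):
    nt = "nt"
    aa = "aa"


@dataclass
class SequenceRecord:
    """One named sequence, nucleotide or amino acid.

    ``taxon`` is a free label (the source transcriptome); transcript
    identifiers are conventionally ``taxon|tNNNNN`` so the taxon survives
    round-trips through headers that carry only the identifier.
    """

    identifier: str
    residues: str
    alphabet: Alphabet = Alphabet.nt
    taxon: str = ""
    is_super_transcript: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError(f"{self.identifier}: empty sequence")
        if any(c.isspace() for c in self.identifier):
            raise FormatError(f"identifier contains whitespace: {self.identifier!r}")
        if not self.taxon and "|" in self.identifier:
            self.taxon = self.identifier.split("|", 1)[0]
        allowed = NT_CANONICAL if self.alphabet is Alphabet.nt else AA_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise AlphabetError(
                f"{self.identifier}: illegal {self.alphabet.value} residue(s) "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# interval conversion

def to_file_interval(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


def from_file_interval(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# FASTA

def _normalize_nt(seq: str, identifier: str) -> str:
    up = seq.upper()
    amb = set(up) & NT_AMBIGUOUS
    if amb:
        logger.warning(
            "%s: IUPAC ambiguity code(s) %s normalized to N", identifier, sorted(amb)
        )
        up = "".join("N" if c in NT_AMBIGUOUS else c for c in up)
    return up


def read_fasta(path: str | Path, alphabet: Alphabet = Alphabet.nt,
               taxon: str = "") -> list[SequenceRecord]:
    """Parse a FASTA file into validated records.

    Sequences are upper-cased and whitespace-stripped; nucleotide ambiguity
    codes other than N are normalized to N with a logged warning.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}:{header_line}: record {header!r} has no sequence")
        if alphabet is Alphabet.nt:
            seq = _normalize_nt(seq, header)
        else:
            seq = seq.upper()
        bad = set(seq) - (NT_CANONICAL if alphabet is Alphabet.nt else AA_ALPHABET)
        if bad:
            raise AlphabetError(
                f"{path}:{line_no}: record {header!r}: illegal residue(s) {sorted(bad)}"
            )
        if header in seen:
            raise DuplicateIdError(f"{path}: duplicate identifier {header!r}")
        seen.add(header)
        records.append(SequenceRecord(header, seq, alphabet, taxon=taxon))
        header, chunks = None, []

    with open(path) as fh:
        n = 0
        for n, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(n)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FormatError(f"{path}:{n}: empty FASTA header")
                header_line = n
            else:
                if header is None:
                    raise FormatError(f"{path}:{n}: sequence before first header")
                chunks.append(line)
        flush(n)
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# hit tables (12-column outfmt-6 dialect)

@dataclass
class HitRecord:
    """One translated-search local alignment of a reference protein against
    a transcript, in the 12-column tabular dialect.

    Protein-side coordinates (qstart/qend) count amino acids; transcript-side
    coordinates (sstart/send) count nucleotides.  All are 1-based inclusive;
    ``sstart > send`` marks a minus-strand (negative frame) hit.
    """

    query: str
    subject: str
    pident: float
    length: int          # alignment columns (aa)
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    # not serialized: set by the built-in search, recomputed otherwise
    frame: int | None = None
    gap_columns: int = 0

    @property
    def minus(self) -> bool:
        return self.sstart > self.send

    @property
    def taxon(self) -> str:
        return self.subject.split("|", 1)[0]

    @property
    def subject_span(self) -> tuple[int, int]:
        """Plus-strand-normalized 0-based half-open nt interval on the subject."""
        lo, hi = sorted((self.sstart, self.send))
        return from_file_interval(lo, hi)

    @property
    def query_span(self) -> tuple[int, int]:
        """0-based half-open aa interval on the query protein."""
        return from_file_interval(self.qstart, self.qend)

    def to_row(self) -> str:
        return "\t".join([
            self.query, self.subject, f"{self.pident:.1f}", str(self.length),
            str(self.mismatch), str(self.gapopen), str(self.qstart),
            str(self.qend), str(self.sstart), str(self.send),
            f"{self.evalue:.2g}", f"{self.bitscore:.1f}",
        ])


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table, preserving row order."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(f"{path}:{n}: expected 12 columns, got {len(cols)}")
            try:
                h = HitRecord(
                    query=cols[0], subject=cols[1], pident=float(cols[2]),
                    length=int(cols[3]), mismatch=int(cols[4]),
                    gapopen=int(cols[5]), qstart=int(cols[6]), qend=int(cols[7]),
                    sstart=int(cols[8]), send=int(cols[9]),
                    evalue=float(cols[10]), bitscore=float(cols[11]),
                )
                # gap columns reconstructed from the span arithmetic
                gq = h.length - (h.qend - h.qstart + 1)
                gs = h.length - (abs(h.send - h.sstart) + 1) // 3
                h.gap_columns = max(gq, 0) + max(gs, 0)
                hits.append(h)
            except ValueError as exc:
                raise FormatError(f"{path}:{n}: non-numeric field ({exc})") from exc
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(h.to_row() + "\n")


# ---------------------------------------------------------------------------
# partition schemes

@dataclass
class PartitionBlock:
    name: str
    intervals: list[tuple[int, int]]      # 1-based inclusive column ranges
    stride: int | None = None             # codon position 1/2/3, or None


@dataclass
class PartitionScheme:
    """Ordered list of named column blocks jointly tiling 1..L exactly once."""

    blocks: list[PartitionBlock]
    total_columns: int

    def __post_init__(self) -> None:
        counts = [0] * self.total_columns
        for b in self.blocks:
            step = 3 if b.stride else 1
            for (s, e) in b.intervals:
                if not (1 <= s <= e <= self.total_columns):
                    raise ValueError(f"block {b.name}: interval {s}-{e} out of range")
                if b.stride and (s - b.stride) % 3 != 0:
                    raise ValueError(
                        f"block {b.name}: stride-{b.stride} block must start on a "
                        f"codon-position-{b.stride} column"
                    )
                for c in range(s, e + 1, step):
                    counts[c - 1] += 1
        if any(c != 1 for c in counts):
            missing = [i + 1 for i, c in enumerate(counts) if c == 0]
            doubled = [i + 1 for i, c in enumerate(counts) if c > 1]
            raise ValueError(
                f"partition scheme does not tile 1..{self.total_columns}: "
                f"missing={missing[:5]} doubled={doubled[:5]}"
            )

    def columns(self, block: PartitionBlock) -> list[int]:
        step = 3 if block.stride else 1
        out: list[int] = []
        for (s, e) in block.intervals:
            out.extend(range(s, e + 1, step))
        return out


def write_partition_file(scheme: PartitionScheme, path: str | Path,
                         model: str = "DNA") -> None:
    """RAxML-style plain partition file: ``MODEL, name = start-end[\\3]``."""
    with open(path, "w") as fh:
        for b in scheme.blocks:
            parts = []
            for (s, e) in b.intervals:
                parts.append(f"{s}-{e}\\3" if b.stride else f"{s}-{e}")
            fh.write(f"{model}, {b.name} = {', '.join(parts)}\n")


def write_supermatrix(rows: dict[str, str], scheme: "PartitionScheme",
                      base: str | Path, datatype: str = "dna") -> dict[str, Path]:
    """Emit one matrix in all three export formats.

    Writes ``<base>.phy`` (relaxed sequential PHYLIP), ``<base>.nex``
    (NEXUS with a charset per block) and ``<base>.partitions`` (plain
    partition file); returns the paths.  Reading any of them back recovers
    the identical character matrix.
    """
    base = Path(base)
    paths = {"phylip": base.with_suffix(".phy"),
             "nexus": base.with_suffix(".nex"),
             "partitions": base.with_suffix(".partitions")}
    write_phylip(rows, paths["phylip"])
    write_nexus(rows, scheme, paths["nexus"], datatype=datatype)
    write_partition_file(scheme, paths["partitions"],
                         model="DNA" if datatype == "dna" else "PROT")
    return paths


_PART_RE = re.compile(r"^\s*(\S+)\s*,\s*(\S+)\s*=\s*(.+)$")


def read_partition_file(path: str | Path, total_columns: int) -> PartitionScheme:
    blocks: list[PartitionBlock] = []
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            m = _PART_RE.match(line)
            if not m:
                raise FormatError(f"{path}:{n}: unparseable partition line")
            _, name, spec = m.groups()
            intervals: list[tuple[int, int]] = []
            stride: int | None = None
            for token in spec.split(","):
                token = token.strip()
                strided = token.endswith("\\3")
                if strided:
                    token = token[:-2]
                s, _, e = token.partition("-")
                s_i, e_i = int(s), int(e)
                intervals.append((s_i, e_i))
                if strided:
                    stride = (s_i - 1) % 3 + 1
            blocks.append(PartitionBlock(name, intervals, stride))
    return PartitionScheme(blocks, total_columns)


# ---------------------------------------------------------------------------
# PHYLIP / NEXUS

def write_phylip(rows: dict[str, str], path: str | Path) -> None:
    """Relaxed sequential PHYLIP (names of any length, single space sep)."""
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError(f"ragged rows: lengths {sorted(lengths)}")
    ncol = lengths.pop() if lengths else 0
    with open(path, "w") as fh:
        fh.write(f"{len(rows)} {ncol}\n")
        width = max((len(n) for n in rows), default=0)
        for name, seq in rows.items():
            fh.write(f"{name.ljust(width)}  {seq}\n")


def read_phylip(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: bad PHYLIP header")
        ntax, ncol = int(header[0]), int(header[1])
        rows: dict[str, str] = {}
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            rows[name] = seq.strip().replace(" ", "")
    if len(rows) != ntax or any(len(s) != ncol for s in rows.values()):
        raise FormatError(f"{path}: PHYLIP body disagrees with header")
    return rows


def write_nexus(rows: dict[str, str], scheme: PartitionScheme | None,
                path: str | Path, datatype: str = "dna") -> None:
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError(f"ragged rows: lengths {sorted(lengths)}")
    ncol = lengths.pop() if lengths else 0
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nbegin data;\n")
        fh.write(f"  dimensions ntax={len(rows)} nchar={ncol};\n")
        fh.write(f"  format datatype={datatype} gap=- missing=?;\n  matrix\n")
        width = max((len(n) for n in rows), default=0)
        for name, seq in rows.items():
            fh.write(f"    {name.ljust(width)}  {seq}\n")
        fh.write("  ;\nend;\n")
        if scheme is not None:
            fh.write("\nbegin sets;\n")
            for b in scheme.blocks:
                parts = []
                for (s, e) in b.intervals:
                    parts.append(f"{s}-{e}\\3" if b.stride else f"{s}-{e}")
                fh.write(f"  charset {b.name} = {' '.join(parts)};\n")
            fh.write("end;\n")


def read_nexus(path: str | Path) -> dict[str, str]:
    """Read back the character matrix of a NEXUS file written by write_nexus."""
    rows: dict[str, str] = {}
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.lower() == "matrix":
                in_matrix = True
                continue
            if in_matrix:
                if stripped == ";":
                    break
                if stripped:
                    name, seq = stripped.split(None, 1)
                    rows[name] = rows.get(name, "") + seq.replace(" ", "")
    if not rows:
        raise FormatError(f"{path}: no matrix block found")
    return rows


# ---------------------------------------------------------------------------
# Newick

def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a single rooted tree with branch lengths from a file or string."""
    text = Path(source).read_text() if isinstance(source, Path) else str(source)
    if isinstance(source, str) and "\n" not in source and Path(source).exists():
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=False)
    except Exception as exc:
        raise FormatError(f"Newick parse error: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize with canonical child ordering and 10-significant-digit lengths."""
    clone = tree.clone(depth=1)

    def sort_key(nd):
        return min(lf.taxon.label for lf in nd.leaf_iter())

    for nd in clone.preorder_node_iter():
        children = nd.child_nodes()
        if children:
            nd.set_child_nodes(sorted(children, key=sort_key))

    def fmt(nd) -> str:
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon else ""
        else:
            label = "(" + ",".join(fmt(c) for c in nd.child_nodes()) + ")"
            if nd.taxon is not None:
                label += nd.taxon.label
            elif nd.label:
                label += nd.label
        if nd.edge.length is not None:
            label += f":{nd.edge.length:.10g}"
        return label

    return fmt(clone.seed_node) + ";"


# ---------------------------------------------------------------------------
# audit log

@dataclass
class AuditEntry:
    gene: str
    rule: str
    verdict: str
    detail: str = ""


class AuditLog:
    """Machine-readable TSV trail of every filter decision.

    One row per (gene, rule) decision, in decision order; the reproducible
    equivalent of hand-auditing candidate matrices in a spreadsheet.
    """

    def __init__(self) -> None:
        self.entries: list[AuditEntry] = []

    def record(self, gene: str, rule: str, verdict: str, detail: str = "") -> None:
        self.entries.append(AuditEntry(gene, rule, verdict, detail))

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\trule\tverdict\tdetail\n")
            for e in self.entries:
                fh.write(f"{e.gene}\t{e.rule}\t{e.verdict}\t{e.detail}\n")

    def terminal_verdicts(self) -> dict[str, str]:
        """Last verdict recorded per gene."""
        out: dict[str, str] = {}
        for e in self.entries:
            out[e.gene] = e.verdict
        return out


# ---------------------------------------------------------------------------
# config

DEFAULT_CONFIG: dict[str, dict[str, object]] = {
    "filter": {
        "min_overlap_nt": 200,
        "min_region_nt": 300,
        "max_gap_fraction": 0.05,
        "paralog_identity_threshold": 0.98,
        "paralog_min_overlap_nt": 100,
        "reading_frame_excess": 1.5,
        "require_all_taxa": True,
        "prefer_complete": True,
        "max_genes": 300,
        "anchor_taxon": "Siro",
    },
    "search": {
        "k": 4,
        "score_min_bits": 40.0,
        "max_hits": 20,
    },
    "generator": {
        "n_single_copy": 300,
        "n_paralogous": 30,
        "n_contaminant": 20,
        "cds_len_min": 150,
        "cds_len_max": 400,
        "utr_len_min": 20,
        "utr_len_max": 90,
        "frag_prob": 0.2,
        "frag_overlap_min": 30,
        "frag_overlap_max": 90,
        "dup_prob": 0.1,
        "paralog_extra": 0.15,
        "rate_meanlog": -3.6,
        "rate_sdlog": 0.6,
        "n_decoys": 25,
    },
    "tree": {
        "bootstrap_replicates": 500,
        "codon_bootstrap": False,
        "saturation_ceiling": 5.0,
    },
}


def load_config(path: str | Path | None = None) -> dict[str, dict[str, object]]:
    """Load the INI config, falling back to defaults for absent keys."""
    cfg = {sec: dict(vals) for sec, vals in DEFAULT_CONFIG.items()}
    if path is None:
        return cfg
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    for sec in parser.sections():
        cfg.setdefault(sec, {})
        for key, raw in parser[sec].items():
            default = DEFAULT_CONFIG.get(sec, {}).get(key)
            if isinstance(default, bool):
                cfg[sec][key] = raw.strip().lower() in ("1", "true", "yes", "on")
            elif isinstance(default, int):
                cfg[sec][key] = int(raw)
            elif isinstance(default, float):
                cfg[sec][key] = float(raw)
            else:
                cfg[sec][key] = raw
    return cfg


def save_config(cfg: dict[str, dict[str, object]], path: str | Path) -> None:
    parser = configparser.ConfigParser()
    for sec, vals in cfg.items():
        parser[sec] = {k: str(v) for k, v in vals.items()}
    with open(path, "w") as fh:
        parser.write(fh)
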