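"""Per-gene codon-aware alignments and partitioned supermatrices.

Fragmented genes are first merged into "super-transcripts": fragments
hitting the same reference protein are ordered along the reference and
spliced, with the strict requirement that overlapping regions be
nucleotide-identical; reference-implied gaps between adjacent fragments are
filled with '?' (missing), never '-' (gap).

Alignment is reference-anchored: each candidate sequence's conceptual
translation is globally aligned to the reference peptide under BLOSUM62
with a 12:3 gap-open:extension penalty, and the amino-acid alignment is
back-threaded onto nucleotides so every gap is a whole codon triple.
Anchoring on the reference protein (which every candidate matched to get
here) makes the multiple alignment deterministic and codon-exact without a
guide tree.

'?' denotes missing/unknown data and '-' a gap; the supermatrix
"gaps and missing" statistic pools both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner

from .homology_search import BLOSUM62, reverse_complement, six_frame_translate
from .io_formats import (Alphabet, PartitionBlock, PartitionScheme,
                         SequenceRecord, AuditLog)
from .synthetic_data import _CODON_TABLE, STOP_CODONS

#: translation-alignment penalties (gap of length k costs 12 + 3k)
ALN_GAP_OPEN = 12
ALN_GAP_EXTEND = 3


class MergeError(ValueError):
    """Fragments disagree inside an overlap; no super-transcript is formed."""


def _make_global_aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = BLOSUM62
    al.open_gap_score = -(ALN_GAP_OPEN + ALN_GAP_EXTEND)
    al.extend_gap_score = -ALN_GAP_EXTEND
    # do not penalize terminal gaps: candidates are often partial
    al.end_gap_score = 0.0
    return al

_GLOBAL = _make_global_aligner()


# ---------------------------------------------------------------------------
# locating a fragment on the reference

@dataclass
class _Placement:
    ref_start: int      # 0-based codon index on the reference
    ref_end: int        # half-open
    cds: str            # in-frame nucleotides covering [ref_start, ref_end)


_PLACE_K = 4
_REF_INDEX_CACHE: dict[str, dict[str, list[int]]] = {}


def _ref_kmer_index(reference: str) -> dict[str, list[int]]:
    idx = _REF_INDEX_CACHE.get(reference)
    if idx is None:
        idx = {}
        for q in range(len(reference) - _PLACE_K + 1):
            idx.setdefault(reference[q:q + _PLACE_K], []).append(q)
        if len(_REF_INDEX_CACHE) > 64:
            _REF_INDEX_CACHE.clear()
        _REF_INDEX_CACHE[reference] = idx
    return idx


def _place_fragment(fragment: SequenceRecord, reference: str,
                    min_score: int = 40) -> _Placement | None:
    """Diagonal placement of a fragment's translation on the reference.

    Transcript pieces are colinear with the reference protein, so placement
    is an exact ungapped diagonal: shared k-mer seeds nominate (frame,
    diagonal) pairs, each is scored by its best ungapped segment, and the
    winning diagonal is taken over its full extent within both sequences.
    UTR codons map outside the reference span and are clipped off.
    """
    from .homology_search import _encode_pep, _ungapped_diag_score
    idx = _ref_kmer_index(reference)
    rarr = _encode_pep(reference)
    best: tuple[int, int, int, str] | None = None   # score, frame, diag, pep
    for frame, pep in six_frame_translate(fragment):
        if len(pep) < _PLACE_K:
            continue
        diags: set[int] = set()
        for sp in range(len(pep) - _PLACE_K + 1):
            for qp in idx.get(pep[sp:sp + _PLACE_K], ()):
                diags.add(sp - qp)
        if not diags:
            continue
        parr = _encode_pep(pep)
        for d in sorted(diags):
            score = _ungapped_diag_score(rarr, parr, d)
            if best is None or score > best[0]:
                best = (score, frame, d, pep)
    if best is None or best[0] < min_score:
        return None
    _, frame, d, pep = best
    q0 = max(0, -d)
    p0 = q0 + d
    n = min(len(reference) - q0, len(pep) - p0)
    if n <= 0:
        return None
    strand = fragment.residues if frame > 0 else reverse_complement(fragment.residues)
    off = abs(frame) - 1
    nt = strand[off + 3 * p0: off + 3 * (p0 + n)]
    return _Placement(q0, q0 + n, nt)


def extract_cds_estimate(record: SequenceRecord, reference: str
                         ) -> SequenceRecord | None:
    """In-frame coding-region estimate of a transcript against a reference.

    Locates the best translated placement over all six frames and returns
    the in-frame nucleotides covering the placed reference span (UTR flanks
    dropped, minus-strand hits reverse-complemented).  None if the
    transcript does not place.
    """
    pl = _place_fragment(record, reference)
    if pl is None or not pl.cds:
        return None
    rec = SequenceRecord(record.identifier, pl.cds, Alphabet.nt,
                         taxon=record.taxon)
    rec.is_super_transcript = record.is_super_transcript
    return rec


def merge_super_transcript(fragments: list[SequenceRecord], reference: str,
                           identifier: str | None = None) -> SequenceRecord:
    """Merge >= 2 fragments of one gene into a single contiguous sequence.

    Fragments are ordered by reference coordinate; overlapping fragments
    are spliced only if the overlap is nucleotide-identical (else
    :class:`MergeError`); adjacent fragments separated on the reference are
    joined with '?' filling the implied gap.  The result is flagged as a
    super-transcript.
    """
    if len(fragments) < 2:
        raise ValueError("need at least two fragments to merge")
    placements = []
    for fr in fragments:
        pl = _place_fragment(fr, reference)
        if pl is None:
            raise MergeError(f"fragment {fr.identifier} does not place on reference")
        placements.append((pl, fr))
    placements.sort(key=lambda t: (t[0].ref_start, t[0].ref_end))

    cur, _ = placements[0]
    merged = cur.cds
    ref_start, ref_end = cur.ref_start, cur.ref_end
    for pl, fr in placements[1:]:
        if pl.ref_end <= ref_end:       # fully contained
            ov_nt = merged[3 * (pl.ref_start - ref_start):
                           3 * (pl.ref_end - ref_start)]
            if ov_nt != pl.cds:
                raise MergeError(f"{fr.identifier}: contained fragment mismatch")
            continue
        if pl.ref_start <= ref_end:     # overlap
            ov_codons = ref_end - pl.ref_start
            a = merged[len(merged) - 3 * ov_codons:]
            b = pl.cds[:3 * ov_codons]
            if a != b:
                raise MergeError(
                    f"{fr.identifier}: overlap mismatch over {3 * ov_codons} nt")
            merged += pl.cds[3 * ov_codons:]
        else:                           # adjacent/gapped: '?' fill
            merged += "?" * (3 * (pl.ref_start - ref_end)) + pl.cds
        ref_end = pl.ref_end
    rec = SequenceRecord(identifier or fragments[0].identifier + "+merged",
                         merged, Alphabet.nt, taxon=fragments[0].taxon)
    rec.is_super_transcript = True
    return rec


# ---------------------------------------------------------------------------
# gene alignment

@dataclass
class GeneAlignment:
    """One trimmed, codon-aware nucleotide alignment of putative orthologs."""

    gene: str
    rows: dict[str, str]                  # taxon -> aligned nt row
    super_transcript: dict[str, bool] = field(default_factory=dict)
    sources: dict[str, list[str]] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("ragged alignment rows")
        for taxon, row in self.rows.items():
            if row and set(row) <= {"?", "-"}:
                raise ValueError(f"row {taxon} entirely missing")


def _translate_for_alignment(nt: str) -> str:
    """Conceptual translation for anchoring; '?' codons become 'X'."""
    out = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i:i + 3]
        if "?" in codon or "N" in codon:
            out.append("X")
        else:
            out.append(_CODON_TABLE.get(codon, "X"))
    return "".join(out)


def align_gene(gene: str, sequences: dict[str, SequenceRecord],
               reference: str, audit: AuditLog | None = None) -> GeneAlignment:
    """Reference-anchored codon-aware alignment of per-taxon CDS estimates.

    ``sequences`` maps taxon -> in-frame nucleotide sequence (at most one
    per taxon, super-transcripts allowed).  Rows whose translation contains
    an internal stop in the given frame are excluded with an audit entry.
    """
    audit = audit if audit is not None else AuditLog()
    ref_len = len(reference)
    per_taxon: dict[str, tuple[list[str], dict[int, str]]] = {}
    excluded: list[str] = []
    sup: dict[str, bool] = {}
    sources: dict[str, list[str]] = {}

    for taxon in sorted(sequences):
        rec = sequences[taxon]
        nt = rec.residues[:len(rec.residues) - len(rec.residues) % 3]
        pep = _translate_for_alignment(nt)
        if "*" in pep[:-1]:
            audit.record(gene, "align", "row_excluded",
                         f"{taxon}: internal stop in frame")
            excluded.append(taxon)
            continue
        aln = next(iter(_GLOBAL.align(reference, pep)))
        ra, rb = aln.aligned
        # per reference codon position: the taxon's codon (or gap);
        # insertions keyed by the reference position they precede
        codon_at: list[str] = ["---"] * ref_len
        inserts: dict[int, str] = {}
        prev_a = prev_b = None
        for (as_, ae), (bs, be) in zip(ra, rb):
            if prev_a is not None and bs > prev_b:
                # insertion in taxon relative to reference, before ref col as_
                ins = nt[3 * prev_b:3 * bs]
                inserts[as_] = inserts.get(as_, "") + ins
            for r, b in zip(range(as_, ae), range(bs, be)):
                codon_at[r] = nt[3 * b:3 * b + 3]
            prev_a, prev_b = ae, be
        per_taxon[taxon] = (codon_at, inserts)
        sup[taxon] = rec.is_super_transcript
        sources[taxon] = [rec.identifier]

    if not per_taxon:
        return GeneAlignment(gene, {}, {}, {}, excluded)

    # merge insertion columns: max insertion length per reference position
    ins_len: dict[int, int] = {}
    for _, (_, inserts) in per_taxon.items():
        for pos, ins in inserts.items():
            ins_len[pos] = max(ins_len.get(pos, 0), len(ins))

    rows: dict[str, str] = {}
    for taxon, (codon_at, inserts) in per_taxon.items():
        parts: list[str] = []
        for r in range(ref_len + 1):
            if r in ins_len:
                ins = inserts.get(r, "")
                parts.append(ins + "-" * (ins_len[r] - len(ins)))
            if r < ref_len:
                parts.append(codon_at[r])
        rows[taxon] = "".join(parts)
    return GeneAlignment(gene, rows, sup, sources, excluded)


# ---------------------------------------------------------------------------
# trimming and translation

def _codon_columns(aln: GeneAlignment) -> list[list[str]]:
    L = aln.length
    taxa = sorted(aln.rows)
    return [[aln.rows[t][i:i + 3] for t in taxa] for i in range(0, L, 3)]


def trim_to_cds(aln: GeneAlignment) -> GeneAlignment:
    """Trim columns before the consensus start codon and after the first
    consensus in-frame stop.

    The consensus is the majority codon over rows with a determinate codon
    at that position.  Rows lacking data inside the kept window keep '?'.
    If no start-codon column exists the gene is flagged partial and
    trimming anchors at the first codon column.
    """
    if aln.length % 3:
        raise ValueError("alignment length not divisible by 3")
    cols = _codon_columns(aln)
    n_col = len(cols)

    def consensus(codons: list[str]) -> str | None:
        det = [c for c in codons if set(c) <= set("ACGT")]
        if not det:
            return None
        vals, counts = np.unique(det, return_counts=True)
        top = counts.max()
        cands = sorted(v for v, c in zip(vals, counts) if c == top)
        return cands[0]

    start_col = None
    for i, codons in enumerate(cols):
        if consensus(codons) == "ATG":
            start_col = i
            break
    partial = start_col is None
    if partial:
        start_col = 0

    stop_col = None
    for i in range(start_col, n_col):
        cons = consensus(cols[i])
        if cons in STOP_CODONS:
            stop_col = i
            break
    end_col = (stop_col + 1) if stop_col is not None else n_col

    taxa = sorted(aln.rows)
    rows = {t: aln.rows[t][3 * start_col:3 * end_col] for t in taxa}
    # rows with no sequence in the window become all-'?' (pad, not drop)
    for t in taxa:
        if set(rows[t]) <= {"-", "?"}:
            rows[t] = "?" * len(rows[t])
    out = GeneAlignment.__new__(GeneAlignment)
    out.gene = aln.gene + ("|partial" if partial else "")
    out.rows = rows
    out.super_transcript = dict(aln.super_transcript)
    out.sources = dict(aln.sources)
    out.excluded = list(aln.excluded)
    return out


def translate_alignment(aln: GeneAlignment) -> dict[str, str]:
    """Codon-wise translation of an aligned nucleotide matrix.

    Stop codons are recoded as missing ('?'); an all-gap codon stays a gap
    ('-'); a codon mixing gaps and nucleotides is unknown ('?').
    """
    if aln.length % 3:
        raise ValueError("alignment length not divisible by 3")
    out: dict[str, str] = {}
    for taxon, row in aln.rows.items():
        aas: list[str] = []
        for i in range(0, len(row), 3):
            codon = row[i:i + 3]
            if codon == "---":
                aas.append("-")
            elif "-" in codon or "?" in codon:
                aas.append("?")
            elif codon in STOP_CODONS:
                aas.append("?")
            elif "N" in codon:
                aas.append("X")
            else:
                aas.append(_CODON_TABLE[codon])
        out[taxon] = "".join(aas)
    return out


# ---------------------------------------------------------------------------
# concatenation

@dataclass
class Supermatrix:
    """Concatenated alignment plus partition schemes and statistics."""

    taxa: list[str]
    rows: dict[str, str]
    gene_names: list[str]
    gene_lengths: list[int]
    by_gene: PartitionScheme
    by_codon: PartitionScheme

    @property
    def n_columns(self) -> int:
        return sum(self.gene_lengths)

    def missing_proportion(self) -> float:
        """Proportion of gap ('-') plus missing ('?') cells."""
        total = len(self.taxa) * self.n_columns
        bad = sum(row.count("-") + row.count("?") for row in self.rows.values())
        return bad / total if total else 0.0

    def super_transcript_counts(self, genes: list[GeneAlignment]) -> dict[str, int]:
        counts = {t: 0 for t in self.taxa}
        for g in genes:
            for t, flag in g.super_transcript.items():
                if flag and t in counts:
                    counts[t] += 1
        return counts


def concatenate(genes: list[GeneAlignment], taxa: list[str]) -> Supermatrix:
    """Concatenate gene alignments over a fixed taxon list.

    Genes keep input order; a taxon absent from a gene is filled with '?'.
    Partition schemes are emitted both by gene and by codon position
    (3 strided blocks over the full matrix, valid because every gene length
    is a codon multiple).
    """
    for g in genes:
        if g.length % 3:
            raise ValueError(f"gene {g.gene}: length not divisible by 3")
        if len(set(g.rows)) != len(g.rows):
            raise ValueError(f"gene {g.gene}: duplicate taxon")
    rows = {t: [] for t in taxa}
    lengths: list[int] = []
    names: list[str] = []
    for g in genes:
        L = g.length
        lengths.append(L)
        names.append(g.gene)
        for t in taxa:
            rows[t].append(g.rows.get(t, "?" * L))
    cat = {t: "".join(parts) for t, parts in rows.items()}
    total = sum(lengths)

    blocks = []
    pos = 1
    for name, L in zip(names, lengths):
        blocks.append(PartitionBlock(name, [(pos, pos + L - 1)], None))
        pos += L
    by_gene = PartitionScheme(blocks, total)
    by_codon = PartitionScheme(
        [PartitionBlock(f"codon{i}", [(i, total)], i) for i in (1, 2, 3)],
        total)
    return Supermatrix(list(taxa), cat, names, lengths, by_gene, by_codon)


def deconcatenate(matrix: Supermatrix) -> list[dict[str, str]]:
    """Recover per-gene row dicts from the by-gene partition scheme."""
    out: list[dict[str, str]] = []
    for block in matrix.by_gene.blocks:
        (s, e) = block.intervals[0]
        out.append({t: matrix.rows[t][s - 1:e] for t in matrix.taxa})
    return out
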