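"""Translated similarity search of reference proteins against transcriptomes.

A desk-scale, fully deterministic stand-in for tblastn/blastx: reference
proteins are matched against all six reading frames of each transcript.
Exact amino-acid k-mer seeds are located first (with a two-hit diagonal
rule, as in the classic seeded-search heuristic), candidate frames are then
aligned with an affine-gap local aligner under BLOSUM62, and raw scores are
converted to bit scores with the standard Karlin-Altschul scaling for gapped
BLOSUM62 (lambda = 0.267, K = 0.041).  E-value thresholds of external
searches map onto bit-score cutoffs, which keeps filtering independent of
database size.

:func:`smith_waterman_protein` is the exact exhaustive aligner used as an
oracle in tests; the production path (:func:`seeded_translated_search`) uses
Biopython's C pairwise aligner with the same scoring scheme for speed, so
optimal scores agree between the two routes by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import HitRecord, SequenceRecord

# gapped BLOSUM62 Karlin-Altschul constants
LAMBDA = 0.267
K_CONST = 0.041

#: gap of length k costs GAP_OPEN + k * GAP_EXTEND (BLAST convention)
GAP_OPEN = 11
GAP_EXTEND = 1

BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62_IDX = {c: i for i, c in enumerate(BLOSUM62.alphabet)}
_B62 = np.array(BLOSUM62, dtype=np.int64)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def bits_from_raw(raw: float) -> float:
    """Raw alignment score -> bit score."""
    return (LAMBDA * raw - math.log(K_CONST)) / math.log(2.0)


def raw_from_bits(bits: float) -> float:
    return (bits * math.log(2.0) + math.log(K_CONST)) / LAMBDA


def bits_from_evalue(evalue: float, search_space: float) -> float:
    """Bit-score cutoff equivalent to an E-value cutoff at a given m*n."""
    return math.log2(search_space / evalue)


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def translate_frame(nt: str, frame: int) -> str:
    """Translate one frame (+1..+3 forward, -1..-3 on reverse complement)."""
    from .synthetic_data import _CODON_TABLE  # shared standard code table
    s = nt if frame > 0 else reverse_complement(nt)
    off = abs(frame) - 1
    out = []
    for i in range(off, len(s) - 2, 3):
        codon = s[i:i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(_CODON_TABLE.get(codon, "X"))
    return "".join(out)


def six_frame_translate(record: SequenceRecord | str) -> list[tuple[int, str]]:
    """All six frame translations as (frame, peptide) pairs.

    Stop codons are rendered '*', N-containing codons 'X'.  Sequences
    shorter than 3 nt yield empty peptides for every frame.
    """
    nt = record.residues if isinstance(record, SequenceRecord) else record
    if len(nt) < 3:
        import logging
        logging.getLogger("opilio").warning("sequence shorter than 3 nt")
        return [(f, "") for f in (1, 2, 3, -1, -2, -3)]
    return [(f, translate_frame(nt, f)) for f in (1, 2, 3, -1, -2, -3)]


# ---------------------------------------------------------------------------
# exact local alignment (oracle)

@dataclass
class LocalAlignment:
    score: int
    a_aligned: str
    b_aligned: str
    a_start: int  # 0-based half-open on a
    a_end: int
    b_start: int
    b_end: int

    @property
    def columns(self) -> int:
        return len(self.a_aligned)

    @property
    def matches(self) -> int:
        return sum(1 for x, y in zip(self.a_aligned, self.b_aligned) if x == y)

    @property
    def gap_columns(self) -> int:
        return sum(1 for x, y in zip(self.a_aligned, self.b_aligned)
                   if x == "-" or y == "-")


def score_alignment(a_aligned: str, b_aligned: str,
                    gap_open: int = GAP_OPEN, gap_extend: int = GAP_EXTEND) -> int:
    """Re-score an explicit alignment under BLOSUM62 + affine gaps."""
    score = 0
    in_gap = False
    for x, y in zip(a_aligned, b_aligned):
        if x == "-" or y == "-":
            if not in_gap:
                score -= gap_open
                in_gap = True
            score -= gap_extend
        else:
            in_gap = False
            score += int(_B62[_B62_IDX[x], _B62_IDX[y]])
    return score


def smith_waterman_protein(a: str, b: str, gap_open: int = GAP_OPEN,
                           gap_extend: int = GAP_EXTEND) -> LocalAlignment:
    """Exact affine-gap Smith-Waterman under BLOSUM62.

    A gap of length k costs ``gap_open + k*gap_extend``.  On score ties the
    traceback prefers diagonal, then up (gap in b), then left (gap in a).
    Empty input gives score 0 and an empty alignment.
    """
    if not a or not b:
        return LocalAlignment(0, "", "", 0, 0, 0, 0)
    n, m = len(a), len(b)
    ai = [_B62_IDX[c] for c in a]
    bi = [_B62_IDX[c] for c in b]
    sub = _B62
    go, ge = gap_open + gap_extend, gap_extend

    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[-10 ** 9] * (m + 1) for _ in range(n + 1)]  # gap in a (left)
    F = [[-10 ** 9] * (m + 1) for _ in range(n + 1)]  # gap in b (up)
    best, bi_, bj_ = 0, 0, 0
    for i in range(1, n + 1):
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        srow = sub[ai[i - 1]]
        for j in range(1, m + 1):
            e = max(Hi[j - 1] - go, Ei[j - 1] - ge)
            f = max(Hi1[j] - go, Fi1[j] - ge)
            d = Hi1[j - 1] + srow[bi[j - 1]]
            h = d
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best, bi_, bj_ = h, i, j
    if best == 0:
        return LocalAlignment(0, "", "", 0, 0, 0, 0)

    # traceback from (bi_, bj_); state M/E/F; ties prefer diagonal, up, left
    out_a: list[str] = []
    out_b: list[str] = []
    i, j, state = bi_, bj_, "M"
    while i > 0 and j > 0:
        h = H[i][j]
        if state == "M":
            if h == 0:
                break
            d = H[i - 1][j - 1] + sub[ai[i - 1]][bi[j - 1]]
            if h == d:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i, j = i - 1, j - 1
                continue
            if h == F[i][j]:
                state = "F"
                continue
            state = "E"
            continue
        if state == "F":  # gap in b: consume a (up)
            out_a.append(a[i - 1])
            out_b.append("-")
            if F[i][j] == H[i - 1][j] - go:
                state = "M"
            i -= 1
            continue
        # state E: gap in a, consume b (left)
        out_a.append("-")
        out_b.append(b[j - 1])
        if E[i][j] == H[i][j - 1] - go:
            state = "M"
        j -= 1
    return LocalAlignment(best, "".join(reversed(out_a)), "".join(reversed(out_b)),
                          i, bi_, j, bj_)


# ---------------------------------------------------------------------------
# fast aligner (same scoring scheme, C implementation)

def _make_aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = BLOSUM62
    # PairwiseAligner convention: first gap position costs open, later extend;
    # open = -(GAP_OPEN + GAP_EXTEND) reproduces cost(k) = GAP_OPEN + k*GAP_EXTEND
    al.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    al.extend_gap_score = -GAP_EXTEND
    return al

_ALIGNER = _make_aligner()


def _fast_local(a: str, b: str) -> LocalAlignment | None:
    score = _ALIGNER.score(a, b)
    if score <= 0:
        return None
    aln = next(iter(_ALIGNER.align(a, b)))
    blocks_a, blocks_b = aln.aligned
    out_a: list[str] = []
    out_b: list[str] = []
    prev_a = prev_b = None
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            out_a.append(a[prev_a:as_])
            out_b.append("-" * (as_ - prev_a))
            out_a.append("-" * (bs - prev_b))
            out_b.append(b[prev_b:bs])
        out_a.append(a[as_:ae])
        out_b.append(b[bs:be])
        prev_a, prev_b = ae, be
    return LocalAlignment(int(score), "".join(out_a), "".join(out_b),
                          int(blocks_a[0][0]), int(blocks_a[-1][1]),
                          int(blocks_b[0][0]), int(blocks_b[-1][1]))


# ---------------------------------------------------------------------------
# seeded search

def _peptide_nt_coords(nt_len: int, frame: int, p_start: int, p_end: int
                       ) -> tuple[int, int]:
    """Peptide interval (0-based half-open) -> 1-based inclusive nt coords.

    For minus frames coordinates are reported on the forward strand with
    sstart > send.
    """
    off = abs(frame) - 1
    lo = off + 3 * p_start          # 0-based on the read strand
    hi = off + 3 * p_end - 1        # inclusive
    if frame > 0:
        return lo + 1, hi + 1
    return nt_len - lo, nt_len - hi


def _hit_from_alignment(query: SequenceRecord, subject: SequenceRecord,
                        frame: int, aln: LocalAlignment) -> HitRecord:
    cols = aln.columns
    matches = aln.matches
    gaps = aln.gap_columns
    sstart, send = _peptide_nt_coords(len(subject.residues), frame,
                                      aln.b_start, aln.b_end)
    bits = bits_from_raw(aln.score)
    evalue = K_CONST * len(query.residues) * len(subject.residues) * math.exp(
        -LAMBDA * aln.score)
    return HitRecord(
        query=query.identifier, subject=subject.identifier,
        pident=100.0 * matches / cols if cols else 0.0,
        length=cols, mismatch=cols - matches - gaps, gapopen=_count_gap_opens(aln),
        qstart=aln.a_start + 1, qend=aln.a_end,
        sstart=sstart, send=send, evalue=evalue, bitscore=round(bits, 1),
        frame=frame, gap_columns=gaps,
    )


def _count_gap_opens(aln: LocalAlignment) -> int:
    opens = 0
    in_gap = False
    for x, y in zip(aln.a_aligned, aln.b_aligned):
        g = x == "-" or y == "-"
        if g and not in_gap:
            opens += 1
        in_gap = g
    return opens


def exhaustive_translated_search(query: SequenceRecord,
                                 subject: SequenceRecord) -> HitRecord | None:
    """Oracle: exact Smith-Waterman over all six frames, best hit only."""
    best: tuple[int, int, LocalAlignment] | None = None
    for frame, pep in six_frame_translate(subject):
        if not pep:
            continue
        aln = smith_waterman_protein(query.residues, pep)
        if aln.score > 0 and (best is None or aln.score > best[0]):
            best = (aln.score, frame, aln)
    if best is None:
        return None
    return _hit_from_alignment(query, subject, best[1], best[2])


def _encode_pep(pep: str) -> np.ndarray:
    return np.fromiter((_B62_IDX.get(c, _B62_IDX["X"]) for c in pep),
                       dtype=np.int64, count=len(pep))


def _ungapped_diag_score(qarr: np.ndarray, parr: np.ndarray, diag: int) -> int:
    """Best ungapped segment score along one diagonal (vectorized Kadane)."""
    q0 = max(0, -diag)
    p0 = q0 + diag
    n = min(len(qarr) - q0, len(parr) - p0)
    if n <= 0:
        return 0
    s = _B62[qarr[q0:q0 + n], parr[p0:p0 + n]]
    cum = np.cumsum(s)
    floor = np.minimum.accumulate(np.concatenate(([0], cum[:-1])))
    return int((cum - floor).max())


def seeded_translated_search(proteins: list[SequenceRecord],
                             transcriptome: dict[str, list[SequenceRecord]],
                             k: int = 4, score_min_bits: float = 40.0,
                             max_hits: int = 20,
                             ungapped_min_raw: int = 40) -> list[HitRecord]:
    """Seeded translated search of proteins against per-taxon transcript sets.

    For each protein x transcript frame, exact k-mer seed words are located;
    every seeded (protein, frame) pair is screened by an ungapped extension
    along its seed diagonals, and pairs scoring at least
    ``ungapped_min_raw`` raw are aligned with the affine-gap local aligner.  Hits below
    ``score_min_bits`` are dropped; per protein and taxon, hits are sorted
    by descending bit score (ties by subject id) and truncated to
    ``max_hits``.
    """
    if k < 2:
        raise ValueError("seed word size k must be >= 2")
    # query k-mer index: kmer -> list of (protein index, position)
    qindex: dict[str, list[tuple[int, int]]] = {}
    qarrs: list[np.ndarray] = []
    for qi, prot in enumerate(proteins):
        seq = prot.residues
        qarrs.append(_encode_pep(seq))
        for p in range(0, len(seq) - k + 1):
            qindex.setdefault(seq[p:p + k], []).append((qi, p))

    hits: list[HitRecord] = []
    for taxon, records in transcriptome.items():
        per_query: dict[int, list[HitRecord]] = {}
        for rec in records:
            for frame, pep in six_frame_translate(rec):
                if len(pep) < k:
                    continue
                # seed pass: count seeds per (query, diagonal)
                by_q: dict[int, dict[int, int]] = {}
                for sp in range(0, len(pep) - k + 1):
                    for (qi, qp) in qindex.get(pep[sp:sp + k], ()):
                        dd = by_q.setdefault(qi, {})
                        dd[sp - qp] = dd.get(sp - qp, 0) + 1
                if not by_q:
                    continue
                parr = _encode_pep(pep)
                for qi in sorted(by_q):
                    dd = by_q[qi]
                    diags = sorted(dd, key=lambda d: -dd[d])[:16]
                    best_ungapped = max(
                        _ungapped_diag_score(qarrs[qi], parr, d) for d in diags)
                    if best_ungapped < ungapped_min_raw:
                        continue
                    if bits_from_raw(_ALIGNER.score(
                            proteins[qi].residues, pep)) < score_min_bits:
                        continue
                    aln = _fast_local(proteins[qi].residues, pep)
                    if aln is None:
                        continue
                    hit = _hit_from_alignment(proteins[qi], rec, frame, aln)
                    per_query.setdefault(qi, []).append(hit)
        for qi, qhits in sorted(per_query.items()):
            # keep the best hit per subject transcript (HSP/frame merging)
            best_by_subject: dict[str, HitRecord] = {}
            for h in qhits:
                cur = best_by_subject.get(h.subject)
                if cur is None or h.bitscore > cur.bitscore:
                    best_by_subject[h.subject] = h
            ranked = sorted(best_by_subject.values(),
                            key=lambda h: (-h.bitscore, h.subject))
            hits.extend(ranked[:max_hits])
    return hits
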