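"""Candidate-gene screening over translated-search hit tables.

Two screens are implemented, mirroring how a transcriptome phylogenomics
study selects single-copy orthologs against outgroup references:

* the **TICK screen** (reference = an annotated outgroup peptide set):
  presence in all eight transcriptomes, minimum region length, no paralogy,
  no conspicuously extended reading frames, low-gap alignments, and a
  preference for complete (start+stop) genes, stopping at ``max_genes``;

* the **SCORP screen** (reference = outgroup EST-derived proteins):
  minimum overlap, no paralogy, presence of an anchor taxon plus at least
  one representative per listed suborder, and a cross-check that anchor and
  outgroup match the same protein in a second reference set.

Paralogy is diagnosed as multiple *divergent* transcripts from one taxon
covering the same reference region: coding-overlap identity below a
threshold (default 0.98 over >= 100 nt).  Transcripts identical over the
coding overlap, differing only in their flanks, are redundant alternative
transcripts and are not penalized.  Every decision is written to the audit
log as (gene, rule, verdict, detail).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import edlib
import numpy as np

from .io_formats import AuditLog, HitRecord, SequenceRecord
from .homology_search import reverse_complement


@dataclass
class FilterParams:
    """Thresholds of the ortholog screens.

    ``min_overlap_nt`` (SCORP) and ``min_region_nt`` (TICK) bound the
    reference-matched region; ``max_gap_fraction`` bounds gap columns in
    the hit alignments; ``reading_frame_excess`` is the maximum ratio of
    harvestman ORF length to reference ORF length before a transcript is
    deemed conspicuously extended (chimeric/fused).
    """

    min_overlap_nt: int = 200
    min_region_nt: int = 300
    max_gap_fraction: float = 0.05
    paralog_identity_threshold: float = 0.98
    paralog_min_overlap_nt: int = 100
    reading_frame_excess: float = 1.5
    require_all_taxa: bool = True
    presence_groups: dict[str, frozenset[str]] = field(default_factory=dict)
    anchor_taxon: str = "Siro"
    prefer_complete: bool = True
    max_genes: int = 300

    def __post_init__(self) -> None:
        for name in ("min_overlap_nt", "min_region_nt", "paralog_min_overlap_nt",
                     "reading_frame_excess", "max_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.paralog_identity_threshold <= 1.0):
            raise ValueError("paralog_identity_threshold must be in (0, 1]")


@dataclass
class TaxonEntry:
    """All hits of one candidate gene to one transcript of one taxon."""

    transcript: str
    hits: list[HitRecord]
    query_span: tuple[int, int]      # 0-based half-open aa interval, merged
    subject_span: tuple[int, int]    # 0-based half-open nt interval, merged
    internal_gaps: list[tuple[int, int]] = field(default_factory=list)

    @property
    def spanned_nt(self) -> int:
        return self.subject_span[1] - self.subject_span[0]


@dataclass
class CandidateGene:
    """A reference protein with its per-taxon matching transcripts."""

    query: str
    taxa: dict[str, list[TaxonEntry]] = field(default_factory=dict)
    region_nt: int = 0               # max spanned nucleotides across taxa
    chosen: dict[str, list[str]] = field(default_factory=dict)
    ledger: list[tuple[str, str, str]] = field(default_factory=list)
    has_start: bool = False
    has_stop: bool = False
    rank_length: int = 0

    def log(self, rule: str, verdict: str, detail: str = "") -> None:
        self.ledger.append((rule, verdict, detail))

    def all_transcripts(self) -> set[str]:
        return {e.transcript for entries in self.taxa.values() for e in entries}


def group_hits(hits: list[HitRecord]) -> list[CandidateGene]:
    """Group a hit stream into per-reference-protein candidates.

    Per taxon, multiple hits to the same transcript are merged into one
    spanned region (recording internal gaps between non-contiguous hits);
    the candidate's region length is the maximum spanned nucleotide extent
    across taxa.
    """
    by_query: dict[str, dict[str, dict[str, list[HitRecord]]]] = {}
    order: list[str] = []
    for h in hits:
        if h.query not in by_query:
            by_query[h.query] = {}
            order.append(h.query)
        by_query[h.query].setdefault(h.taxon, {}).setdefault(h.subject, []).append(h)

    out: list[CandidateGene] = []
    for query in sorted(order):
        cand = CandidateGene(query=query)
        for taxon in sorted(by_query[query]):
            entries: list[TaxonEntry] = []
            for subject in sorted(by_query[query][taxon]):
                shits = by_query[query][taxon][subject]
                q_lo = min(h.query_span[0] for h in shits)
                q_hi = max(h.query_span[1] for h in shits)
                s_lo = min(h.subject_span[0] for h in shits)
                s_hi = max(h.subject_span[1] for h in shits)
                ivals = sorted(h.subject_span for h in shits)
                gaps = []
                cur_end = ivals[0][1]
                for (s, e) in ivals[1:]:
                    if s > cur_end:
                        gaps.append((cur_end, s))
                    cur_end = max(cur_end, e)
                entries.append(TaxonEntry(subject, shits, (q_lo, q_hi),
                                          (s_lo, s_hi), gaps))
            entries.sort(key=lambda e: e.query_span)
            cand.taxa[taxon] = entries
        # spanned region: per taxon the union extent over its transcripts,
        # measured on the reference (aa * 3) so fragments accumulate
        spans = []
        for entries in cand.taxa.values():
            q_lo = min(e.query_span[0] for e in entries)
            q_hi = max(e.query_span[1] for e in entries)
            nt_union = 3 * (q_hi - q_lo)
            spans.append(max(nt_union, max(e.spanned_nt for e in entries)))
        cand.region_nt = max(spans) if spans else 0
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# paralogy

def _coding_subseq(entry_hit: HitRecord, transcript: str,
                   q_lo: int, q_hi: int) -> str | None:
    """Transcript nucleotides matching reference aa interval [q_lo, q_hi).

    Assumes colinearity within the hit (no indel correction); minus-strand
    hits are reported on the forward strand and reverse-complemented here.
    """
    h = entry_hit
    hq_lo, hq_hi = h.query_span
    if q_lo < hq_lo or q_hi > hq_hi:
        return None
    off_nt = 3 * (q_lo - hq_lo)
    span_nt = 3 * (q_hi - q_lo)
    if not h.minus:
        start = (h.sstart - 1) + off_nt
        return transcript[start:start + span_nt]
    start = (h.sstart - 1) - off_nt
    seg = transcript[start - span_nt + 1:start + 1]
    return reverse_complement(seg)


def _overlap_identity(e1: TaxonEntry, e2: TaxonEntry,
                      seqs: dict[str, str]) -> tuple[float, int]:
    """Aligned identity of two transcripts over their shared reference region.

    Returns (identity, overlap_nt); overlap_nt = 0 if no usable overlap.
    """
    q_lo = max(e1.query_span[0], e2.query_span[0])
    q_hi = min(e1.query_span[1], e2.query_span[1])
    if q_hi <= q_lo:
        return 1.0, 0
    h1 = max(e1.hits, key=lambda h: h.bitscore)
    h2 = max(e2.hits, key=lambda h: h.bitscore)
    q_lo = max(q_lo, h1.query_span[0], h2.query_span[0])
    q_hi = min(q_hi, h1.query_span[1], h2.query_span[1])
    if q_hi <= q_lo:
        return 1.0, 0
    s1 = _coding_subseq(h1, seqs[e1.transcript], q_lo, q_hi)
    s2 = _coding_subseq(h2, seqs[e2.transcript], q_lo, q_hi)
    if s1 is None or s2 is None or not s1 or not s2:
        return 1.0, 0
    dist = edlib.align(s1, s2, task="distance")["editDistance"]
    ident = 1.0 - dist / max(len(s1), len(s2))
    return ident, 3 * (q_hi - q_lo)


def detect_paralogy(candidate: CandidateGene, params: FilterParams,
                    sequences: dict[str, str]) -> str:
    """Classify a candidate: ``single_copy`` / ``paralogous`` /
    ``alternative_transcripts``.

    A taxon with two transcripts whose aligned coding-region identity over
    an overlap of at least ``paralog_min_overlap_nt`` falls below
    ``paralog_identity_threshold`` marks the candidate paralogous.
    Transcripts identical over the coding overlap (differing only outside
    it) are alternative transcripts of one gene.
    """
    saw_alternative = False
    for taxon, entries in candidate.taxa.items():
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                ident, ov = _overlap_identity(entries[i], entries[j], sequences)
                if ov < params.paralog_min_overlap_nt:
                    continue
                if ident < params.paralog_identity_threshold:
                    candidate.log("paralogy", "paralogous",
                                  f"{taxon}: identity {ident:.3f} over {ov} nt")
                    return "paralogous"
                saw_alternative = True
    verdict = "alternative_transcripts" if saw_alternative else "single_copy"
    candidate.log("paralogy", verdict, "")
    return verdict


# ---------------------------------------------------------------------------
# ORF inspection

_STOPS = {"TAA", "TAG", "TGA"}


def orf_extent(transcript: str, hit: HitRecord) -> tuple[int, int, bool, bool]:
    """Open reading frame around a hit: (orf_len_aa, hit frame offset,
    has_start, has_stop).

    The ORF is the maximal stop-free in-frame stretch containing the hit,
    scanned on the hit's strand; has_start requires an ATG at or upstream of
    the hit start inside the ORF, has_stop a stop codon immediately 3' of
    the ORF.
    """
    seq = transcript if not hit.minus else reverse_complement(transcript)
    n = len(seq)
    if not hit.minus:
        lo = hit.sstart - 1
    else:
        lo = n - hit.sstart
    frame_off = lo % 3
    codon_start = lo // 3
    codons = [seq[i:i + 3] for i in range(frame_off, n - 2, 3)]
    c = min(max(codon_start, 0), len(codons) - 1)
    # scan upstream to the first stop
    up = c
    while up > 0 and codons[up - 1] not in _STOPS:
        up -= 1
    # scan downstream to the first stop
    down = c
    while down < len(codons) - 1 and codons[down] not in _STOPS:
        down += 1
    has_stop = codons[down] in _STOPS
    orf_codons = codons[up:down]
    has_start = "ATG" in orf_codons[:max(1, c - up + 1)]
    try:
        atg = orf_codons.index("ATG")
    except ValueError:
        atg = 0
        has_start = False
    orf_len = len(orf_codons) - (atg if has_start else 0)
    return orf_len, frame_off, has_start, has_stop


# ---------------------------------------------------------------------------
# TICK screen

def apply_tick_filter(candidates: list[CandidateGene], params: FilterParams,
                      sequences: dict[str, str],
                      reference: dict[str, SequenceRecord],
                      all_taxa: tuple[str, ...] | None = None,
                      audit: AuditLog | None = None,
                      rng: np.random.Generator | None = None
                      ) -> list[CandidateGene]:
    """The strict outgroup-peptide screen.

    Rule order: presence in all taxa -> region length -> paralogy ->
    reading-frame excess -> gap fraction; completeness (start and stop
    codons in all taxa) is a ranking preference applied at the
    ``max_genes`` cutoff, not a discard.  Boundary semantics are literal:
    a 299-nt region is discarded and a 300-nt region kept; a gap fraction
    of 0.051 is discarded and 0.050 kept.
    """
    audit = audit if audit is not None else AuditLog()
    rng = rng if rng is not None else np.random.default_rng(0)
    if all_taxa is None:
        from .synthetic_data import TAXA
        all_taxa = TAXA

    retained: list[CandidateGene] = []
    for cand in candidates:
        gene = cand.query
        # rule 1: presence in all taxa
        present = set(cand.taxa)
        if params.require_all_taxa and present != set(all_taxa):
            missing = sorted(set(all_taxa) - present)
            cand.log("presence", "discard", f"missing {missing}")
            audit.record(gene, "presence", "discard", f"missing {missing}")
            continue
        audit.record(gene, "presence", "pass", f"{len(present)}/{len(all_taxa)}")

        # rule 2: region length (strictly-less-than-300 discards)
        if cand.region_nt < params.min_region_nt:
            cand.log("length", "discard", f"{cand.region_nt} nt")
            audit.record(gene, "length", "discard", f"{cand.region_nt} nt")
            continue
        audit.record(gene, "length", "pass", f"{cand.region_nt} nt")

        # rule 3: paralogy
        verdict = detect_paralogy(cand, params, sequences)
        audit.record(gene, "paralogy", verdict, "")
        if verdict == "paralogous":
            continue

        # choose one transcript per taxon (fragments keep all pieces for
        # later super-transcript merging; alternatives: random under seed)
        discard = None
        for taxon, entries in cand.taxa.items():
            if len(entries) == 1:
                cand.chosen[taxon] = [entries[0].transcript]
            else:
                overlapping = _any_overlap(entries, params)
                if overlapping:
                    pick = entries[int(rng.integers(len(entries)))]
                    cand.chosen[taxon] = [pick.transcript]
                else:
                    cand.chosen[taxon] = [e.transcript for e in entries]

        # rule 4: conspicuously longer reading frames
        ref_len = len(reference[cand.query].residues)
        completeness: list[tuple[bool, bool]] = []
        for taxon, tids in cand.chosen.items():
            entries = {e.transcript: e for e in cand.taxa[taxon]}
            starts, stops = [], []
            for tid in tids:
                h = max(entries[tid].hits, key=lambda h: h.bitscore)
                orf_len, _, st, sp = orf_extent(sequences[tid], h)
                starts.append(st)
                stops.append(sp)
                if orf_len > params.reading_frame_excess * ref_len:
                    discard = (taxon, tid, orf_len)
                    break
            completeness.append((any(starts), any(stops)))
            if discard:
                break
        if discard:
            cand.log("reading_frame", "discard",
                     f"{discard[0]}/{discard[1]}: ORF {discard[2]} aa vs ref {ref_len}")
            audit.record(gene, "reading_frame", "discard",
                         f"ORF {discard[2]} aa vs ref {ref_len}")
            continue
        audit.record(gene, "reading_frame", "pass", "")

        # rule 5: gap fraction over the candidate's hit alignments
        cols = gaps = 0
        for taxon, tids in cand.chosen.items():
            entries = {e.transcript: e for e in cand.taxa[taxon]}
            for tid in tids:
                for h in entries[tid].hits:
                    cols += h.length
                    gaps += h.gap_columns
        frac = gaps / cols if cols else 0.0
        if frac > params.max_gap_fraction:
            cand.log("gap_fraction", "discard", f"{frac:.3f}")
            audit.record(gene, "gap_fraction", "discard", f"{frac:.3f}")
            continue
        audit.record(gene, "gap_fraction", "pass", f"{frac:.3f}")

        # rule 6 (preference only): completeness flags
        cand.has_start = all(st for st, _ in completeness)
        cand.has_stop = all(sp for _, sp in completeness)
        cand.rank_length = cand.region_nt
        cand.log("retained", "retained", "")
        audit.record(gene, "retained", "retained", "")
        retained.append(cand)

    if params.prefer_complete:
        retained.sort(key=lambda c: (-(c.has_start and c.has_stop),
                                     -c.rank_length, c.query))
    else:
        retained.sort(key=lambda c: (-c.rank_length, c.query))
    if len(retained) > params.max_genes:
        for cand in retained[params.max_genes:]:
            cand.log("max_genes", "discard", "over gene cap")
            audit.record(cand.query, "max_genes", "discard", "over gene cap")
        retained = retained[:params.max_genes]
    return retained


def _any_overlap(entries: list[TaxonEntry], params: FilterParams) -> bool:
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            lo = max(entries[i].query_span[0], entries[j].query_span[0])
            hi = min(entries[i].query_span[1], entries[j].query_span[1])
            if 3 * (hi - lo) >= params.paralog_min_overlap_nt:
                return True
    return False


# ---------------------------------------------------------------------------
# SCORP screen

def apply_scorp_filter(candidates: list[CandidateGene], params: FilterParams,
                       sequences: dict[str, str],
                       outgroup_hits: dict[str, str] | None = None,
                       audit: AuditLog | None = None,
                       rng: np.random.Generator | None = None
                       ) -> list[CandidateGene]:
    """The EST-outgroup screen.

    Discard short overlaps (< ``min_overlap_nt``) and paralogy; require the
    anchor taxon plus at least one representative of every listed suborder
    group.  ``outgroup_hits`` maps source ids (the anchor sequence and the
    reference query) to their best second-reference protein; the outgroup
    row is only kept when both map to the same protein (the gene itself is
    kept either way).
    """
    audit = audit if audit is not None else AuditLog()
    rng = rng if rng is not None else np.random.default_rng(0)
    outgroup_hits = outgroup_hits or {}

    retained: list[CandidateGene] = []
    for cand in candidates:
        gene = cand.query
        if cand.region_nt < params.min_overlap_nt:
            cand.log("overlap", "discard", f"{cand.region_nt} nt")
            audit.record(gene, "overlap", "discard", f"{cand.region_nt} nt")
            continue
        audit.record(gene, "overlap", "pass", f"{cand.region_nt} nt")

        verdict = detect_paralogy(cand, params, sequences)
        audit.record(gene, "paralogy", verdict, "")
        if verdict == "paralogous":
            continue

        present = set(cand.taxa)
        if params.anchor_taxon not in present:
            cand.log("presence", "discard", f"anchor {params.anchor_taxon} absent")
            audit.record(gene, "presence", "discard", "anchor absent")
            continue
        missing_groups = [g for g, taxa in params.presence_groups.items()
                          if not (taxa & present)]
        if missing_groups:
            cand.log("presence", "discard", f"no representative of {missing_groups}")
            audit.record(gene, "presence", "discard", str(missing_groups))
            continue
        audit.record(gene, "presence", "pass", "")

        anchor_match = outgroup_hits.get(f"{gene}:{params.anchor_taxon}")
        query_match = outgroup_hits.get(f"{gene}:query")
        include = (anchor_match is not None and anchor_match == query_match)
        cand.log("outgroup_crosscheck",
                 "include_outgroup" if include else "omit_outgroup", "")
        audit.record(gene, "outgroup_crosscheck",
                     "include_outgroup" if include else "omit_outgroup", "")

        for taxon, entries in cand.taxa.items():
            if len(entries) == 1:
                cand.chosen[taxon] = [entries[0].transcript]
            elif _any_overlap(entries, params):
                pick = entries[int(rng.integers(len(entries)))]
                cand.chosen[taxon] = [pick.transcript]
            else:
                cand.chosen[taxon] = [e.transcript for e in entries]
        cand.rank_length = cand.region_nt
        cand.log("retained", "retained", "")
        audit.record(gene, "retained", "retained", "")
        retained.append(cand)
    return retained


# ---------------------------------------------------------------------------
# cross-set uniqueness

def enforce_uniqueness(gene_sets: dict[str, list[CandidateGene]]
                       ) -> tuple[dict[str, list[CandidateGene]],
                                  list[tuple[str, str, str, str]]]:
    """Drop later-ranked genes whose chosen transcripts were already used.

    Sets are processed in insertion order (the EST screen is assembled
    before the peptide screen, so its genes win cross-set collisions).
    Returns (deduplicated sets, collision report); each report row is
    (set, gene, transcript, first-claimed-by).
    """
    used: dict[str, str] = {}
    report: list[tuple[str, str, str, str]] = []
    out: dict[str, list[CandidateGene]] = {}
    for set_name, genes in gene_sets.items():
        kept: list[CandidateGene] = []
        for cand in genes:
            tids = [tid for tids in cand.chosen.values() for tid in tids] \
                or sorted(cand.all_transcripts())
            clash = next((t for t in tids if t in used), None)
            if clash is not None:
                report.append((set_name, cand.query, clash, used[clash]))
                cand.log("uniqueness", "discard", f"{clash} already used")
                continue
            for t in tids:
                used[t] = f"{set_name}:{cand.query}"
            kept.append(cand)
        out[set_name] = kept
    return out, report
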