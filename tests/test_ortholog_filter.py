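"""Candidate-gene screens: grouping, paralogy, rule boundaries, uniqueness."""

import numpy as np
import pytest

import opilio.ortholog_filter as of
from opilio.io_formats import Alphabet, AuditLog, HitRecord, SequenceRecord
from opilio.synthetic_data import TAXA, _CODON_TABLE

# first codon per amino acid, for deterministic reverse translation
_AA2CODON = {}
for codon, aa in _CODON_TABLE.items():
    _AA2CODON.setdefault(aa, codon)


def back_translate(pep: str) -> str:
    return "".join(_AA2CODON[a] for a in pep)


def mk_hit(query, subject, qstart, qend, sstart, send, bits=200.0,
           gap_columns=0, length=None):
    length = length or (qend - qstart + 1)
    return HitRecord(query=query, subject=subject, pident=100.0,
                     length=length, mismatch=0, gapopen=0,
                     qstart=qstart, qend=qend, sstart=sstart, send=send,
                     evalue=0.0, bitscore=bits, frame=1,
                     gap_columns=gap_columns)


def full_gene(query="ref|g1", pep_len=120, taxa=TAXA, gaps=0, nt_span=None):
    """One candidate hit per taxon covering pep_len aa."""
    hits = []
    send = nt_span if nt_span else 3 * pep_len
    for t in taxa:
        hits.append(mk_hit(query, f"{t}|t1", 1, pep_len, 1, send,
                           gap_columns=gaps, length=pep_len))
    return hits


PEP = "M" + "KVLDEARNGFHQWYITCSPM" * 7   # 141 aa reference
CDS = back_translate(PEP) + "TAA"
REF = {"ref|g1": SequenceRecord("ref|g1", PEP, Alphabet.aa)}
SEQS = {f"{t}|t1": CDS for t in TAXA}


# ---------------------------------------------------------------------------
# grouping

def test_group_hits_one_candidate_per_query():
    hits = full_gene()
    (cand,) = of.group_hits(hits)
    assert cand.query == "ref|g1"
    assert len(cand.taxa) == 8
    assert all(len(v) == 1 for v in cand.taxa.values())


def test_group_hits_merges_split_hits_with_recorded_gap():
    hits = [mk_hit("ref|g1", "Siro|t1", 1, 50, 1, 150),
            mk_hit("ref|g1", "Siro|t1", 101, 150, 301, 450)]
    (cand,) = of.group_hits(hits)
    (entry,) = cand.taxa["Siro"]
    assert entry.subject_span == (0, 450)
    assert entry.spanned_nt == 450
    assert entry.internal_gaps == [(150, 300)]


def test_group_hits_partitions_by_query():
    hits = full_gene("ref|g1") + full_gene("ref|g2")
    cands = of.group_hits(hits)
    assert [c.query for c in cands] == ["ref|g1", "ref|g2"]


def test_group_hits_empty_input():
    assert of.group_hits([]) == []


# ---------------------------------------------------------------------------
# paralogy

def _two_transcript_candidate(identity: float):
    """Siro carries two transcripts overlapping the full CDS; the second
    differs from the first at a controlled fraction of coding sites."""
    hits = full_gene()
    hits.append(mk_hit("ref|g1", "Siro|t2", 1, 141, 1, 423))
    (cand,) = of.group_hits(hits)
    seqs = dict(SEQS)
    cds = CDS[:-3]
    n_mut = round(len(cds) * (1 - identity))
    rng = np.random.default_rng(5)
    pos = rng.choice(len(cds), n_mut, replace=False)
    mutated = list(cds)
    for p in pos:
        mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
    seqs["Siro|t2"] = "".join(mutated) + "TAA"
    return cand, seqs


def test_divergent_second_transcript_is_paralogous():
    cand, seqs = _two_transcript_candidate(0.90)
    assert of.detect_paralogy(cand, of.FilterParams(), seqs) == "paralogous"


def test_identical_coding_overlap_is_alternative_transcripts():
    hits = full_gene()
    hits.append(mk_hit("ref|g1", "Siro|t2", 1, 141, 31, 453))
    (cand,) = of.group_hits(hits)
    seqs = dict(SEQS)
    seqs["Siro|t2"] = "GGGGGGGGGGGGGGGGGGGGGGGGGGGGGG" + CDS + "CCCCC"
    assert of.detect_paralogy(cand, of.FilterParams(), seqs) == \
        "alternative_transcripts"


def test_single_transcript_per_taxon_is_single_copy():
    (cand,) = of.group_hits(full_gene())
    assert of.detect_paralogy(cand, of.FilterParams(), SEQS) == "single_copy"


# ---------------------------------------------------------------------------
# TICK rule boundaries

def run_tick(hits, seqs=None, **params):
    cands = of.group_hits(hits)
    audit = AuditLog()
    retained = of.apply_tick_filter(
        cands, of.FilterParams(**params), seqs or SEQS, REF,
        audit=audit, rng=np.random.default_rng(0))
    return retained, audit


def test_presence_seven_of_eight_discarded():
    retained, audit = run_tick(full_gene(taxa=TAXA[:7]))
    assert retained == []
    assert audit.entries[0].rule == "presence"
    assert audit.entries[0].verdict == "discard"


def test_presence_eight_of_eight_passes():
    retained, _ = run_tick(full_gene())
    assert len(retained) == 1


def test_region_length_boundary_299_vs_300():
    pep60 = "M" + "KVLDEARNGFHQWYITCSPM" * 5  # 101 aa
    cds = back_translate(pep60) + "TAA"
    ref = {"ref|g1": SequenceRecord("ref|g1", pep60, Alphabet.aa)}
    seqs = {f"{t}|t1": cds for t in TAXA}
    for span, kept in [(299, 0), (300, 1)]:
        hits = [mk_hit("ref|g1", f"{t}|t1", 1, span // 3, 1, span) for t in TAXA]
        cands = of.group_hits(hits)
        retained = of.apply_tick_filter(cands, of.FilterParams(), seqs, ref,
                                        rng=np.random.default_rng(0))
        assert len(retained) == kept, f"span {span}"


def test_gap_fraction_boundary():
    for gaps, kept in [(51, 0), (50, 1)]:
        retained, _ = run_tick(full_gene(gaps=gaps, pep_len=1000))
        assert len(retained) == kept, f"gap columns {gaps}"


def test_reading_frame_excess_discards_extended_orf():
    # harvestman ORF made conspicuously longer: embed the CDS in a long
    # stop-free open frame (poly-AAA = poly-K) exceeding 1.5x the reference
    long_orf = "ATG" + "AAA" * 200 + CDS[3:]
    seqs = dict(SEQS)
    seqs["Siro|t1"] = long_orf
    hits = full_gene()
    retained, audit = run_tick(hits, seqs=seqs)
    assert retained == []
    assert audit.terminal_verdicts()["ref|g1"] == "discard"
    assert any(e.rule == "reading_frame" and e.verdict == "discard"
               for e in audit.entries)


def test_max_genes_cap_prefers_complete_then_longer():
    hits = []
    for i, pep_len in [(1, 100), (2, 140), (3, 120)]:
        for t in TAXA:
            hits.append(mk_hit(f"ref|g{i}", f"{t}|t{i}", 1, pep_len,
                               1, 3 * pep_len, length=pep_len))
    peps = {1: "M" + "A" * 99, 2: "M" + "A" * 139, 3: "M" + "A" * 119}
    ref = {f"ref|g{i}": SequenceRecord(f"ref|g{i}", p, Alphabet.aa)
           for i, p in peps.items()}
    seqs = {}
    for i, p in peps.items():
        for t in TAXA:
            seqs[f"{t}|t{i}"] = back_translate(p) + "TAA"
    cands = of.group_hits(hits)
    retained = of.apply_tick_filter(cands, of.FilterParams(max_genes=2),
                                    seqs, ref, rng=np.random.default_rng(0))
    assert [c.query for c in retained] == ["ref|g2", "ref|g3"]


def test_ledger_completeness(small_hits, small_batch):
    """discarded + retained = input; every candidate ends in one verdict."""
    seqs = {r.identifier: r.residues
            for recs in small_batch.transcriptomes.values() for r in recs}
    ref = {r.identifier: r for r in small_batch.reference}
    cands = of.group_hits(small_hits)
    audit = AuditLog()
    retained = of.apply_tick_filter(cands, of.FilterParams(), seqs, ref,
                                    audit=audit, rng=np.random.default_rng(0))
    verdicts = audit.terminal_verdicts()
    assert set(verdicts) == {c.query for c in cands}
    n_kept = sum(1 for v in verdicts.values() if v == "retained")
    assert n_kept == len(retained)


def test_filter_deterministic_byte_for_byte(tmp_path, small_hits, small_batch):
    seqs = {r.identifier: r.residues
            for recs in small_batch.transcriptomes.values() for r in recs}
    ref = {r.identifier: r for r in small_batch.reference}
    outs = []
    for run in "ab":
        audit = AuditLog()
        of.apply_tick_filter(of.group_hits(small_hits), of.FilterParams(),
                             seqs, ref, audit=audit,
                             rng=np.random.default_rng(7))
        p = tmp_path / f"{run}.tsv"
        audit.write(p)
        outs.append(p.read_bytes())
    assert outs[0] == outs[1]


def test_threshold_monotonicity(small_hits, small_batch):
    """Relaxing any single threshold never decreases the retained count."""
    seqs = {r.identifier: r.residues
            for recs in small_batch.transcriptomes.values() for r in recs}
    ref = {r.identifier: r for r in small_batch.reference}

    def count(**kw):
        return len(of.apply_tick_filter(
            of.group_hits(small_hits), of.FilterParams(**kw), seqs, ref,
            rng=np.random.default_rng(0)))

    base = count()
    assert count(min_region_nt=150) >= base
    assert count(max_gap_fraction=0.5) >= base
    assert count(paralog_identity_threshold=0.5) >= base


# ---------------------------------------------------------------------------
# SCORP screen

GROUPS = {"Laniatores": frozenset({"Sitalcina", "Sclerobunus"}),
          "Dyspnoi": frozenset({"Hesperonemastoma", "Ortholasma", "Trogulus"}),
          "Eupnoi": frozenset({"Leiobunum", "Protolophus"})}


def run_scorp(hits, outgroup_hits=None):
    cands = of.group_hits(hits)
    params = of.FilterParams(presence_groups=GROUPS, anchor_taxon="Siro")
    return of.apply_scorp_filter(cands, params, SEQS,
                                 outgroup_hits=outgroup_hits,
                                 rng=np.random.default_rng(0))


def test_scorp_overlap_boundary_199_vs_200():
    for span, kept in [(199, 0), (200, 1)]:
        hits = [mk_hit("ref|g1", f"{t}|t1", 1, span // 3, 1, span)
                for t in ("Siro", "Sitalcina", "Hesperonemastoma", "Leiobunum")]
        assert len(run_scorp(hits)) == kept, f"span {span}"


def test_scorp_requires_anchor_and_each_suborder():
    # anchor + 2 Eupnoi + 1 Dyspnoi, no Laniatores -> discarded
    hits = [mk_hit("ref|g1", f"{t}|t1", 1, 100, 1, 300)
            for t in ("Siro", "Leiobunum", "Protolophus", "Ortholasma")]
    assert run_scorp(hits) == []
    hits.append(mk_hit("ref|g1", "Sitalcina|t1", 1, 100, 1, 300))
    assert len(run_scorp(hits)) == 1


def test_scorp_outgroup_crosscheck():
    hits = [mk_hit("ref|g1", f"{t}|t1", 1, 100, 1, 300)
            for t in ("Siro", "Sitalcina", "Hesperonemastoma", "Leiobunum")]
    # anchor and reference query match different second-reference proteins:
    # gene kept, outgroup row omitted
    (kept,) = run_scorp(hits, {"ref|g1:Siro": "IX1", "ref|g1:query": "IX2"})
    assert ("outgroup_crosscheck", "omit_outgroup", "") in kept.ledger
    (kept,) = run_scorp(hits, {"ref|g1:Siro": "IX1", "ref|g1:query": "IX1"})
    assert ("outgroup_crosscheck", "include_outgroup", "") in kept.ledger


# ---------------------------------------------------------------------------
# uniqueness

def _candidate(query, transcript_ids):
    cand = of.CandidateGene(query=query)
    cand.chosen = {f"tax{i}": [t] for i, t in enumerate(transcript_ids)}
    return cand


def test_uniqueness_drops_later_ranked_gene():
    g1 = _candidate("g1", ["Siro|t1"])
    g2 = _candidate("g2", ["Siro|t1"])
    out, report = of.enforce_uniqueness({"TICK": [g1, g2]})
    assert [c.query for c in out["TICK"]] == ["g1"]
    assert report == [("TICK", "g2", "Siro|t1", "TICK:g1")]


def test_uniqueness_disjoint_sets_unchanged():
    g1 = _candidate("g1", ["Siro|t1"])
    g2 = _candidate("g2", ["Siro|t2"])
    out, report = of.enforce_uniqueness({"TICK": [g1, g2]})
    assert len(out["TICK"]) == 2 and report == []


def test_uniqueness_scorp_wins_cross_set_collision():
    scorp = _candidate("s1", ["Siro|t1"])
    tick = _candidate("t1", ["Siro|t1"])
    out, report = of.enforce_uniqueness({"SCORP": [scorp], "TICK": [tick]})
    assert [c.query for c in out["SCORP"]] == ["s1"]
    assert out["TICK"] == []
    assert report[0][:2] == ("TICK", "t1")
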