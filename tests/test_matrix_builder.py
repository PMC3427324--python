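"""Super-transcripts, codon-aware alignment, trimming, concatenation."""

import numpy as np
import pytest

import opilio.matrix_builder as mb
from opilio.io_formats import Alphabet, SequenceRecord
from opilio.synthetic_data import _CODON_TABLE, simulate_batch, translate_cds

_AA2CODON = {}
for codon, aa in _CODON_TABLE.items():
    _AA2CODON.setdefault(aa, codon)


def back_translate(pep):
    return "".join(_AA2CODON[a] for a in pep)


# non-repetitive test protein (no internal Met, fixed seed)
_rng = np.random.default_rng(2024)
PEP = "M" + "".join(_rng.choice(list("KVLDEARNGFHQWYITCSP"), 120))
CDS = back_translate(PEP) + "TAA"


def rec(seq, ident="Tax|t1", taxon="Tax"):
    return SequenceRecord(ident, seq, Alphabet.nt, taxon=taxon)


# ---------------------------------------------------------------------------
# super-transcript merging

def test_merge_overlap_splice():
    a, b = CDS[:210], CDS[180:]
    m = mb.merge_super_transcript([rec(a, "T|f1", "T"), rec(b, "T|f2", "T")],
                                  PEP)
    assert m.residues == CDS[:-3] or m.residues == CDS
    assert m.is_super_transcript


def test_merge_overlap_mismatch_fails():
    a = CDS[:210]
    b = list(CDS[180:])
    b[12] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[12]]
    with pytest.raises(mb.MergeError):
        mb.merge_super_transcript([rec(a, "T|f1", "T"),
                                   rec("".join(b), "T|f2", "T")], PEP)


def test_merge_adjacent_fragments_gap_filled():
    # codons 1-50 and 61-121: reference-implied gap of 10 codons -> 30 '?'
    a, b = CDS[:150], CDS[180:]
    m = mb.merge_super_transcript([rec(a, "T|f1", "T"), rec(b, "T|f2", "T")],
                                  PEP)
    assert "?" * 30 in m.residues
    assert m.residues.count("?") == 30
    assert m.residues.replace("?", "") == a + b[:-3] or \
        m.residues.replace("?", "") == a + b


def test_merge_requires_two_fragments():
    with pytest.raises(ValueError):
        mb.merge_super_transcript([rec(CDS)], PEP)


def test_merge_reconstructs_generator_fragments():
    """Synthetic fragmented genes merge back to the exact CDS substring.

    Rates are kept moderate: merging is only ever attempted on fragments
    the search stage matched to the reference in the first place."""
    batch = simulate_batch(12, 0, 0, seed=21, rate_meanlog=-4.5)
    seqs = {r.identifier: r.residues
            for recs in batch.transcriptomes.values() for r in recs}
    by_gene_taxon = {}
    for tid, (gene, taxon, iv) in batch.truth.fragment_map.items():
        by_gene_taxon.setdefault((gene, taxon), []).append(tid)
    assert by_gene_taxon
    for (gene, taxon), tids in by_gene_taxon.items():
        ft = batch.truth.families[gene]
        ref_pep = translate_cds(ft.root_cds)[:-1]
        frags = [rec(seqs[t], t, taxon) for t in sorted(tids)]
        m = mb.merge_super_transcript(frags, ref_pep)
        core = m.residues.strip("?")
        assert "?" not in core
        assert core in ft.cds[taxon]


# ---------------------------------------------------------------------------
# alignment

def _aln_from(seq_by_taxon, ref_pep):
    recs = {t: rec(s, f"{t}|t1", t) for t, s in seq_by_taxon.items()}
    return mb.align_gene("g", recs, ref_pep)


def test_align_identical_sequences_no_gaps():
    aln = _aln_from({"A": CDS, "B": CDS, "C": CDS}, PEP)
    assert set(aln.rows["A"]) <= set("ACGT")
    assert aln.rows["A"] == aln.rows["B"] == aln.rows["C"]


def test_align_one_codon_deletion_gives_single_triplet_gap():
    deleted = CDS[:60] + CDS[63:]
    aln = _aln_from({"A": CDS, "B": deleted}, PEP)
    assert aln.rows["B"].count("-") == 3
    assert "---" in aln.rows["B"]
    assert aln.rows["A"].count("-") == 0


def test_align_gap_runs_are_codon_phased():
    deleted = CDS[:30] + CDS[39:]   # 3-codon deletion
    aln = _aln_from({"A": CDS, "B": deleted, "C": CDS}, PEP)
    for row in aln.rows.values():
        run = 0
        for ch in row + "X":
            if ch == "-":
                run += 1
            else:
                if run:
                    assert run % 3 == 0
                run = 0


def test_align_excludes_rows_with_internal_stop():
    broken = CDS[:30] + "TAA" + CDS[33:]
    aln = _aln_from({"A": CDS, "B": CDS, "C": broken}, PEP)
    assert "C" in aln.excluded
    assert set(aln.rows) == {"A", "B"}


# ---------------------------------------------------------------------------
# trimming

def test_trim_removes_noncoding_flanks():
    flanked = {t: "NNN" + CDS + "GGG" for t in "AB"}
    aln = _aln_from(flanked, PEP)  # placement already clips; build manually
    rows = {t: "NNN" + CDS + "GGG" for t in "AB"}
    ga = mb.GeneAlignment("g", rows)
    trimmed = mb.trim_to_cds(ga)
    assert trimmed.rows["A"] == CDS
    assert trimmed.length % 3 == 0


def test_trim_without_stop_keeps_tail_codons():
    rows = {t: CDS[:-3] for t in "AB"}   # reference-like partial: no stop
    trimmed = mb.trim_to_cds(mb.GeneAlignment("g", rows))
    assert trimmed.rows["A"] == CDS[:-3]


def test_trim_no_start_flags_partial():
    rows = {t: CDS[30:-3] for t in "AB"}
    trimmed = mb.trim_to_cds(mb.GeneAlignment("g", rows))
    assert "partial" in trimmed.gene
    assert trimmed.length == len(CDS) - 33


# ---------------------------------------------------------------------------
# translation

@pytest.mark.parametrize("codons,expected", [
    ("ATGTAA", "M?"),      # stop recoded as missing
    ("AAA---", "K-"),      # all-gap codon stays a gap
    ("AAAAT-", "K?"),      # mixed gap/nucleotide codon is unknown
])
def test_translate_alignment_examples(codons, expected):
    ga = mb.GeneAlignment("g", {"A": codons, "B": "ATG" * (len(codons) // 3)})
    assert mb.translate_alignment(ga)["A"] == expected


def test_translate_requires_codon_multiple():
    ga = mb.GeneAlignment("g", {"A": "ATGA", "B": "ATGA"})
    with pytest.raises(ValueError):
        mb.translate_alignment(ga)


def test_translate_trim_commutes_with_row_subsetting():
    # aligned rows: C has one gap codon and a missing tail
    rows = {"A": CDS, "B": CDS, "C": CDS[:60] + "---" + CDS[63:-3] + "???"}
    full = mb.translate_alignment(mb.trim_to_cds(mb.GeneAlignment("g", rows)))
    sub_rows = {t: rows[t] for t in ("A", "C")}
    sub = mb.translate_alignment(mb.trim_to_cds(mb.GeneAlignment("g", sub_rows)))
    assert sub["A"] == full["A"] and sub["C"] == full["C"]


# ---------------------------------------------------------------------------
# concatenation

def _ga(gene, taxa, length, fill="ATG"):
    row = (fill * (length // 3 + 1))[:length]
    return mb.GeneAlignment(gene, {t: row for t in taxa})


def test_concatenate_partition_arithmetic():
    g1 = _ga("g1", "ABCDEFGH", 300)
    g2 = _ga("g2", "ABCDEFGH", 600)
    sm = mb.concatenate([g1, g2], list("ABCDEFGH"))
    assert sm.n_columns == 900
    assert [b.intervals for b in sm.by_gene.blocks] == [[(1, 300)], [(301, 900)]]
    assert [len(sm.by_codon.columns(b)) for b in sm.by_codon.blocks] == \
        [300, 300, 300]


def test_concatenate_missing_taxon_fill_proportion():
    g1 = _ga("g1", "ABCDEFGH", 300)
    g2 = _ga("g2", "ABCDEFG", 600)    # H missing the 600-nt gene
    sm = mb.concatenate([g1, g2], list("ABCDEFGH"))
    assert sm.rows["H"][300:] == "?" * 600
    assert sm.missing_proportion() == pytest.approx(600 / 7200)


def test_deconcatenate_recovers_each_gene():
    g1 = _ga("g1", "ABCD", 30)
    g2 = _ga("g2", "ABCD", 60, fill="GCA")
    sm = mb.concatenate([g1, g2], list("ABCD"))
    parts = mb.deconcatenate(sm)
    assert parts[0] == g1.rows
    assert parts[1] == g2.rows


def test_concatenate_rejects_non_codon_length():
    bad = mb.GeneAlignment("g", {"A": "ATGA", "B": "ATGA"})
    with pytest.raises(ValueError):
        mb.concatenate([bad], ["A", "B"])
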