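"""Generator ground truth: chronogram ages, substitution model, noise layers."""

import numpy as np
import pytest

import opilio.synthetic_data as sd


# ---------------------------------------------------------------------------
# chronogram

def test_classical_chronogram_ages(chronogram):
    assert chronogram.root_age == pytest.approx(5.01)
    # Palpatores node: MRCA of the five palpatorid taxa
    tree = chronogram.tree
    mrca = tree.mrca(taxon_labels=sorted(sd.CLADES["Palpatores"]))
    assert chronogram.node_age(mrca) == pytest.approx(3.60)
    for clade, age in [("Eupnoi", 0.97), ("Dyspnoi", 2.94),
                       ("Troguloidea", 1.44), ("Laniatores", 2.37),
                       ("Phalangida", 4.88)]:
        mrca = tree.mrca(taxon_labels=sorted(sd.CLADES[clade]))
        assert chronogram.node_age(mrca) == pytest.approx(age)


def test_chronogram_ultrametric(chronogram):
    assert chronogram.is_ultrametric(1e-9)
    assert sorted(chronogram.leaf_labels) == sorted(sd.TAXA)


# ---------------------------------------------------------------------------
# gene-family evolution

def test_zero_rate_gives_identical_taxa(chronogram):
    fam = sd.evolve_gene_family(chronogram, 0.0, 120, 5)
    root = fam.pop("__root__")
    assert all(seq == root for seq in fam.values())
    assert root.startswith("ATG")
    assert root[-3:] in sd.STOP_CODONS


def test_no_internal_stops_and_fixed_boundaries(chronogram):
    fam = sd.evolve_gene_family(chronogram, 0.08, 150, 7)
    for taxon, seq in fam.items():
        assert seq.startswith("ATG")
        assert seq[-3:] in sd.STOP_CODONS
        internal = [seq[i:i + 3] for i in range(3, len(seq) - 3, 3)]
        assert not any(c in sd.STOP_CODONS for c in internal)


def test_evolution_deterministic_under_seed(chronogram):
    a = sd.evolve_gene_family(chronogram, 0.05, 130, 99)
    b = sd.evolve_gene_family(chronogram, 0.05, 130, 99)
    assert a == b


def test_pairwise_divergence_matches_closed_form():
    """Two taxa separated by total time t under the symmetric model:
    E[p] = (3/4)(1 - e^(-(8/3) lambda t)); at lambda*t = 0.1 per branch
    p ~ 0.1756.  Monte-Carlo mean over 200 replicate genes, internal sites
    only (the start and stop codons are held invariant)."""
    two_taxon = sd.Chronogram(
        __import__("dendropy").Tree.get(data="(A:1.0,B:1.0);", schema="newick"))
    lam = 0.1
    expected = 0.75 * (1 - np.exp(-(8.0 / 3.0) * lam * 1.0))
    assert expected == pytest.approx(0.1756, abs=2e-4)
    rng = np.random.default_rng(12)
    diffs = comps = 0
    for _ in range(200):
        fam = sd.evolve_gene_family(two_taxon, lam, 100, rng)
        a, b = fam["A"][3:-3], fam["B"][3:-3]
        diffs += sum(1 for x, y in zip(a, b) if x != y)
        comps += len(a)
    p_hat = diffs / comps
    # the no-internal-stop constraint suppresses substitutions in
    # stop-adjacent codons by a few percent relative; the realized mean must
    # still sit within 0.01 absolute of the unconstrained closed form
    assert p_hat == pytest.approx(expected, abs=0.01)
    # and strictly between half and full closed-form divergence
    assert 0.5 * expected < p_hat <= expected + 0.005


def test_rate_ordering_preserved(chronogram):
    """Genes simulated at a higher rate realize higher mean divergence."""
    rng = np.random.default_rng(3)
    def mean_div(rate):
        out = []
        for _ in range(50):
            fam = sd.evolve_gene_family(chronogram, rate, 100, rng)
            fam.pop("__root__")
            seqs = list(fam.values())
            d = np.mean([sum(a != b for a, b in zip(seqs[0], s)) / len(s)
                         for s in seqs[1:]])
            out.append(d)
        return out
    slow, fast = mean_div(0.01), mean_div(0.05)
    wins = sum(f > s for f, s in zip(fast, slow))
    # sign test: 50 paired batches, P(wins >= 40 | p=0.5) << 0.01
    assert wins >= 40


# ---------------------------------------------------------------------------
# transcriptome noise layers

def test_truth_classification_complete(small_batch):
    """Every emitted transcript is classified exactly once."""
    truth = small_batch.truth
    for taxon, records in small_batch.transcriptomes.items():
        for rec in records:
            assert truth.classify(rec.identifier) in (
                "ortholog", "paralog", "contaminant"), rec.identifier


def test_fragments_jointly_cover_cds(small_batch):
    truth = small_batch.truth
    by_gene_taxon = {}
    for tid, (gene, taxon, iv) in truth.fragment_map.items():
        by_gene_taxon.setdefault((gene, taxon), []).append(iv)
    assert by_gene_taxon, "expected some fragmented genes at frag_prob=0.2"
    for (gene, taxon), ivals in by_gene_taxon.items():
        L = len(truth.families[gene].cds[taxon])
        ivals.sort()
        assert ivals[0][0] == 0 and ivals[-1][1] == L
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            assert s2 <= e1  # overlapping or adjacent


def test_fragmentation_probability_zero_gives_single_transcripts():
    noise = sd.NoiseParams(frag_prob=0.0, dup_prob=0.0)
    batch = sd.simulate_batch(10, 0, 0, seed=4, noise=noise)
    for ft in batch.truth.families.values():
        assert all(len(tids) == 1 for tids in ft.transcripts.values())
    assert not batch.truth.fragment_map


def test_fragment_overlap_exceeding_cds_is_an_error():
    noise = sd.NoiseParams(frag_overlap=(500, 600), frag_prob=1.0)
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        sd._fragment_cds("ATG" + "AAA" * 100 + "TAA", noise, rng)


def test_paralog_divergence_detectable_by_direct_identity():
    """With paralog probability forced, the paralog copy's identity to the
    ortholog stays below 0.98 over the CDS (oracle: direct comparison)."""
    noise = sd.NoiseParams(paralog_extra=0.15, paralog_taxon_prob=1.0,
                           frag_prob=0.0, dup_prob=0.0)
    batch = sd.simulate_batch(2, 8, 0, seed=9, noise=noise)
    checked = 0
    seqs = {r.identifier: r.residues
            for recs in batch.transcriptomes.values() for r in recs}
    for tid, gene in batch.truth.paralog_transcripts.items():
        taxon = tid.split("|")[0]
        true_cds = batch.truth.families[gene].cds[taxon]
        par = seqs[tid]
        # locate CDS-length window: paralog transcript is UTR+cds'+UTR
        best = 0.0
        for off in range(len(par) - len(true_cds) + 1):
            w = par[off:off + len(true_cds)]
            ident = sum(a == b for a, b in zip(w, true_cds)) / len(true_cds)
            best = max(best, ident)
        assert best < 0.98
        checked += 1
    assert checked >= 8


def test_simulation_byte_identical_under_seed(tmp_path):
    from opilio.io_formats import write_fasta
    for i, run in enumerate("ab"):
        batch = sd.simulate_batch(5, 1, 2, seed=77)
        p = tmp_path / f"{run}.fasta"
        write_fasta([r for recs in batch.transcriptomes.values() for r in recs], p)
    a = (tmp_path / "a.fasta").read_bytes()
    b = (tmp_path / "b.fasta").read_bytes()
    assert a == b


def test_outgroup_cds_present_and_divergent(small_batch):
    for ft in small_batch.truth.families.values():
        assert len(ft.outgroup_cds) == len(ft.root_cds)
        assert ft.outgroup_cds != ft.root_cds
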