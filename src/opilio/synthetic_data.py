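"""Synthetic eight-taxon transcriptomes with known ground truth.

Emulates the inputs of a harvestman (Opiliones) transcriptome phylogenomics
study: eight taxa spanning the four suborders, each contributing an assembled
transcript set containing shared single-copy ortholog coding sequences with
UTR flanks, fragmented transcripts (the highly fragmented normalized-library
condition), redundant alternative transcripts differing only in UTRs,
divergent paralogs, and contaminant sequences.  Every emitted transcript is
classified in a :class:`SyntheticTruth` table so downstream screening stages
can be scored against known answers.

Coding sequences evolve along an ultrametric species chronogram under the
4-state symmetric (Jukes-Cantor-type) substitution model, sites independent,
with internal stop codons disallowed.  Time is measured in units of 100 Myr.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io_formats import Alphabet, SequenceRecord

# ---------------------------------------------------------------------------
# chronogram

#: study taxa, one per terminal of the classical Opiliones phylogeny
TAXA = ("Siro", "Leiobunum", "Protolophus", "Hesperonemastoma",
        "Ortholasma", "Trogulus", "Sitalcina", "Sclerobunus")

#: named clades of the classical hypothesis (used for support reporting)
CLADES: dict[str, frozenset[str]] = {
    "Eupnoi": frozenset({"Leiobunum", "Protolophus"}),
    "Troguloidea": frozenset({"Ortholasma", "Trogulus"}),
    "Dyspnoi": frozenset({"Hesperonemastoma", "Ortholasma", "Trogulus"}),
    "Palpatores": frozenset({"Leiobunum", "Protolophus", "Hesperonemastoma",
                             "Ortholasma", "Trogulus"}),
    "Laniatores": frozenset({"Sitalcina", "Sclerobunus"}),
    "Phalangida": frozenset(set(TAXA) - {"Siro"}),
}

#: node ages in 100-Myr units (autocorrelated-rates dating, calibration 1)
NODE_AGES = {
    "Opiliones": 5.01,
    "Phalangida": 4.88,
    "Palpatores": 3.60,
    "Eupnoi": 0.97,
    "Dyspnoi": 2.94,
    "Troguloidea": 1.44,
    "Laniatores": 2.37,
}


class Chronogram:
    """A rooted ultrametric species tree with node ages in 100-Myr units."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._ages: dict[dendropy.Node, float] = {}
        # ages from leaf depths: leaves at 0
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                self._ages[nd] = 0.0
            else:
                kids = nd.child_nodes()
                self._ages[nd] = max(self._ages[c] + (c.edge.length or 0.0)
                                     for c in kids)

    @property
    def root_age(self) -> float:
        return self._ages[self.tree.seed_node]

    def node_age(self, node: dendropy.Node) -> float:
        return self._ages[node]

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = []
        for lf in self.tree.leaf_node_iter():
            d, nd = 0.0, lf
            while nd.parent_node is not None:
                d += nd.edge.length or 0.0
                nd = nd.parent_node
            depths.append(d)
        return max(depths) - min(depths) <= tol

    def edges(self) -> list[tuple[dendropy.Node, dendropy.Node, float]]:
        """(parent, child, duration) triples in preorder."""
        out = []
        for nd in self.tree.preorder_node_iter():
            for c in nd.child_nodes():
                out.append((nd, c, c.edge.length or 0.0))
        return out


def classical_chronogram() -> Chronogram:
    """The classical Opiliones topology with dated nodes.

    Topology (Cyphophthalmi,(Palpatores,Laniatores)) with Palpatores =
    (Eupnoi,Dyspnoi); ages from the autocorrelated-rates dating analysis
    (calibration 1, replicate 1): root 501 Myr, Phalangida 488, Palpatores
    360, Eupnoi 97, Dyspnoi 294, Troguloidea 144, Laniatores 237.
    """
    a = NODE_AGES
    newick = (
        "(Siro:{root:.10g},"
        "(((Leiobunum:{eup:.10g},Protolophus:{eup:.10g}):{eup_b:.10g},"
        "(Hesperonemastoma:{dys:.10g},"
        "(Ortholasma:{tro:.10g},Trogulus:{tro:.10g}):{tro_b:.10g}):{dys_b:.10g}"
        "):{palp_b:.10g},"
        "(Sitalcina:{lan:.10g},Sclerobunus:{lan:.10g}):{lan_b:.10g}"
        "):{phal_b:.10g});"
    ).format(
        root=a["Opiliones"], eup=a["Eupnoi"], eup_b=a["Palpatores"] - a["Eupnoi"],
        dys=a["Dyspnoi"], tro=a["Troguloidea"], tro_b=a["Dyspnoi"] - a["Troguloidea"],
        dys_b=a["Palpatores"] - a["Dyspnoi"], palp_b=a["Phalangida"] - a["Palpatores"],
        lan=a["Laniatores"], lan_b=a["Phalangida"] - a["Laniatores"],
        phal_b=a["Opiliones"] - a["Phalangida"],
    )
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return Chronogram(tree)


# ---------------------------------------------------------------------------
# codon machinery

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
_ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
SENSE_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS; codons with N or ? become X, stops '*'."""
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3]
        out.append(_CODON_TABLE.get(codon, "X"))
    return "".join(out)


def jc_expected_p(rate: float, t: float) -> float:
    """Expected p-distance between sequences separated by total time t."""
    return 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * rate * t))


# ---------------------------------------------------------------------------
# gene-family evolution

_B2I = {b: i for i, b in enumerate(BASES)}


def _random_root_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random sense codons + random stop."""
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop


def _mutate_branch(seq: np.ndarray, rate: float, t: float,
                   rng: np.random.Generator) -> np.ndarray:
    """One branch of symmetric 4-state evolution on an integer-coded CDS.

    The first codon (start) and last codon (stop) are held invariant,
    emulating strong purifying selection on translation boundaries; any
    substitution creating an internal stop codon is resampled.
    """
    p = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * rate * t))
    out = seq.copy()
    n = len(seq)
    mutable = np.zeros(n, dtype=bool)
    mutable[3:n - 3] = True
    hit = (rng.random(n) < p) & mutable
    idx = np.nonzero(hit)[0]
    # new base uniform among the three alternatives
    shifts = rng.integers(1, 4, size=idx.size)
    out[idx] = (out[idx] + shifts) % 4

    # resample any internal codon that became a stop
    stop_codes = {tuple(_B2I[b] for b in s) for s in STOP_CODONS}
    for _ in range(64):
        bad = []
        for c in range(1, n // 3 - 1):
            tri = tuple(out[3 * c:3 * c + 3])
            if tri in stop_codes:
                bad.append(c)
        if not bad:
            break
        for c in bad:
            sl = slice(3 * c, 3 * c + 3)
            out[sl] = seq[sl]
            hit_c = rng.random(3) < p
            shifts_c = rng.integers(1, 4, size=3)
            tri = out[sl].copy()
            tri[hit_c] = (tri[hit_c] + shifts_c[hit_c]) % 4
            out[sl] = tri
    else:  # pragma: no cover - p would have to be ~1
        raise RuntimeError("could not resample internal stop codons")
    return out


def evolve_gene_family(chronogram: Chronogram, rate: float, cds_len: int,
                       seed: int | np.random.Generator) -> dict[str, str]:
    """Evolve one single-copy gene family along the chronogram.

    Returns a mapping taxon -> CDS, plus the ancestral sequence under the
    key ``"__root__"``.  ``cds_len`` counts codons (>= 100); ``rate`` is in
    substitutions/site per 100 Myr.
    """
    if cds_len < 100:
        raise ValueError("cds_len must be >= 100 codons")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = _random_root_cds(cds_len, rng)
    root_arr = np.array([_B2I[b] for b in root], dtype=np.int8)

    states: dict[dendropy.Node, np.ndarray] = {chronogram.tree.seed_node: root_arr}
    out: dict[str, str] = {"__root__": root}
    for parent, child, dur in chronogram.edges():
        child_arr = _mutate_branch(states[parent], rate, dur, rng)
        states[child] = child_arr
        if child.is_leaf():
            out[child.taxon.label] = "".join(BASES[i] for i in child_arr)
    return out


# ---------------------------------------------------------------------------
# transcriptome assembly with noise

@dataclass
class NoiseParams:
    """Generator noise settings (lengths in nt, probabilities in [0,1])."""

    utr_len: tuple[int, int] = (20, 90)
    frag_prob: float = 0.2
    frag_overlap: tuple[int, int] = (30, 90)
    dup_prob: float = 0.1
    paralog_extra: float = 0.15       # extra expected subs/site on paralog copies
    paralog_taxon_prob: float = 0.5   # chance each taxon carries the paralog copy
    contaminant_len: tuple[int, int] = (200, 1000)


@dataclass
class FamilyTruth:
    gene: str
    single_copy: bool
    rate: float
    root_cds: str
    cds: dict[str, str]                       # taxon -> true ortholog CDS
    transcripts: dict[str, list[str]] = field(default_factory=dict)
    outgroup_cds: str = ""                    # distant-outgroup ortholog


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated batch.

    Every emitted transcript id appears in exactly one of: a family's
    ortholog transcript list, the paralog registry image, or the
    contaminant set.
    """

    chronogram: Chronogram
    families: dict[str, FamilyTruth] = field(default_factory=dict)
    paralog_transcripts: dict[str, str] = field(default_factory=dict)  # tid -> gene
    paralog_registry: dict[str, dict] = field(default_factory=dict)    # gene -> info
    fragment_map: dict[str, tuple[str, str, tuple[int, int]]] = field(
        default_factory=dict)  # tid -> (gene, taxon, 0-based half-open CDS interval)
    contaminants: set[str] = field(default_factory=set)

    def classify(self, tid: str) -> str:
        in_family = any(tid in ft.transcripts.get(ft_taxon, [])
                        for ft in self.families.values()
                        for ft_taxon in ft.transcripts)
        classes = [in_family, tid in self.paralog_transcripts,
                   tid in self.contaminants]
        if sum(classes) != 1:
            return "unclassified" if sum(classes) == 0 else "multiple"
        return ("ortholog", "paralog", "contaminant")[classes.index(True)]


def _random_utr(lo: int, hi: int, rng: np.random.Generator) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


#: shortest fragment the generator emits (assemblers do not produce
#: ultrashort contigs; the emulated assemblies kept transcripts > 100 bp)
MIN_FRAGMENT_NT = 150


def _fragment_cds(cds: str, noise: NoiseParams,
                  rng: np.random.Generator) -> list[tuple[int, int]]:
    """Split a CDS into 2-3 jointly covering intervals with declared overlaps.

    Returns 0-based half-open intervals on the CDS, in order; consecutive
    intervals overlap by a value drawn from ``noise.frag_overlap`` (an
    overlap of 0 means exactly adjacent).  Every piece is at least
    ``MIN_FRAGMENT_NT`` long before overlap extension.
    """
    lo, hi = noise.frag_overlap
    L = len(cds)
    if hi >= L:
        raise ValueError(f"fragment overlap range ({lo},{hi}) exceeds CDS length {L}")
    n_frag = int(rng.integers(2, 4))
    while n_frag > 2 and L < n_frag * MIN_FRAGMENT_NT:
        n_frag -= 1
    cuts: list[int] = []
    prev = 0
    for i in range(n_frag - 1):
        remaining = (n_frag - 1 - i) * MIN_FRAGMENT_NT
        c = int(rng.integers(prev + MIN_FRAGMENT_NT, L - remaining + 1))
        cuts.append(c)
        prev = c
    bounds = [0] + cuts + [L]
    intervals = []
    for i in range(n_frag):
        s, e = bounds[i], bounds[i + 1]
        if i > 0:
            ov = int(rng.integers(lo, hi + 1))
            s = max(0, s - ov)
        intervals.append((s, e))
    return intervals


def reconstructs_cds_exactly(row: str, true_cds: str) -> bool:
    """Whether an assembled/aligned row matches the true CDS exactly.

    Gap characters are ignored; '?' runs mark reference-implied regions no
    fragment covered (legitimate missing data).  Every covered segment must
    occur in the true CDS, in order and without overlap — i.e. the
    reconstruction made no sequence errors over what it covers.
    """
    core = row.replace("-", "")
    pos = 0
    any_seg = False
    for seg in (s for s in core.split("?") if s):
        any_seg = True
        idx = true_cds.find(seg, pos)
        if idx < 0:
            return False
        pos = idx + len(seg)
    return any_seg


def true_supermatrix_rows(truth: SyntheticTruth, include_outgroup: bool = True,
                          outgroup_taxon: str = "Outgroup",
                          single_copy_only: bool = True) -> dict[str, str]:
    """Concatenated true coding sequences, one row per taxon.

    Family CDSs evolve without indels and are therefore colinear; this is
    the noise-free supermatrix implied by the truth table, useful as a
    known-answer input for distance and tree machinery.
    """
    rows: dict[str, list[str]] = {t: [] for t in TAXA}
    if include_outgroup:
        rows[outgroup_taxon] = []
    for gene in sorted(truth.families):
        ft = truth.families[gene]
        if single_copy_only and not ft.single_copy:
            continue
        for t in TAXA:
            rows[t].append(ft.cds[t])
        if include_outgroup:
            rows[outgroup_taxon].append(ft.outgroup_cds)
    return {t: "".join(parts) for t, parts in rows.items()}


@dataclass
class SyntheticBatch:
    transcriptomes: dict[str, list[SequenceRecord]]
    reference: list[SequenceRecord]       # amino-acid reference set
    truth: SyntheticTruth
    decoy_ids: set[str]


def simulate_batch(n_single_copy: int = 300, n_paralogous: int = 30,
                   n_contaminant: int = 20, *, seed: int = 0,
                   cds_len: tuple[int, int] = (150, 400),
                   rate_meanlog: float = -3.6, rate_sdlog: float = 0.6,
                   noise: NoiseParams | None = None,
                   n_decoys: int = 25,
                   chronogram: Chronogram | None = None,
                   outgroup_time: float = 2.0) -> SyntheticBatch:
    """Simulate a full eight-taxon batch with known truth.

    Per-gene rates are lognormal so a default batch spans realized average
    pairwise divergences of roughly 0.05-0.45, emulating a fast/medium/slow
    spread.  The reference protein set is the translated ancestral CDS of
    every family plus ``n_decoys`` random decoy proteins, standing in for an
    annotated outgroup peptide set.  Each family also carries a
    distant-outgroup ortholog (the ancestral CDS evolved along an outgroup
    stem of ``outgroup_time`` extra 100-Myr units) so supermatrices can be
    rooted on a distant reference taxon, as such matrices usually are.
    """
    rng = np.random.default_rng(seed)
    noise = noise or NoiseParams()
    chrono = chronogram or classical_chronogram()
    truth = SyntheticTruth(chronogram=chrono)

    n_fam = n_single_copy + n_paralogous
    rates = np.exp(rng.normal(rate_meanlog, rate_sdlog, size=n_fam))
    lens = rng.integers(cds_len[0], cds_len[1] + 1, size=n_fam)
    paralog_idx = set(rng.choice(n_fam, size=n_paralogous, replace=False).tolist())

    transcriptomes: dict[str, list[SequenceRecord]] = {t: [] for t in TAXA}
    counters = {t: 0 for t in TAXA}
    reference: list[SequenceRecord] = []

    def new_tid(taxon: str) -> str:
        counters[taxon] += 1
        return f"{taxon}|t{counters[taxon]:05d}"

    def emit(taxon: str, seq: str) -> str:
        tid = new_tid(taxon)
        transcriptomes[taxon].append(
            SequenceRecord(tid, seq, Alphabet.nt, taxon=taxon))
        return tid

    for g in range(n_fam):
        gene = f"g{g:04d}"
        fam = evolve_gene_family(chrono, float(rates[g]), int(lens[g]), rng)
        root_cds = fam.pop("__root__")
        is_paralogous = g in paralog_idx
        ft = FamilyTruth(gene=gene, single_copy=not is_paralogous,
                         rate=float(rates[g]), root_cds=root_cds, cds=dict(fam))
        root_arr = np.array([_B2I[c] for c in root_cds], dtype=np.int8)
        out_arr = _mutate_branch(root_arr, float(rates[g]), outgroup_time, rng)
        ft.outgroup_cds = "".join(BASES[i] for i in out_arr)
        truth.families[gene] = ft
        reference.append(SequenceRecord(
            f"ref|{gene}", translate_cds(root_cds)[:-1], Alphabet.aa))

        paralog_taxa: list[str] = []
        if is_paralogous:
            paralog_taxa = [t for t in TAXA
                            if rng.random() < noise.paralog_taxon_prob]
            if not paralog_taxa:
                paralog_taxa = [TAXA[int(rng.integers(len(TAXA)))]]
            truth.paralog_registry[gene] = {
                "taxa": set(paralog_taxa), "extra_divergence": noise.paralog_extra,
            }

        for taxon in TAXA:
            cds = fam[taxon]
            ft.transcripts[taxon] = []

            fragmented = rng.random() < noise.frag_prob
            if fragmented:
                intervals = _fragment_cds(cds, noise, rng)
                for i, (s, e) in enumerate(intervals):
                    piece = cds[s:e]
                    utr5 = _random_utr(*noise.utr_len, rng) if i == 0 else ""
                    utr3 = (_random_utr(*noise.utr_len, rng)
                            if i == len(intervals) - 1 else "")
                    tid = emit(taxon, utr5 + piece + utr3)
                    ft.transcripts[taxon].append(tid)
                    truth.fragment_map[tid] = (gene, taxon, (s, e))
            else:
                utr5 = _random_utr(*noise.utr_len, rng)
                utr3 = _random_utr(*noise.utr_len, rng)
                tid = emit(taxon, utr5 + cds + utr3)
                ft.transcripts[taxon].append(tid)
                if rng.random() < noise.dup_prob:
                    # redundant alternative transcript: same CDS, new UTRs
                    tid2 = emit(taxon, _random_utr(*noise.utr_len, rng) + cds
                                + _random_utr(*noise.utr_len, rng))
                    ft.transcripts[taxon].append(tid2)

            if is_paralogous and taxon in paralog_taxa:
                arr = np.array([_B2I[b] for b in cds], dtype=np.int8)
                par = _mutate_branch(arr, 1.0, noise.paralog_extra, rng)
                par_cds = "".join(BASES[i] for i in par)
                tid = emit(taxon, _random_utr(*noise.utr_len, rng) + par_cds
                           + _random_utr(*noise.utr_len, rng))
                truth.paralog_transcripts[tid] = gene

    # contaminants: random-composition sequences spread across taxa
    for i in range(n_contaminant):
        taxon = TAXA[i % len(TAXA)]
        n = int(rng.integers(*noise.contaminant_len))
        seq = "".join(BASES[j] for j in rng.integers(0, 4, size=n))
        tid = emit(taxon, seq)
        truth.contaminants.add(tid)

    decoy_ids: set[str] = set()
    aa = "ACDEFGHIKLMNPQRSTVWY"
    for i in range(n_decoys):
        n = int(rng.integers(cds_len[0], cds_len[1] + 1))
        pep = "".join(aa[j] for j in rng.integers(0, 20, size=n))
        rid = f"decoy|d{i:03d}"
        reference.append(SequenceRecord(rid, pep, Alphabet.aa))
        decoy_ids.add(rid)

    return SyntheticBatch(transcriptomes=transcriptomes, reference=reference,
                          truth=truth, decoy_ids=decoy_ids)
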