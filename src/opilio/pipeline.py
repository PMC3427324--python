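"""End-to-end orchestration: simulate -> search -> filter -> build ->
rates -> tree, with one config, one seed, and a manifest of artifacts.

Each stage writes its outputs under the run directory and records
input/output file hashes in the manifest, so identical (config, seed)
pairs reproduce identical manifests and reruns of any stage can be
checked against the chain.  The global seed is fanned out to per-stage
seeds through :class:`numpy.random.SeedSequence` spawning.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats as io
from . import synthetic_data as sd
from .homology_search import seeded_translated_search
from .matrix_builder import (GeneAlignment, MergeError, align_gene, concatenate,
                             extract_cds_estimate, merge_super_transcript,
                             trim_to_cds)
from .ortholog_filter import (CandidateGene, FilterParams, apply_tick_filter,
                              enforce_uniqueness, group_hits)
from .rates_informativeness import (avg_pairwise_divergence, bin_genes_by_rate,
                                    estimate_site_rates, pi_profile)
from .tree_inference import bootstrap_support

STAGES = ("simulate", "search", "filter", "build", "rates", "tree")


class PipelineError(RuntimeError):
    pass


def stage_seeds(seed: int, n: int = len(STAGES)) -> list[int]:
    """Fan one global seed out to per-stage seeds (all < 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[dict] = field(default_factory=list)
    counts: dict = field(default_factory=dict)

    def add_stage(self, name: str, inputs: list[Path], outputs: list[Path]) -> None:
        self.stages.append({
            "stage": name,
            "inputs": {p.name: _hash_file(p) for p in inputs},
            "outputs": {p.name: _hash_file(p) for p in outputs},
        })

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "seed": self.seed,
             "stages": self.stages, "counts": self.counts}, indent=2))


def candidates_to_alignments(retained: list[CandidateGene],
                             sequences: dict[str, str],
                             reference: dict[str, io.SequenceRecord],
                             audit: io.AuditLog | None = None,
                             outgroup: dict[str, str] | None = None,
                             outgroup_taxon: str = "Outgroup"
                             ) -> list[GeneAlignment]:
    """Extract chosen per-taxon sequences (merging fragments into
    super-transcripts), align each gene against its reference, and trim.

    ``outgroup`` optionally maps reference query ids to an outgroup coding
    sequence included as an extra row (for outgroup-rooted matrices).
    """
    audit = audit if audit is not None else io.AuditLog()
    out: list[GeneAlignment] = []
    for cand in retained:
        ref_pep = reference[cand.query].residues
        per_taxon: dict[str, io.SequenceRecord] = {}
        ok = True
        if outgroup and cand.query in outgroup:
            est = extract_cds_estimate(
                io.SequenceRecord(f"{outgroup_taxon}|{cand.query}",
                                  outgroup[cand.query], io.Alphabet.nt,
                                  taxon=outgroup_taxon), ref_pep)
            if est is not None:
                per_taxon[outgroup_taxon] = est
        for taxon, tids in cand.chosen.items():
            if len(tids) == 1:
                est = extract_cds_estimate(
                    io.SequenceRecord(tids[0], sequences[tids[0]],
                                      io.Alphabet.nt, taxon=taxon), ref_pep)
                if est is None:
                    audit.record(cand.query, "align", "row_excluded",
                                 f"{taxon}: no translated placement")
                    continue
                per_taxon[taxon] = est
            else:
                frags = [io.SequenceRecord(t, sequences[t], io.Alphabet.nt,
                                           taxon=taxon) for t in tids]
                try:
                    per_taxon[taxon] = merge_super_transcript(
                        frags, ref_pep, identifier=f"{taxon}|st_{cand.query}")
                    audit.record(cand.query, "super_transcript", "merged",
                                 f"{taxon}: {len(tids)} fragments")
                except MergeError as exc:
                    audit.record(cand.query, "super_transcript", "merge_failure",
                                 f"{taxon}: {exc}")
                    ok = False
                    break
        if not ok:
            continue
        aln = align_gene(cand.query, per_taxon, ref_pep, audit=audit)
        aln = trim_to_cds(aln)
        if aln.rows:
            out.append(aln)
    return out


def run_pipeline(config: dict | None = None, seed: int = 0,
                 outdir: str | Path = "pipeline_out") -> RunManifest:
    """Execute all stages in order on a synthetic batch.

    Returns the manifest; any stage failure raises :class:`PipelineError`
    after saving a manifest recording the completed stages.
    """
    cfg = config or io.load_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    manifest = RunManifest(config=cfg, seed=seed)
    mpath = outdir / "manifest.json"

    try:
        # ---- simulate
        gen = cfg["generator"]
        noise = sd.NoiseParams(
            utr_len=(int(gen["utr_len_min"]), int(gen["utr_len_max"])),
            frag_prob=float(gen["frag_prob"]),
            frag_overlap=(int(gen["frag_overlap_min"]), int(gen["frag_overlap_max"])),
            dup_prob=float(gen["dup_prob"]),
            paralog_extra=float(gen["paralog_extra"]))
        batch = sd.simulate_batch(
            int(gen["n_single_copy"]), int(gen["n_paralogous"]),
            int(gen["n_contaminant"]), seed=seeds[0],
            cds_len=(int(gen["cds_len_min"]), int(gen["cds_len_max"])),
            rate_meanlog=float(gen["rate_meanlog"]),
            rate_sdlog=float(gen["rate_sdlog"]), noise=noise,
            n_decoys=int(gen["n_decoys"]))
        fasta_paths = []
        for taxon, records in batch.transcriptomes.items():
            p = outdir / f"transcriptome_{taxon}.fasta"
            io.write_fasta(records, p)
            fasta_paths.append(p)
        ref_path = outdir / "reference_proteins.fasta"
        io.write_fasta(batch.reference, ref_path)
        manifest.add_stage("simulate", [], fasta_paths + [ref_path])
        manifest.counts["transcripts"] = sum(
            len(r) for r in batch.transcriptomes.values())
        manifest.counts["reference_proteins"] = len(batch.reference)

        # ---- search
        scfg = cfg["search"]
        hits = seeded_translated_search(
            batch.reference, batch.transcriptomes, k=int(scfg["k"]),
            score_min_bits=float(scfg["score_min_bits"]),
            max_hits=int(scfg["max_hits"]))
        hits_path = outdir / "hits.tsv"
        io.write_hit_table(hits, hits_path)
        manifest.add_stage("search", fasta_paths + [ref_path], [hits_path])
        manifest.counts["hits"] = len(hits)

        # ---- filter
        fcfg = cfg["filter"]
        params = FilterParams(
            min_overlap_nt=int(fcfg["min_overlap_nt"]),
            min_region_nt=int(fcfg["min_region_nt"]),
            max_gap_fraction=float(fcfg["max_gap_fraction"]),
            paralog_identity_threshold=float(fcfg["paralog_identity_threshold"]),
            paralog_min_overlap_nt=int(fcfg["paralog_min_overlap_nt"]),
            reading_frame_excess=float(fcfg["reading_frame_excess"]),
            require_all_taxa=bool(fcfg["require_all_taxa"]),
            prefer_complete=bool(fcfg["prefer_complete"]),
            max_genes=int(fcfg["max_genes"]),
            anchor_taxon=str(fcfg["anchor_taxon"]))
        sequences = {r.identifier: r.residues
                     for recs in batch.transcriptomes.values() for r in recs}
        reference = {r.identifier: r for r in batch.reference}
        audit = io.AuditLog()
        candidates = group_hits(hits)
        rng = np.random.default_rng(seeds[2])
        retained = apply_tick_filter(candidates, params, sequences, reference,
                                     audit=audit, rng=rng)
        deduped, collisions = enforce_uniqueness({"TICK": retained})
        retained = deduped["TICK"]
        audit_path = outdir / "filter_audit.tsv"
        audit.write(audit_path)
        manifest_path = outdir / "retained_genes.tsv"
        with open(manifest_path, "w") as fh:
            fh.write("gene\tregion_nt\tcomplete\ttranscripts\n")
            for c in retained:
                tids = ";".join(",".join(v) for v in c.chosen.values())
                fh.write(f"{c.query}\t{c.region_nt}\t"
                         f"{int(c.has_start and c.has_stop)}\t{tids}\n")
        manifest.add_stage("filter", [hits_path], [audit_path, manifest_path])
        manifest.counts["candidates"] = len(candidates)
        manifest.counts["retained"] = len(retained)
        manifest.counts["uniqueness_collisions"] = len(collisions)

        # ---- build
        build_audit = io.AuditLog()
        alignments = candidates_to_alignments(retained, sequences, reference,
                                              audit=build_audit)
        taxa = sorted(batch.transcriptomes)
        sm = concatenate(alignments, taxa)
        phy = outdir / "supermatrix.phy"
        nex = outdir / "supermatrix.nex"
        part_gene = outdir / "partitions_by_gene.txt"
        part_codon = outdir / "partitions_by_codon.txt"
        io.write_phylip(sm.rows, phy)
        io.write_nexus(sm.rows, sm.by_codon, nex)
        io.write_partition_file(sm.by_gene, part_gene)
        io.write_partition_file(sm.by_codon, part_codon)
        manifest.add_stage("build", [manifest_path],
                           [phy, nex, part_gene, part_codon])
        manifest.counts["aligned_genes"] = len(alignments)
        manifest.counts["supermatrix_columns"] = sm.n_columns
        manifest.counts["missing_proportion"] = round(sm.missing_proportion(), 5)

        # ---- rates / informativeness
        chrono = batch.truth.chronogram
        gene_rows = []
        divs = {}
        for aln in alignments:
            divs[aln.gene] = avg_pairwise_divergence(aln.rows)
        bins = bin_genes_by_rate(divs, 3) if len(divs) >= 3 else [list(divs)]
        bin_of = {g: lbl for lbl, b in zip(("FAST", "MED", "SLOW"), bins)
                  for g in b}
        for aln in alignments:
            rates = estimate_site_rates(aln.rows, chrono)
            prof = pi_profile(rates, chrono)
            gene_rows.append((aln.gene, aln.length, divs[aln.gene],
                              bin_of.get(aln.gene, "NA"), prof.summed_net,
                              prof.summed_per_site,
                              prof.peak_time if prof.peak_time is not None
                              else float("nan")))
        rates_path = outdir / "gene_informativeness.tsv"
        with open(rates_path, "w") as fh:
            fh.write("gene\tlength_nt\tavg_pairwise_divergence\tbin\t"
                     "summed_net_pi\tsummed_per_site_pi\tpeak_time\n")
            for row in gene_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        manifest.add_stage("rates", [phy], [rates_path])
        manifest.counts["genes_profiled"] = len(gene_rows)

        # ---- tree
        tcfg = cfg["tree"]
        st = bootstrap_support(sm.rows,
                               replicates=int(tcfg["bootstrap_replicates"]),
                               seed=seeds[5],
                               codon_triples=bool(tcfg["codon_bootstrap"]),
                               ceiling=float(tcfg["saturation_ceiling"]))
        tree_path = outdir / "nj_bootstrap.nwk"
        tree_path.write_text(st.tree.newick(with_support=True) + "\n")
        manifest.add_stage("tree", [phy], [tree_path])
        manifest.counts["bootstrap_replicates"] = st.replicates
    except Exception as exc:
        manifest.counts["error"] = str(exc)
        manifest.save(mpath)
        raise PipelineError(f"pipeline failed: {exc}") from exc

    manifest.save(mpath)
    return manifest
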