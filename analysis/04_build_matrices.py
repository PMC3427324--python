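"""Build per-gene codon alignments and the partitioned supermatrix.

Merges fragmented genes into super-transcripts, aligns each retained gene
against its reference protein, trims to the coding region, appends the
distant-outgroup row, and concatenates.  Supermatrix exports (PHYLIP,
NEXUS, partition files) go to scratch/analysis/; the per-taxon matrix
summary (the super-transcript census) goes to results/.
"""

import argparse
import pickle
from pathlib import Path

from opilio import io_formats as io
from opilio.matrix_builder import concatenate, translate_alignment
from opilio.pipeline import candidates_to_alignments

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    with open(SCRATCH / "batch.pkl", "rb") as fh:
        batch = pickle.load(fh)
    with open(SCRATCH / "retained.pkl", "rb") as fh:
        retained = pickle.load(fh)
    seqs = {r.identifier: r.residues
            for recs in batch.transcriptomes.values() for r in recs}
    ref = {r.identifier: r for r in batch.reference}
    outgroup = {f"ref|{g}": ft.outgroup_cds
                for g, ft in batch.truth.families.items()}

    audit = io.AuditLog()
    alignments = candidates_to_alignments(retained, seqs, ref, audit=audit,
                                          outgroup=outgroup)
    taxa = sorted(batch.transcriptomes) + ["Outgroup"]
    sm = concatenate(alignments, taxa)
    io.write_phylip(sm.rows, SCRATCH / "supermatrix.phy")
    io.write_nexus(sm.rows, sm.by_codon, SCRATCH / "supermatrix.nex")
    io.write_partition_file(sm.by_gene, SCRATCH / "partitions_by_gene.txt")
    io.write_partition_file(sm.by_codon, SCRATCH / "partitions_by_codon.txt")
    aa_rows = {t: "".join(translate_alignment(a).get(t, "?" * (a.length // 3))
                          for a in alignments) for t in taxa}
    io.write_phylip(aa_rows, SCRATCH / "supermatrix_aa.phy")
    with open(SCRATCH / "alignments.pkl", "wb") as fh:
        pickle.dump((alignments, sm), fh)

    counts = sm.super_transcript_counts(alignments)
    with open(RESULTS / "04_matrix_summary.tsv", "w") as fh:
        fh.write("taxon\tn_super_transcripts\tn_genes\tfraction\n")
        for t in sorted(batch.transcriptomes):
            fh.write(f"{t}\t{counts[t]}\t{len(alignments)}\t"
                     f"{counts[t]/len(alignments):.4f}\n")
    print(f"aligned {len(alignments)} genes; supermatrix "
          f"{len(taxa)} x {sm.n_columns} nt; gap+missing proportion "
          f"{100*sm.missing_proportion():.2f}%")
    for t in sorted(counts):
        print(f"  {t}: {counts[t]} super-transcripts in {len(alignments)} genes")


if __name__ == "__main__":
    argparse.ArgumentParser().parse_args()
    main()
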