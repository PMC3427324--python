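"""Translated search of the reference proteome against all transcriptomes.

Runs the seeded translated search (the desk-scale tblastn stand-in) and
writes the 12-column hit table under scratch/analysis/ plus a per-taxon
summary under results/.
"""

import argparse
import pickle
import time
from pathlib import Path

import numpy as np

from opilio import io_formats as io
from opilio.homology_search import seeded_translated_search

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main() -> None:
    with open(SCRATCH / "batch.pkl", "rb") as fh:
        batch = pickle.load(fh)
    t0 = time.time()
    hits = seeded_translated_search(batch.reference, batch.transcriptomes)
    io.write_hit_table(hits, SCRATCH / "hits.tsv")
    with open(SCRATCH / "hits.pkl", "wb") as fh:
        pickle.dump(hits, fh)

    with open(RESULTS / "02_search_summary.tsv", "w") as fh:
        fh.write("taxon\tn_hits\tmedian_bits\tmedian_pident\n")
        for taxon in sorted(batch.transcriptomes):
            th = [h for h in hits if h.taxon == taxon]
            fh.write(f"{taxon}\t{len(th)}\t"
                     f"{np.median([h.bitscore for h in th]):.1f}\t"
                     f"{np.median([h.pident for h in th]):.1f}\n")
    n_decoy = sum(1 for h in hits if h.query.startswith("decoy"))
    print(f"{len(hits)} hits in {time.time()-t0:.0f}s "
          f"({n_decoy} to decoy references)")


if __name__ == "__main__":
    argparse.ArgumentParser().parse_args()
    main()
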