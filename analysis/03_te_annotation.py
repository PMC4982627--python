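#!/usr/bin/env python
"""Annotation arithmetic for the nine insertion alleles.

Builds promoter constructs with synthetic element sequence for each allele,
recovers their TSDs, predicts the PCR genotyping bands and classes, builds the
TSD consensus logo, and computes the transcript 5'-UTR models. Writes
results/te_annotation.tsv.
"""

import pathlib

import numpy as np
import pandas as pd

from rooscan.synthetic_data import build_promoter_construct, random_sequence
from rooscan.te_annotation import (
    NINE_INSERTIONS,
    ROO_PLUS7_WITH_DUP,
    InsertionRecord,
    build_tsd_logo,
    detect_tsd,
    predict_pcr_bands,
    transcript_utr_lengths,
)

SEED = 20160812


def main():
    rng = np.random.default_rng(SEED)
    element = random_sequence(428, rng)  # synthetic stand-in LTR sequence
    reference = random_sequence(600, rng)

    rows = []
    for rec in NINE_INSERTIONS + (ROO_PLUS7_WITH_DUP,):
        rec = InsertionRecord(
            rec.insertion_id, rec.offset_bp, rec.orientation,
            rec.element_length, rec.tsd, rec.extras_flank_dup_bp,
            rec.te_internal_tss, element,
        )
        point = 300 + rec.offset_bp
        tsd_here = reference[point : point + len(rec.tsd)]
        rec = InsertionRecord(
            rec.insertion_id, rec.offset_bp, rec.orientation,
            rec.element_length, tsd_here, rec.extras_flank_dup_bp,
            rec.te_internal_tss, element,
        )
        construct = build_promoter_construct(reference, rec, point)
        tsd, pt, _ = detect_tsd(reference, construct)
        pcr = predict_pcr_bands(rec)
        utr = transcript_utr_lengths(rec)
        rows.append({
            "insertion_id": rec.insertion_id,
            "offset_bp": rec.offset_bp,
            "orientation": rec.orientation,
            "tsd_detected": tsd,
            "tsd_length": len(tsd),
            "pcr_class": pcr["class"],
            "flr_bp": pcr["bands"].get("FL-R"),
            "lr_bp": pcr["bands"].get("L-R"),
            "te_tss_utr_bp": utr.get("te_tss_utr_bp"),
            "downstream_utr_bp": utr["downstream_tss_utr_bp"],
        })
    df = pd.DataFrame(rows)
    out = pathlib.Path("results/te_annotation.tsv")
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, sep="\t", index=False)
    print(f"wrote {out}")
    print(df.to_string(index=False))

    logo = build_tsd_logo([r.tsd for r in NINE_INSERTIONS if r.tsd])
    print(f"\nTSD consensus over the {logo.n_sequences} modal-length "
          f"duplications: {logo.consensus}")


if __name__ == "__main__":
    main()
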