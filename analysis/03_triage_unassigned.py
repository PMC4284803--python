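#!/usr/bin/env python
"""Triage unassigned transcripts: artefact, novel lncRNA, or coding.

Combines three evidence types — active promoter marks in ±5 kb of the
5' end, position relative to the nearest upstream gene (read-through
geometry), and a coding-potential score trained on the annotated
mRNA/lncRNA sets — into the deterministic verdict cascade, then compares
verdicts with the planted labels.
"""

from pathlib import Path

import pandas as pd

from p53lnc.chromatin import MarkTrack, promoter_mark_evidence
from p53lnc.coding import read_fasta, score_transcripts, train_coding_model
from p53lnc.genome import Biotype, LNCRNA_BIOTYPES, build_genes, parse_annotation
from p53lnc.motifs import reverse_complement
from p53lnc.targets import neighbor_context_for, triage_unassigned

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "sim"


def main() -> None:
    with open(SIM / "annotation.gtf") as fh:
        transcripts = parse_annotation(fh)
    genes = build_genes(transcripts)
    genome = read_fasta(SIM / "genome.fa")
    marks = [
        MarkTrack.from_bed(m, SIM / f"mark_{m}.bed")
        for m in ("H3K4me3", "H3K4me1", "H3K27ac")
    ]

    def seq_of(t):
        s = "".join(genome[t.chrom][e.start : e.end] for e in t.exons)
        return reverse_complement(s) if t.strand == "-" else s

    coding = [seq_of(t) for t in transcripts if t.biotype == Biotype.MRNA]
    noncoding = [seq_of(t) for t in transcripts if t.biotype in LNCRNA_BIOTYPES]
    model, table = train_coding_model(coding, noncoding)
    unassigned = [t for t in transcripts if t.biotype == Biotype.UNASSIGNED]
    scored = score_transcripts({t.transcript_id: seq_of(t) for t in unassigned}, model, table)
    scored.to_csv(ROOT / "coding_potential.tsv", sep="\t", index=False)
    prob = dict(zip(scored["transcript_id"], scored["coding_prob"]))

    rows = []
    for t in unassigned:
        ev = promoter_mark_evidence(t, marks)
        ctx = neighbor_context_for(t, genes)
        v = triage_unassigned(t, ev, prob[t.transcript_id], ctx)
        rows.append({"transcript_id": t.transcript_id, "verdict": v.verdict,
                     "reasons": ";".join(v.reasons)})
    triage = pd.DataFrame(rows)
    triage.to_csv(ROOT / "triage.tsv", sep="\t", index=False)

    truth = pd.read_csv(SIM / "truth_transcripts.tsv", sep="\t")
    merged = triage.merge(truth, on="transcript_id")
    print(f"{len(unassigned)} unassigned transcripts triaged:")
    print(merged["verdict"].value_counts().to_string())
    print("\nverdict vs planted label:")
    print(pd.crosstab(merged["label"], merged["verdict"]).to_string())


if __name__ == "__main__":
    main()
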