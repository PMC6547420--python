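"""On-disk formats: FASTA genomes and the pipeline's TSV tables.

All tables are tab-separated with a header row; coordinates on disk follow
the internal convention (0-based, half-open start/end).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .catalog import IESForm, IESLocus, cluster_forms
from .refine import RefinedCall
from .simulate import TruthRecord


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")  # 60-column wrapped


def read_genome(path) -> dict[str, str]:
    """Load a FASTA genome fully into memory (indexed access via pyfaidx)."""
    fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- truth ------------------------------------------------------------------

def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": t.locus_id,
                "contig": t.contig,
                "true_A": t.true_A,
                "true_B": t.true_B,
                "planted_motif": t.planted_motif or "",
                "left_motif_distance": "" if t.left_motif_distance is None else t.left_motif_distance,
                "right_motif_distance": "" if t.right_motif_distance is None else t.right_motif_distance,
                "microhomology": t.microhomology,
            }
            for t in truth
        ]
    )


def frame_to_truth(frame: pd.DataFrame) -> list[TruthRecord]:
    out = []
    for row in frame.fillna("").itertuples(index=False):
        motif = str(row.planted_motif) or None
        out.append(
            TruthRecord(
                locus_id=str(row.locus_id),
                contig=str(row.contig),
                true_A=int(row.true_A),
                true_B=int(row.true_B),
                planted_motif=motif,
                left_motif_distance=int(row.left_motif_distance) if motif else None,
                right_motif_distance=int(row.right_motif_distance) if motif else None,
                microhomology=str(row.microhomology),
            )
        )
    return out


# -- forms / calls / catalogue ----------------------------------------------

def forms_to_frame(forms: Sequence[IESForm]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": f.source_id or "",
                "strain": f.strain,
                "contig": f.contig,
                "start": f.A,
                "end": f.B,
                "mh_len": f.mh_len,
            }
            for f in forms
        ]
    )


def frame_to_forms(frame: pd.DataFrame) -> list[IESForm]:
    return [
        IESForm(
            strain=str(row.strain),
            contig=str(row.contig),
            A=int(row.start),
            B=int(row.end),
            mh_len=int(getattr(row, "mh_len", 0) or 0),
            source_id=str(row.locus_id) if getattr(row, "locus_id", "") else None,
        )
        for row in frame.fillna("").itertuples(index=False)
    ]


def calls_to_frame(calls: Sequence[RefinedCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain": c.strain,
                "contig": c.contig,
                "start": c.A,
                "end": c.B,
                "support_A": c.support_A,
                "support_B": c.support_B,
                "source_id": c.source_id or "",
            }
            for c in calls
        ]
    )


def frame_to_calls(frame: pd.DataFrame) -> list[RefinedCall]:
    return [
        RefinedCall(
            strain=str(row.strain),
            contig=str(row.contig),
            A=int(row.start),
            B=int(row.end),
            support_A=int(getattr(row, "support_A", 0)),
            support_B=int(getattr(row, "support_B", 0)),
            source_id=str(row.source_id) if getattr(row, "source_id", "") else None,
        )
        for row in frame.fillna("").itertuples(index=False)
    ]


def catalog_to_frame(loci: Sequence[IESLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": locus.locus_id,
                "strain": f.strain,
                "contig": f.contig,
                "start": f.A,
                "end": f.B,
                "mh_len": f.mh_len,
            }
            for locus in loci
            for f in locus.forms
        ]
    )


def frame_to_loci(frame: pd.DataFrame) -> list[IESLocus]:
    """Rebuild loci from a catalogue table (re-clusters, then asserts ids)."""
    forms = [
        IESForm(
            strain=str(row.strain),
            contig=str(row.contig),
            A=int(row.start),
            B=int(row.end),
            mh_len=int(getattr(row, "mh_len", 0) or 0),
        )
        for row in frame.itertuples(index=False)
    ]
    return cluster_forms(forms)


def loci_to_bed(loci: Sequence[IESLocus]) -> pd.DataFrame:
    rows = []
    for locus in loci:
        start, end = locus.span
        rows.append(
            {"contig": locus.contig, "start": start, "end": end, "name": locus.locus_id}
        )
    return pd.DataFrame(rows, columns=["contig", "start", "end", "name"])
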