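"""Readers and writers for the plain-text formats used across the package.

FASTA via Biopython; BED (6-column, 0-based half-open), methylation
tracks, count tables and sensorgram traces as TSV/CSV through pandas.
"""

from __future__ import annotations

from io import StringIO
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED_COLUMNS = ["chrom", "start", "end", "region_id", "score", "strand"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as {name: upper-case sequence}."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def fasta_text(genome: dict[str, str]) -> str:
    buf = StringIO()
    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")
                 for name, seq in genome.items()], buf, "fasta")
    return buf.getvalue()


def read_bed(path: str | Path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED_COLUMNS)
    frame.columns = BED_COLUMNS[: frame.shape[1]]
    return frame


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_sensorgrams(sensorgrams, path: str | Path) -> None:
    """Concatenate sensorgrams into one CSV
    (time_s, response_nm, phase, concentration_nM)."""
    frames = [sg.to_frame() for sg in sensorgrams]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensorgrams(path: str | Path):
    """Split a sensorgram CSV back into one Sensorgram per concentration."""
    from .bli_kinetics import Sensorgram

    frame = pd.read_csv(path)
    return [Sensorgram.from_frame(group)
            for _, group in frame.groupby("concentration_nM", sort=True)]
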