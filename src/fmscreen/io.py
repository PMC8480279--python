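"""Plain-text readers/writers for stage inputs and outputs.

Every table is TSV and every sequence set is FASTA, so each pipeline stage
can be rerun and inspected independently. Table files may start with '#'
comment lines carrying provenance (seed, config hash); readers skip them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(path: str | Path, records: dict[str, str] | list[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(df: pd.DataFrame, path: str | Path,
              comments: list[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


#: fixed quantization step for 16-bit TIFF round trips; rendered images
#: live in roughly [0, 2.5] intensity units, so 1e4 leaves ample headroom
TIFF_SCALE = 10_000.0


def write_image_tiff(path: str | Path, img) -> None:
    """Write a (3, H, W) float image as 16-bit TIFF (DAPI, Texas red, FITC).

    Intensities are clipped at zero and quantized at 1/TIFF_SCALE units.
    """
    import numpy as np
    import tifffile

    data = np.clip(np.asarray(img), 0.0, None) * TIFF_SCALE
    tifffile.imwrite(str(path), data.round().astype("uint16"),
                     photometric="minisblack", planarconfig="separate")


def read_image_tiff(path: str | Path):
    """Read a 16-bit TIFF written by ``write_image_tiff`` back to floats."""
    import tifffile

    return tifffile.imread(str(path)).astype(float) / TIFF_SCALE
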