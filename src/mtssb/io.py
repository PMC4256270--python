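"""Readers and writers for the pipeline's file formats.

Formats are deliberately plain: FASTA for references, FASTQ for reads
(qualities ignored on input), BED for regions/truth labels/alignments,
bedGraph for per-strand tracks, TSV for profiles and assay tables, YAML
for run configuration, JSON for reports. Sequence formats go through
Bio.SeqIO.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import CircularGenome, Region, RegionSet
from .occupancy import OccupancyProfile
from .replication import ExposureProfile, Mode, ReplicationConfig
from .strandseq import AlignmentSet, ReadSet

__all__ = [
    "read_genome_fasta",
    "write_genome_fasta",
    "read_fastq",
    "write_fastq",
    "read_regions_bed",
    "write_truth_bed",
    "write_alignments_bed",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_bedgraph",
    "load_config",
    "write_json_report",
]


# -- sequences ---------------------------------------------------------------


def read_genome_fasta(
    path, ori_h: int, ori_l: int, name: str | None = None
) -> CircularGenome:
    """Load a single circular reference record from FASTA.

    Circularity is declared by configuration (origins given here), never
    inferred from the file.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly 1 record, found {len(records)}")
    rec = records[0]
    return CircularGenome(
        length=len(rec.seq), ori_h=ori_h, ori_l=ori_l,
        sequence=str(rec.seq), name=name or rec.id,
    )


def write_genome_fasta(genome: CircularGenome, path) -> None:
    if genome.sequence is None:
        raise ValueError("genome has no sequence to write")
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="circular")
    SeqIO.write([rec], str(path), "fasta")


def read_fastq(path) -> ReadSet:
    """Load reads from FASTQ; qualities are ignored."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    return ReadSet(ids=ids, sequences=seqs)


def write_fastq(reads: ReadSet, path) -> None:
    """Write reads as FASTQ with flat placeholder qualities."""
    with open(path, "w") as fh:
        for rid, seq in zip(reads.ids, reads.sequences):
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# -- intervals ---------------------------------------------------------------


def read_regions_bed(path) -> RegionSet:
    """Regions from BED (0-based half-open; first 4 columns used)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: BED line needs 4 columns: {line!r}")
            regions.append(Region(name=parts[3], start=int(parts[1]), end=int(parts[2])))
    return RegionSet(tuple(regions))


def write_truth_bed(reads: ReadSet, genome: CircularGenome, path, read_length: int) -> None:
    """Generator truth labels as BED (background reads get chrom '.')."""
    if reads.truth is None:
        raise ValueError("read set carries no truth labels")
    with open(path, "w") as fh:
        for rec in reads.truth.itertuples(index=False):
            if rec.is_background:
                fh.write(f".\t0\t0\t{rec.read_id}\t0\t.\n")
            else:
                strand = "+" if rec.strand == "H" else "-"
                fh.write(
                    f"{genome.name}\t{rec.position}\t{rec.position + read_length}"
                    f"\t{rec.read_id}\t0\t{strand}\n"
                )


def write_alignments_bed(alignments: AlignmentSet, genome: CircularGenome, path) -> None:
    """Mapped reads as BED6 (H-strand footprint coordinates; L reads as '-')."""
    mapped = alignments.table[alignments.table["mapped"]]
    with open(path, "w") as fh:
        for rec in mapped.itertuples(index=False):
            strand = "+" if rec.strand == "H" else "-"
            fh.write(
                f"{genome.name}\t{rec.position}\t{rec.position + rec.length}"
                f"\t{rec.read_id}\t0\t{strand}\n"
            )


# -- profiles ----------------------------------------------------------------


def write_profile_tsv(
    path,
    exposure: ExposureProfile | None = None,
    occupancy: OccupancyProfile | None = None,
) -> None:
    """Per-position profile as 4-column TSV: position, strand, exposure, occupancy.

    Either profile may be omitted; its column is written as 0.
    """
    if exposure is None and occupancy is None:
        raise ValueError("need an exposure or an occupancy profile")
    genome = (exposure or occupancy).genome
    L = genome.length
    zeros = np.zeros(L)
    exp_h = exposure.t_ss_h if exposure is not None else zeros
    exp_l = exposure.t_ss_l if exposure is not None else zeros
    occ_h = occupancy.occ_h if occupancy is not None else zeros
    occ_l = occupancy.occ_l if occupancy is not None else zeros
    frame = pd.DataFrame({
        "position": np.tile(np.arange(L), 2),
        "strand": np.repeat(["H", "L"], L),
        "exposure": np.concatenate([exp_h, exp_l]),
        "occupancy": np.concatenate([occ_h, occ_l]),
    })
    frame.to_csv(path, sep="\t", index=False)


def read_profile_tsv(path, genome: CircularGenome):
    """Inverse of :func:`write_profile_tsv`; returns (exposure_h, exposure_l,
    occupancy_h, occupancy_l) arrays."""
    frame = pd.read_csv(path, sep="\t")
    out = []
    for col in ("exposure", "occupancy"):
        for strand in ("H", "L"):
            sub = frame[frame["strand"] == strand].sort_values("position")
            if len(sub) != genome.length:
                raise ValueError(f"{path}: profile length mismatch for strand {strand}")
            out.append(sub[col].to_numpy(dtype=float))
    return out[0], out[1], out[2], out[3]


def write_bedgraph(values, genome: CircularGenome, path, track_name: str) -> None:
    """Per-position values as bedGraph with run-length-merged intervals."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        start = 0
        for i in range(1, genome.length + 1):
            if i == genome.length or values[i] != values[start]:
                fh.write(f"{genome.name}\t{start}\t{i}\t{values[start]:g}\n")
                start = i


# -- configuration and reports ----------------------------------------------


def load_config(path) -> dict:
    """Run configuration from YAML.

    Recognized layout::

        genome: {length, ori_h, ori_l, fasta}   # fasta optional
        model:  {mode, v_h, v_l, okazaki_length, oril_delay}
        seed:   integer

    Returns a dict with ``genome`` (CircularGenome or the raw mapping when
    only geometry is given), ``config`` (ReplicationConfig) and ``seed``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {"seed": int(raw.get("seed", 20141204)), "raw": raw}
    gspec = raw.get("genome", {})
    model = raw.get("model", {})
    cfg_kwargs = {
        k: model[k]
        for k in ("v_h", "v_l", "okazaki_length", "oril_delay")
        if k in model
    }
    out["config"] = ReplicationConfig(mode=Mode(model.get("mode", "SDM")), **cfg_kwargs)
    if gspec.get("fasta"):
        base = Path(path).parent
        fasta = Path(gspec["fasta"])
        if not fasta.is_absolute():
            fasta = base / fasta
        out["genome"] = read_genome_fasta(
            fasta, ori_h=int(gspec["ori_h"]), ori_l=int(gspec["ori_l"])
        )
    elif {"length", "ori_h", "ori_l"}.issubset(gspec):
        out["genome"] = CircularGenome(
            length=int(gspec["length"]), ori_h=int(gspec["ori_h"]),
            ori_l=int(gspec["ori_l"]),
        )
    else:
        out["genome"] = None
    return out


def write_json_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
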