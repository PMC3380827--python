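"""Plain-text readers and writers for the pipeline's external formats.

Genotype panels round-trip through PLINK-style PED/MAP pairs (alleles coded
A/B, POLLED class carried in the family column); variant tables, allele calls
and pedigrees are tab-separated tables; read-start tracks are BED (one
zero-length feature per read start); per-marker statistics and ratio tracks
are bedGraph.  Everything is uncompressed text.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .cnv import ReadStartTrack
from .filtering import RECORD_COLUMNS, VariantTable
from .intervals import Convention, GenomicInterval
from .mapping import GenotypePanel

PathLike = Union[str, Path]

_GENO_TO_ALLELES = {0: ("A", "A"), 1: ("A", "B"), 2: ("B", "B"), -1: ("0", "0")}
_ALLELES_TO_GENO = {v: k for k, v in _GENO_TO_ALLELES.items()}
_CLASS_TO_PHENO = {"pp": "1", "PP": "2", "Pp": "3", "unknown": "0"}
_PHENO_TO_CLASS = {v: k for k, v in _CLASS_TO_PHENO.items()}


def write_ped_map(panel: GenotypePanel, prefix: PathLike) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, m in panel.markers.iterrows():
            fh.write(f"{m['chrom']}\t{m['id']}\t0\t{m['bp']}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, a in panel.animals.iterrows():
            fields = [a["breed"], a["id"], "0", "0", "0",
                      _CLASS_TO_PHENO.get(a["polled_class"], "0")]
            for g in panel.genotypes[i]:
                fields += _GENO_TO_ALLELES[int(g)]
            fh.write("\t".join(fields) + "\n")


def read_ped_map(prefix: PathLike) -> GenotypePanel:
    prefix = Path(prefix)
    markers = pd.read_csv(prefix.with_suffix(".map"), sep="\t", header=None,
                          names=["chrom", "id", "cm", "bp"],
                          dtype={"chrom": str})[["id", "chrom", "bp"]]
    animal_rows, geno_rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            animal_rows.append((f[1], f[0], _PHENO_TO_CLASS.get(f[5], "unknown")))
            alleles = f[6:]
            geno_rows.append([_ALLELES_TO_GENO[(alleles[2 * k], alleles[2 * k + 1])]
                              for k in range(len(alleles) // 2)])
    animals = pd.DataFrame(animal_rows, columns=["id", "breed", "polled_class"])
    return GenotypePanel(animals=animals, markers=markers,
                         genotypes=np.array(geno_rows, dtype=np.int8))


def write_variant_table(table: VariantTable, records_path: PathLike,
                        samples_path: PathLike) -> None:
    table.records.to_csv(records_path, sep="\t", index=False)
    table.samples.to_csv(samples_path, sep="\t", index=False)


def read_variant_table(records_path: PathLike, samples_path: PathLike) -> VariantTable:
    records = pd.read_csv(records_path, sep="\t", dtype={"chrom": str})
    if len(records) == 0:
        records = pd.DataFrame(columns=RECORD_COLUMNS)
    samples = pd.read_csv(samples_path, sep="\t", dtype={"chrom": str})
    return VariantTable(records=records, samples=samples)


def write_read_track_bed(track: ReadStartTrack, path: PathLike) -> None:
    with open(path, "w") as fh:
        chrom = track.interval.chrom
        for p in track.positions:
            fh.write(f"{chrom}\t{p - 1}\t{p}\t{track.group}\n")


def read_read_track_bed(path: PathLike, interval: GenomicInterval) -> ReadStartTrack:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "group"], dtype={"chrom": str})
    group = str(df["group"].iloc[0]) if len(df) else "reads"
    return ReadStartTrack(group, np.sort(df["end"].to_numpy()), interval)


def write_bedgraph(chrom: str, starts, ends, values, path: PathLike) -> None:
    with open(path, "w") as fh:
        for s, e, v in zip(starts, ends, values):
            fh.write(f"{chrom}\t{int(s) - 1}\t{int(e)}\t{v:.6g}\n")


def write_stats_tsv(panel: GenotypePanel, stats: np.ndarray, pvalues: np.ndarray,
                    path: PathLike) -> None:
    out = panel.markers.copy()
    out["S"] = stats
    out["p"] = pvalues
    out.to_csv(path, sep="\t", index=False)


def write_intervals_bed(intervals, path: PathLike, names=None) -> None:
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            end = iv.end if iv.convention is Convention.HALF_OPEN else iv.end + 1
            name = names[k] if names else f"interval_{k}"
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{end - 1}\t{name}\n")


def write_json(obj, path: PathLike) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
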