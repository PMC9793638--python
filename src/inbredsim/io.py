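"""Plain-text file formats: PLINK .ped/.map, pedigree/frequency/ROH TSV, config.

Genotypes are exchanged in the classic PLINK text dialect: the .map file has
one row per SNP (chromosome, SNP id, genetic position in cM, bp position) and
the .ped file one row per individual (family, id, sire, dam, sex, phenotype,
then two allele columns per SNP).  Alleles are written as ``1`` (reference)
and ``2`` (counted/derived), with ``0 0`` for missing, so the 0/1/2 dosage is
the count of allele ``2``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gene_drop import Pedigree
from .roh import RohParams, RohSegment

__all__ = [
    "FormatError",
    "write_ped_map",
    "read_ped_map",
    "write_pedigree_tsv",
    "read_pedigree_tsv",
    "write_frequencies_tsv",
    "read_frequencies_tsv",
    "write_roh_tsv",
    "RunConfig",
    "load_config",
    "config_hash",
]


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# PLINK .ped/.map


def write_ped_map(
    prefix: str | Path,
    x: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    ids: list | None = None,
    snp_ids: list | None = None,
) -> tuple[Path, Path]:
    """Write a 0/1/2 dosage matrix (-1 = missing) as <prefix>.ped/.map."""
    prefix = Path(prefix)
    x = np.atleast_2d(np.asarray(x, np.int64))
    n, s_count = x.shape
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, np.int64)
    if chrom.size != s_count or pos.size != s_count:
        raise ValueError("SNP metadata does not match the genotype matrix")
    if ids is None:
        ids = [f"ind{i + 1}" for i in range(n)]
    if snp_ids is None:
        snp_ids = [f"snp{j + 1}" for j in range(s_count)]
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for c, sid, p in zip(chrom, snp_ids, pos):
            fh.write(f"{int(c) + 1}\t{sid}\t0\t{int(p)}\n")
    allele = {0: "1 1", 1: "1 2", 2: "2 2", -1: "0 0"}
    with open(ped_path, "w") as fh:
        for i in range(n):
            geno = " ".join(allele[int(v)] for v in x[i])
            fh.write(f"FAM1 {ids[i]} 0 0 0 -9 {geno}\n")
    return ped_path, map_path


def read_ped_map(ped_path: str | Path, map_path: str | Path):
    """Read PLINK text genotypes; returns (x, chrom, pos, ids, snp_ids).

    ``chrom`` comes back 0-based (the writer adds 1 for the file), dosages are
    counts of allele ``2`` and missing genotypes are -1.
    """
    chrom: list[int] = []
    pos: list[int] = []
    snp_ids: list[str] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{lineno}: expected 4 columns")
            try:
                chrom.append(int(parts[0]) - 1)
                pos.append(int(parts[3]))
            except ValueError as exc:
                raise FormatError(f"{map_path}:{lineno}: {exc}") from None
            snp_ids.append(parts[1])
    s_count = len(snp_ids)
    rows: list[list[int]] = []
    ids: list[str] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * s_count:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * s_count} fields, "
                    f"got {len(parts)}"
                )
            ids.append(parts[1])
            geno = parts[6:]
            row = []
            for j in range(s_count):
                a, b = geno[2 * j], geno[2 * j + 1]
                if a == "0" or b == "0":
                    row.append(-1)
                elif a in "12" and b in "12":
                    row.append((a == "2") + (b == "2"))
                else:
                    raise FormatError(
                        f"{ped_path}:{lineno}: unexpected allele pair {a} {b}")
            rows.append(row)
    return (
        np.array(rows, np.int64).reshape(len(rows), s_count),
        np.array(chrom, np.int64),
        np.array(pos, np.int64),
        ids,
        snp_ids,
    )


# ---------------------------------------------------------------------------
# pedigree / frequency / ROH tables


def write_pedigree_tsv(path: str | Path, pedigree) -> Path:
    """Write (id, sire, dam, cohort[, sex]); accepts Pedigree or PedigreeBook."""
    path = Path(path)
    if hasattr(pedigree, "to_frame"):
        frame = pedigree.to_frame()
    else:
        frame = pd.DataFrame(pedigree)
    frame = frame.rename(columns={"generation": "cohort"})
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_pedigree_tsv(path: str | Path) -> Pedigree:
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from None
    needed = {"id", "sire", "dam", "cohort"}
    if not needed.issubset(frame.columns):
        raise FormatError(f"{path}: missing columns {needed - set(frame.columns)}")
    try:
        return Pedigree.from_frame(frame)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_frequencies_tsv(path: str | Path, p: np.ndarray,
                          provenance: str, snp_ids=None) -> Path:
    path = Path(path)
    p = np.asarray(p, float)
    if snp_ids is None:
        snp_ids = [f"snp{j + 1}" for j in range(p.size)]
    pd.DataFrame({"snp_id": snp_ids, "p": p, "provenance": provenance}).to_csv(
        path, sep="\t", index=False, float_format="%.17g")
    return path


def read_frequencies_tsv(path: str | Path):
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("snp_id", "p", "provenance"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return frame["p"].to_numpy(float), str(frame["provenance"].iloc[0]), list(frame["snp_id"])


def write_roh_tsv(path: str | Path,
                  segments_by_individual: dict[str, list[RohSegment]]) -> Path:
    """Segment table mirroring the classic .hom layout."""
    rows = []
    for ind, segs in segments_by_individual.items():
        for seg in segs:
            rows.append({
                "individual": ind,
                "chromosome": seg.chromosome + 1,
                "start_bp": seg.start_bp,
                "end_bp": seg.end_bp,
                "n_snps": seg.n_snps,
                "length_kb": seg.length_bp / 1000.0,
            })
    pd.DataFrame(rows, columns=["individual", "chromosome", "start_bp",
                                "end_bp", "n_snps", "length_kb"]).to_csv(
        Path(path), sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a replicated scenario run.

    ``preset`` selects the mutation model ('default', 'high_density',
    'alternative'); the genome may be scaled down for desk runs while keeping
    all per-bp rates.  Every stochastic stage derives its seed from
    ``seed`` so a run is reproducible from the config alone.
    """

    preset: str = "default"
    n_chromosomes: int | None = None
    chrom_length_bp: int | None = None
    ancestral_n: int = 500
    burn_in_generations: int = 5000
    scheme: str = "RC"
    n: int = 20
    t: int = 10
    replicates: int = 200
    seed: int = 1
    natural_selection: bool = True
    tracer_spacing_bp: int = 500_000
    maf_thresholds: tuple[float, ...] = ()
    roh: bool = False
    roh_params: RohParams = field(default_factory=RohParams)
    outdir: str = "inbredsim_out"
    cache_dir: str | None = None

    def genome_and_effects(self):
        from .sim_core import PRESETS

        preset = PRESETS[self.preset]
        genome = preset.genome.scaled(self.n_chromosomes, self.chrom_length_bp)
        return genome, preset.effects


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    if "roh_params" in raw:
        raw["roh_params"] = RohParams(**raw["roh_params"])
    if "maf_thresholds" in raw:
        raw["maf_thresholds"] = tuple(raw["maf_thresholds"])
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]
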