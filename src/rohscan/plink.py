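"""Readers and writers for PLINK PED/MAP and BED/BIM/FAM file sets.

Both dialects are supported bit-exactly:

* **PED/MAP** — whitespace-delimited text; one sample per PED line with six
  leading columns (family id, sample id, father, mother, sex, phenotype)
  followed by two allele tokens per marker; ``0`` is the missing-allele code.
* **BED/BIM/FAM** — PLINK v1.0 binary, SNP-major.  The BED file starts with
  the magic bytes ``0x6c 0x1b`` and a mode byte ``0x01``; each SNP is then a
  packed run of two-bit genotype codes, least-significant pair first:
  ``00`` hom allele1, ``01`` missing, ``10`` het, ``11`` hom allele2.

The family-ID column doubles as the population label, the common convention
for breed/population panels.  A sidecar TSV (``sample_id<TAB>population``)
may override it.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, Sample, SNPRecord

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# two-bit BED code -> allele2 dosage
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
# allele2 dosage (index -1 used for MISSING) -> two-bit BED code
_BED_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def _ext(prefix: Path, ext: str) -> Path:
    """Append an extension to a path stem without clobbering dots in the stem."""
    return prefix.parent / (prefix.name + ext)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required PLINK companion file not found: {path}")
    return path


def _read_map(path: Path, with_alleles: bool) -> list[SNPRecord]:
    records = []
    ncols = 6 if with_alleles else 4
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != ncols:
                raise ValueError(
                    f"{path}:{lineno}: expected {ncols} columns, got {len(tokens)}"
                )
            chrom, snp_id, cm, bp = tokens[:4]
            a1, a2 = (tokens[4], tokens[5]) if with_alleles else ("0", "0")
            records.append(
                SNPRecord(
                    chrom=chrom,
                    snp_id=snp_id,
                    genetic_pos=float(cm),
                    bp_pos=int(bp),
                    allele1=a1,
                    allele2=a2,
                )
            )
    return records


def _read_fam_fields(tokens: list[str]) -> Sample:
    fid, iid, _pat, _mat, sex = tokens[0], tokens[1], tokens[2], tokens[3], tokens[4]
    return Sample(sample_id=iid, population=fid, sex=int(float(sex)))


def _read_ped(path_prefix: Path) -> GenotypeMatrix:
    map_path = _require(_ext(path_prefix, ".map"))
    ped_path = _require(_ext(path_prefix, ".ped"))
    snps = _read_map(map_path, with_alleles=False)
    n_snps = len(snps)

    samples: list[Sample] = []
    rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                continue
            expected = 6 + 2 * n_snps
            if len(tokens) != expected:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {expected} tokens "
                    f"(6 + 2 x {n_snps} markers), got {len(tokens)}"
                )
            samples.append(_read_fam_fields(tokens[:6]))
            rows.append(
                [(tokens[6 + 2 * j], tokens[7 + 2 * j]) for j in range(n_snps)]
            )

    # Establish the allele coding per SNP from the file: allele1 is the first
    # distinct allele observed, allele2 the second.  Monomorphic markers get
    # allele1 = "0" so that the single observed allele is allele2 and its
    # homozygote has dosage 2.
    calls = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    coded_snps: list[SNPRecord] = []
    for j in range(n_snps):
        alleles: list[str] = []
        for pair in (row[j] for row in rows):
            for a in pair:
                if a != "0" and a not in alleles:
                    alleles.append(a)
        if len(alleles) > 2:
            raise ValueError(
                f"{ped_path}: SNP {snps[j].snp_id} has >2 alleles: {alleles}"
            )
        if len(alleles) == 2:
            a1, a2 = alleles
        elif len(alleles) == 1:
            a1, a2 = "0", alleles[0]
        else:
            a1, a2 = "0", "0"
        rec = snps[j]
        coded_snps.append(
            SNPRecord(rec.chrom, rec.snp_id, rec.genetic_pos, rec.bp_pos, a1, a2)
        )
        for i, row in enumerate(rows):
            x, y = row[j]
            if x == "0" or y == "0":
                continue
            calls[i, j] = (x == a2) + (y == a2)

    return GenotypeMatrix(samples, coded_snps, calls).sorted_by_position()


def _read_bed(path_prefix: Path) -> GenotypeMatrix:
    bim_path = _require(_ext(path_prefix, ".bim"))
    fam_path = _require(_ext(path_prefix, ".fam"))
    bed_path = _require(_ext(path_prefix, ".bed"))

    snps = _read_map(bim_path, with_alleles=True)
    samples: list[Sample] = []
    with open(fam_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 6:
                raise ValueError(f"{fam_path}:{lineno}: expected 6 columns")
            samples.append(_read_fam_fields(tokens))

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:2]) != _BED_MAGIC:
        raise ValueError(f"{bed_path}: not a PLINK BED file (bad magic bytes)")
    if raw[2] != _SNP_MAJOR:
        raise ValueError(f"{bed_path}: only SNP-major BED files are supported")

    n, m = len(samples), len(snps)
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * m:
        raise ValueError(
            f"{bed_path}: expected {bytes_per_snp * m} genotype bytes, got {len(body)}"
        )
    calls = np.empty((n, m), dtype=np.int8)
    if m:
        blocks = body.reshape(m, bytes_per_snp)
        # unpack two-bit codes, least-significant pair = first sample
        codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
        for shift in range(4):
            codes[:, shift::4] = (blocks >> (2 * shift)) & 0b11
        calls[:] = _BED_DECODE[codes[:, :n]].T
    return GenotypeMatrix(samples, snps, calls).sorted_by_position()


def read_genotypes(
    path_prefix: str | os.PathLike,
    format: str = "auto",
    population_tsv: str | os.PathLike | None = None,
) -> GenotypeMatrix:
    """Read a PLINK file set into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path_prefix:
        Path stem shared by the file set (``stem.ped``/``stem.map`` or
        ``stem.bed``/``stem.bim``/``stem.fam``).
    format:
        ``"ped"``, ``"bed"`` or ``"auto"`` (``bed`` if ``stem.bed`` exists).
    population_tsv:
        Optional two-column TSV ``sample_id<TAB>population`` overriding the
        family-ID-derived population labels.

    Returns a matrix with SNPs sorted by (chromosome, bp position); missing
    genotypes are coded :data:`~rohscan.genotypes.MISSING`.
    """
    prefix = Path(path_prefix)
    if format == "auto":
        format = "bed" if _ext(prefix, ".bed").exists() else "ped"
    if format == "ped":
        g = _read_ped(prefix)
    elif format == "bed":
        g = _read_bed(prefix)
    else:
        raise ValueError(f"unknown format {format!r}; use 'ped', 'bed' or 'auto'")
    if population_tsv is not None:
        g = _apply_population_tsv(g, Path(population_tsv))
    return g


def _apply_population_tsv(g: GenotypeMatrix, path: Path) -> GenotypeMatrix:
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            sid, pop = line.rstrip("\n").split("\t")[:2]
            labels[sid] = pop
    samples = [
        Sample(s.sample_id, labels.get(s.sample_id, s.population), s.sex)
        for s in g.samples
    ]
    return GenotypeMatrix(samples, g.snps, g.calls, validate=False)


def _fam_line(s: Sample) -> str:
    return f"{s.population} {s.sample_id} 0 0 {s.sex} -9"


def _write_ped(g: GenotypeMatrix, prefix: Path) -> list[Path]:
    map_path = _ext(prefix, ".map")
    ped_path = _ext(prefix, ".ped")
    with open(map_path, "w") as fh:
        for v in g.snps:
            fh.write(f"{v.chrom} {v.snp_id} {v.genetic_pos:g} {v.bp_pos}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(g.samples):
            fields = [_fam_line(s)]
            for j, v in enumerate(g.snps):
                d = g.calls[i, j]
                if d == MISSING:
                    fields.append("0 0")
                elif d == 0:
                    fields.append(f"{v.allele1} {v.allele1}")
                elif d == 1:
                    fields.append(f"{v.allele1} {v.allele2}")
                else:
                    fields.append(f"{v.allele2} {v.allele2}")
            fh.write(" ".join(fields) + "\n")
    return [ped_path, map_path]


def _write_bed(g: GenotypeMatrix, prefix: Path) -> list[Path]:
    bim_path = _ext(prefix, ".bim")
    fam_path = _ext(prefix, ".fam")
    bed_path = _ext(prefix, ".bed")
    with open(bim_path, "w") as fh:
        for v in g.snps:
            fh.write(
                f"{v.chrom}\t{v.snp_id}\t{v.genetic_pos:g}\t{v.bp_pos}"
                f"\t{v.allele1}\t{v.allele2}\n"
            )
    with open(fam_path, "w") as fh:
        for s in g.samples:
            fh.write(_fam_line(s) + "\n")

    n, m = g.n_samples, g.n_snps
    bytes_per_snp = (n + 3) // 4
    body = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for i in range(n):
        byte_idx, shift = divmod(i, 4)
        col = np.array(
            [_BED_ENCODE[int(d)] for d in g.calls[i, :]], dtype=np.uint8
        )
        body[:, byte_idx] |= col << (2 * shift)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(body.tobytes())
    return [bed_path, bim_path, fam_path]


def write_genotypes(
    g: GenotypeMatrix, path_prefix: str | os.PathLike, format: str = "ped"
) -> list[Path]:
    """Write ``g`` as a PLINK file set; returns the paths written.

    Output is deterministic for a fixed input and readable both by
    :func:`read_genotypes` and by standard PLINK-compatible tools.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "ped":
        return _write_ped(g, prefix)
    if format == "bed":
        return _write_bed(g, prefix)
    raise ValueError(f"unknown format {format!r}; use 'ped' or 'bed'")
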