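"""Reading and writing the pipeline's file formats.

VCF is read through cyvcf2/htslib and written by a small deterministic text
emitter (fixed column set, byte-stable for a fixed matrix).  Population maps
and phenotype tables are TSV; gene annotations are BED (0-based half-open)
or GFF3 (1-based inclusive), auto-detected by extension and normalised to
0-based half-open internally.  All user-facing coordinates are 1-based.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .matrix import MISSING, GenotypeMatrix, IntervalSet, PopulationMap

_INFO_TAGS = ("QD", "FS", "ReadPosRankSum")


class VCFFormatError(ValueError):
    """Malformed or unsupported VCF input."""


def _fmt_float(x: float) -> str:
    """Shortest round-trip decimal representation (no trailing '.0')."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, 1, np.iinfo(np.int64).max
    lo, _, hi = span.partition("-")
    return chrom, int(lo), int(hi) if hi else np.iinfo(np.int64).max

def read_vcf(path: str | os.PathLike, region: str | None = None) -> GenotypeMatrix:
    """Read a VCF 4.x file with GT fields into a :class:`GenotypeMatrix`.

    Multi-allelic sites are retained but flagged ``is_biallelic=False``
    (genotype calls involving an allele index > 1 become missing).  INFO
    tags QD, FS and ReadPosRankSum are captured when present.

    Parameters
    ----------
    region
        Optional ``chrom`` or ``chrom:start-end`` restriction (1-based
        inclusive), applied while streaming — no index required.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    if samples and "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise VCFFormatError(f"{path}: no GT FORMAT defined in header")
    want = _parse_region(region) if region else None

    chroms, positions, refs, alts, quals, bial = [], [], [], [], [], []
    info = {k: [] for k in _INFO_TAGS}
    dosage_rows = []
    last: dict[str, int] = {}
    for v in vcf:
        if want is not None:
            if v.CHROM != want[0] or not (want[1] <= v.POS <= want[2]):
                continue
        if v.POS <= last.get(v.CHROM, 0):
            raise VCFFormatError(
                f"{path}: positions not strictly increasing at {v.CHROM}:{v.POS}"
            )
        last[v.CHROM] = v.POS
        chroms.append(v.CHROM)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0] if v.ALT else ".")
        quals.append(np.nan if v.QUAL is None else float(v.QUAL))
        bial.append(len(v.ALT) == 1)
        for k in _INFO_TAGS:
            val = v.INFO.get(k)
            info[k].append(np.nan if val is None else float(val))
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for j, g in enumerate(v.genotypes):
            a = [x for x in g[:-1] if x >= 0]
            if len(a) == 2 and max(a) <= 1:
                row[j] = a[0] + a[1]
        dosage_rows.append(row)
    vcf.close()

    n = len(positions)
    qual = np.asarray(quals, dtype=float)
    info_arr = {
        k: np.asarray(vals, dtype=float)
        for k, vals in info.items()
        if n and not np.isnan(vals).all()
    }
    return GenotypeMatrix(
        chrom=np.asarray(chroms, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
        sample_ids=samples,
        dosages=(
            np.vstack(dosage_rows)
            if dosage_rows
            else np.empty((0, len(samples)), dtype=np.int8)
        ),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        qual=qual if n and not np.isnan(qual).all() else None,
        info=info_arr,
        is_biallelic=np.asarray(bial, dtype=bool),
    )


_GT = {0: "0/0", 1: "0/1", 2: "1/1", int(MISSING): "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal deterministic VCF 4.2 file.

    Dosages are emitted as unphased genotypes (dosage 1 -> ``0/1``).
    Output bytes are a pure function of the matrix.
    """
    for c in pd.unique(matrix.chrom):
        pos = matrix.positions[matrix.chrom == c]
        if len(np.unique(pos)) != len(pos):
            raise ValueError(f"duplicate positions on {c}")
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in pd.unique(matrix.chrom)]
    for tag, desc in (
        ("QD", "Variant confidence by depth"),
        ("FS", "Phred-scaled strand bias Fisher test p-value"),
        ("ReadPosRankSum", "Alt vs ref read position rank-sum Z"),
    ):
        if tag in matrix.info:
            lines.append(
                f'##INFO=<ID={tag},Number=1,Type=Float,Description="{desc}">'
            )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    lines.append(header + "".join(f"\t{s}" for s in matrix.sample_ids))
    for i in range(matrix.n_sites):
        qual = "."
        if matrix.qual is not None and not np.isnan(matrix.qual[i]):
            qual = _fmt_float(matrix.qual[i])
        info_parts = [
            f"{k}={_fmt_float(v[i])}"
            for k, v in matrix.info.items()
            if not np.isnan(v[i])
        ]
        row = [
            str(matrix.chrom[i]),
            str(matrix.positions[i]),
            ".",
            str(matrix.ref[i]),
            str(matrix.alt[i]),
            qual,
            ".",
            ";".join(info_parts) or ".",
            "GT",
        ]
        row += [_GT[int(d)] for d in matrix.dosages[i]]
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_population_map(path: str | os.PathLike) -> PopulationMap:
    """Read a TSV with columns sample, population, group, altitude."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str})
    required = {"sample", "population", "group", "altitude"}
    if not required.issubset(df.columns):
        raise ValueError(f"population map needs columns {sorted(required)}")
    return PopulationMap(df.set_index("sample"))


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV phenotype table (sample, sex, one column per parameter)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns or "sex" not in df.columns:
        raise ValueError("phenotype table needs 'sample' and 'sex' columns")
    df = df.set_index("sample")
    if df.index.has_duplicates:
        raise ValueError("duplicate sample ids in phenotype table")
    return df


def read_intervals(path: str | os.PathLike) -> IntervalSet:
    """Read gene intervals from BED or GFF3 (detected by extension).

    BED is taken as-is (0-based half-open); GFF3 start/end (1-based
    inclusive) become (start-1, end).
    """
    path = str(path)
    ext = os.path.splitext(path)[1].lower()
    out: list[tuple[str, int, int, str]] = []
    if ext == ".bed":
        with open(path) as fh:
            for ln in fh:
                ln = ln.strip()
                if not ln or ln.startswith(("#", "track", "browser")):
                    continue
                f = ln.split("\t")
                name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
                out.append((f[0], int(f[1]), int(f[2]), name))
    elif ext in (".gff", ".gff3"):
        with open(path) as fh:
            for ln in fh:
                ln = ln.strip()
                if not ln or ln.startswith("#"):
                    continue
                f = ln.split("\t")
                if len(f) < 9:
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                name = attrs.get("Name") or attrs.get("ID") or f"{f[0]}:{f[3]}"
                out.append((f[0], int(f[3]) - 1, int(f[4]), name))
    else:
        raise ValueError(f"unrecognised interval file extension: {ext}")
    return IntervalSet(out)
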