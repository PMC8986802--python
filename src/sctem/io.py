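"""File-format readers and writers.

All on-disk conventions live here: FASTA / gzipped FASTQ (via pysam's
fastx parser), BED6 annotations (0-based half-open), Bismark-dialect
.cov tables (1-based, start == end), plate sheets, counts matrices
(TSV and MTX triplet) and per-cell summary TSVs.  Writers emit
byte-stable output (fixed column order, fixed float formatting);
readers are strict and raise :class:`~sctem.errors.FormatError` naming
the file and line of the first offending record.
"""

from __future__ import annotations

import gzip
import io as _io
import os
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .errors import FormatError
from .methylation import CellMethylation
from .reference import PrimerPair, PrimerPlate, TEAnnotation
from .simulate import ReadPair


def _opener(path, mode="rt"):
    if str(path).endswith(".gz"):
        if "w" in mode:
            # fixed mtime and no embedded filename keep output
            # byte-stable across reruns
            raw = open(path, "wb")
            gz = gzip.GzipFile(filename="", fileobj=raw, mode="wb",
                               mtime=0)

            class _Wrapper(_io.TextIOWrapper):
                def close(self):  # flush trailer, then the raw handle
                    super().close()
                    raw.close()

            return _Wrapper(gz)
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            if rec.name in out:
                raise FormatError(f"{path}: duplicate sequence {rec.name}")
            out[rec.name] = rec.sequence.upper()
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------- FASTQ

def _strip_mate(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    """Read synchronized paired FASTQ; error on the first desync."""
    pairs = []
    with pysam.FastxFile(str(r1_path)) as f1, \
            pysam.FastxFile(str(r2_path)) as f2:
        for i, (a, b) in enumerate(zip(f1, f2), start=1):
            if _strip_mate(a.name) != _strip_mate(b.name):
                raise FormatError(
                    f"{r1_path}/{r2_path}: record {i}: desynchronized ids "
                    f"{a.name!r} vs {b.name!r}")
            pairs.append(ReadPair(_strip_mate(a.name), a.sequence,
                                  a.quality or "I" * len(a.sequence),
                                  b.sequence,
                                  b.quality or "I" * len(b.sequence)))
    n1 = sum(1 for _ in pysam.FastxFile(str(r1_path)))
    n2 = sum(1 for _ in pysam.FastxFile(str(r2_path)))
    if n1 != n2:
        raise FormatError(
            f"{r1_path}/{r2_path}: unequal record counts {n1} vs {n2}")
    return pairs


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path, r2_path) -> None:
    with _opener(r1_path, "wt") as f1, _opener(r2_path, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


# ------------------------------------------------------------------ BED

def write_bed(annotations: Sequence[TEAnnotation], path) -> None:
    """BED6; the name field carries ``element_id|family``."""
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t"
                     f"{a.element_id}|{a.family}\t0\t{a.strand}\n")


def read_bed(path) -> list[TEAnnotation]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{ln}: expected >= 6 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: non-integer coordinate") \
                    from e
            if start >= end or start < 0:
                raise FormatError(f"{path}:{ln}: bad interval {start}-{end}")
            if f[5] not in "+-":
                raise FormatError(f"{path}:{ln}: bad strand {f[5]!r}")
            name = f[3]
            element_id, _, family = name.partition("|")
            out.append(TEAnnotation(f[0], start, end, f[5],
                                    family or "unknown", element_id))
    return out


# ------------------------------------------------------------------ cov

def write_cov(cov: pd.DataFrame, path) -> None:
    """Bismark-dialect coverage: chrom, pos, pos, %, n_meth, n_unmeth."""
    with open(path, "w") as fh:
        for row in cov.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos}\t"
                     f"{row.meth_percent:.6g}\t{row.count_methylated}\t"
                     f"{row.count_unmethylated}\n")


def read_cov(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 6:
                raise FormatError(f"{path}:{ln}: expected 6 columns")
            try:
                start, end = int(f[1]), int(f[2])
                pct = float(f[3])
                cm, cu = int(f[4]), int(f[5])
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: malformed fields") from e
            if start != end or start < 1:
                raise FormatError(f"{path}:{ln}: cov positions must be "
                                  "1-based with start == end")
            if cm < 0 or cu < 0 or cm + cu == 0:
                raise FormatError(f"{path}:{ln}: bad counts {cm}/{cu}")
            if abs(pct - 100.0 * cm / (cm + cu)) > 0.05:
                raise FormatError(f"{path}:{ln}: percent inconsistent "
                                  "with counts")
            rows.append((f[0], start, pct, cm, cu))
    return pd.DataFrame(rows, columns=["chrom", "pos", "meth_percent",
                                       "count_methylated",
                                       "count_unmethylated"])


# ---------------------------------------------------------- plate sheet

PLATE_COLUMNS = ["well_id", "index_f", "index_r", "spacer_f", "spacer_r",
                 "orientation", "prime_f", "prime_r"]


def write_plate(plate: PrimerPlate, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#anchor_f\t{plate.anchor_f[0]}\t{plate.anchor_f[1]}\n")
        fh.write(f"#anchor_r\t{plate.anchor_r[0]}\t{plate.anchor_r[1]}\n")
        fh.write("\t".join(PLATE_COLUMNS) + "\n")
        for w in plate.wells.values():
            fh.write("\t".join([
                w.well_id, w.index_f, w.index_r, str(w.spacer_f),
                str(w.spacer_r), w.orientation, w.prime_f, w.prime_r,
            ]) + "\n")


def read_plate(path) -> PrimerPlate:
    wells: dict[str, PrimerPair] = {}
    anchor_f = anchor_r = (0, 0)
    with open(path) as fh:
        header_seen = False
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#anchor_f"):
                _, a, b = line.split("\t")
                anchor_f = (int(a), int(b))
                continue
            if line.startswith("#anchor_r"):
                _, a, b = line.split("\t")
                anchor_r = (int(a), int(b))
                continue
            if line.startswith("#"):
                continue
            f = line.split("\t")
            if not header_seen:
                if f != PLATE_COLUMNS:
                    raise FormatError(f"{path}:{ln}: bad plate header")
                header_seen = True
                continue
            if len(f) != len(PLATE_COLUMNS):
                raise FormatError(f"{path}:{ln}: expected "
                                  f"{len(PLATE_COLUMNS)} columns")
            try:
                well = PrimerPair(
                    well_id=f[0], index_f=f[1], index_r=f[2],
                    spacer_f=int(f[3]), spacer_r=int(f[4]),
                    prime_f=f[6], prime_r=f[7], orientation=f[5],
                )
            except Exception as e:
                raise FormatError(f"{path}:{ln}: {e}") from e
            if well.well_id in wells:
                raise FormatError(f"{path}:{ln}: duplicate well {f[0]}")
            wells[well.well_id] = well
    if not wells:
        raise FormatError(f"{path}: no wells")
    return PrimerPlate(wells=wells, anchor_f=anchor_f, anchor_r=anchor_r)


# ------------------------------------------------------- counts / misc

def write_counts_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature")


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative counts")
    return df


def write_counts_mtx(matrix: pd.DataFrame, prefix) -> None:
    """MTX triplet with sidecar feature/cell id files."""
    from scipy import io as spio
    from scipy import sparse
    spio.mmwrite(f"{prefix}.mtx", sparse.csr_matrix(matrix.to_numpy()))
    with open(f"{prefix}.features.tsv", "w") as fh:
        fh.writelines(f"{f}\n" for f in matrix.index)
    with open(f"{prefix}.cells.tsv", "w") as fh:
        fh.writelines(f"{c}\n" for c in matrix.columns)


def read_counts_mtx(prefix) -> pd.DataFrame:
    from scipy import io as spio
    m = spio.mmread(f"{prefix}.mtx").toarray()
    with open(f"{prefix}.features.tsv") as fh:
        feats = [x.strip() for x in fh if x.strip()]
    with open(f"{prefix}.cells.tsv") as fh:
        cells = [x.strip() for x in fh if x.strip()]
    return pd.DataFrame(m, index=feats, columns=cells)


SUMMARY_COLUMNS = ["cell_id", "mean_site_methylation",
                   "read_weighted_methylation", "n_unique_te_annotations",
                   "n_covered_cpg_sites", "chg_rate", "chh_rate",
                   "n_aligned_reads", "qc_pass"]


def write_summary_tsv(cells: Sequence[CellMethylation], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for c in cells:
            fh.write("\t".join([
                c.cell_id, f"{c.mean_site_methylation:.6g}",
                f"{c.read_weighted_methylation:.6g}",
                str(c.n_unique_te_annotations),
                str(c.n_covered_cpg_sites),
                f"{c.chg_rate:.6g}", f"{c.chh_rate:.6g}",
                str(c.n_aligned_reads), str(int(c.qc_pass)),
            ]) + "\n")


def read_summary_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df["qc_pass"] = df["qc_pass"].astype(bool)
    return df
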