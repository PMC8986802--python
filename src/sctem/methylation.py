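"""Reduced-alphabet bisulfite alignment and per-cell methylation.

Bisulfite conversion destroys the C/T distinction on the strand being
assayed, so alignment happens in a reduced ("three-letter") alphabet:
reads and reference are collapsed C->T (top strand) or G->A (bottom
strand) and compared by Hamming distance.  Non-directional mode tries
all four post-PCR strand configurations:

======  ===========  =========
config  orientation  reduction
======  ===========  =========
OT      forward      C->T
CTOT    revcomp      C->T
OB      revcomp      G->A
CTOB    forward      G->A
======  ===========  =========

Candidate placements come from a seeded k-mer index; seeds hitting more
reference positions than a cap are uninformative for unique placement
(they sit in sequence shared by many TE copies) and are skipped — reads
with no informative seed are inherently multi-mapping and are reported
unaligned, mirroring the unique-alignment-only policy downstream.

Per-cell methylation is the *unweighted mean over covered CpG sites* of
site-level methylation percent (not the read-weighted mean); QC demands
a minimum number of distinct annotated TE elements overlapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from . import _seq
from .errors import ConfigurationError, InsufficientDataError, \
    InvalidParameterError
from .reference import TEAnnotation
from .simulate import ReadPair

CONFIGS = ("OT", "CTOT", "OB", "CTOB")
# config -> (is_revcomp, reduction)
_CONFIG_DEF = {"OT": (False, "CT"), "CTOT": (True, "CT"),
               "OB": (True, "GA"), "CTOB": (False, "GA")}

CTX_CPG, CTX_CHG, CTX_CHH, CTX_NA = 0, 1, 2, 3
CTX_NAMES = ("CpG", "CHG", "CHH")


@dataclass(frozen=True)
class BisulfiteAlignment:
    read_id: str
    chrom: str
    start: int
    end: int
    strand_config: str
    n_mismatches: int
    unique: bool


@dataclass
class CellMethylation:
    """Per-cell summary of the site-mean methylation estimate and QC."""

    cell_id: str
    mean_site_methylation: float
    read_weighted_methylation: float
    n_unique_te_annotations: int
    n_covered_cpg_sites: int
    chg_rate: float
    chh_rate: float
    n_aligned_reads: int
    qc_pass: bool


class BisulfiteReference:
    """Indexed reference for reduced-alphabet alignment.

    Chromosomes are concatenated with N gaps into one coordinate space;
    two k-mer indexes (C->T and G->A reduced) provide seed lookups.
    """

    GAP = 50

    def __init__(self, genome: dict[str, str], seed_k: int = 16):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ConfigurationError("empty reference")
        self.seed_k = seed_k
        self.chroms = list(genome)
        parts, starts, pos = [], [], 0
        gap = np.full(self.GAP, _seq.N, dtype=np.uint8)
        for i, c in enumerate(self.chroms):
            if i:
                parts.append(gap)
                pos += self.GAP
            starts.append(pos)
            arr = _seq.encode(genome[c])
            parts.append(arr)
            pos += arr.size
        self.codes = np.concatenate(parts)
        self.chrom_starts = np.array(starts)
        self.chrom_lens = np.array([len(genome[c]) for c in self.chroms])
        self.ct = _seq.reduce_ct(self.codes)
        self.ga = _seq.reduce_ga(self.codes)
        self._ctx_top, self._ctx_bot = self._contexts()
        self._index = {
            "CT": self._build_index(self.ct),
            "GA": self._build_index(self.ga),
        }

    def _contexts(self):
        c = self.codes
        pad = np.concatenate([[_seq.N, _seq.N], c, [_seq.N, _seq.N]])
        top = np.full(c.size, CTX_NA, dtype=np.uint8)
        is_c = c == _seq.C
        nxt1, nxt2 = pad[3:3 + c.size], pad[4:4 + c.size]
        top[is_c & (nxt1 == _seq.G)] = CTX_CPG
        top[is_c & (nxt1 != _seq.G) & (nxt2 == _seq.G)] = CTX_CHG
        top[is_c & (nxt1 != _seq.G) & (nxt2 != _seq.G)] = CTX_CHH
        bot = np.full(c.size, CTX_NA, dtype=np.uint8)
        is_g = c == _seq.G
        prv1, prv2 = pad[1:1 + c.size], pad[0:c.size]
        bot[is_g & (prv1 == _seq.C)] = CTX_CPG
        bot[is_g & (prv1 != _seq.C) & (prv2 == _seq.C)] = CTX_CHG
        bot[is_g & (prv1 != _seq.C) & (prv2 != _seq.C)] = CTX_CHH
        return top, bot

    def _build_index(self, reduced: np.ndarray):
        k = self.seed_k
        km = _seq.kmer_codes(reduced, k)
        ok = _seq.kmer_valid(reduced, k)
        pos = np.flatnonzero(ok)
        km = km[ok]
        order = np.argsort(km, kind="stable")
        return km[order], pos[order].astype(np.int64)

    def reduced(self, which: str) -> np.ndarray:
        return self.ct if which == "CT" else self.ga

    def to_chrom_pos(self, gpos: np.ndarray):
        idx = np.searchsorted(self.chrom_starts, gpos, side="right") - 1
        return ([self.chroms[i] for i in idx],
                gpos - self.chrom_starts[idx])

    def global_pos(self, chrom: str, pos: int) -> int:
        return int(self.chrom_starts[self.chroms.index(chrom)] + pos)


# --------------------------------------------------------------------------
# alignment core
# --------------------------------------------------------------------------

def _candidates_for_config(reduced_reads: np.ndarray, ref: BisulfiteReference,
                           reduction: str, seed_step: int, count_cap: int):
    """Seed lookup: returns (read_idx, start) candidate arrays."""
    n, L = reduced_reads.shape
    k = ref.seed_k
    km_sorted, pos_sorted = ref._index[reduction]
    offsets = list(range(0, L - k + 1, seed_step))
    if offsets and offsets[-1] != L - k:
        offsets.append(L - k)
    pow5 = (5.0 ** np.arange(k - 1, -1, -1))
    rid_parts, start_parts = [], []
    for off in offsets:
        q = (reduced_reads[:, off:off + k].astype(np.float64) @ pow5)
        q = q.astype(np.uint64)
        lo = np.searchsorted(km_sorted, q, side="left")
        hi = np.searchsorted(km_sorted, q, side="right")
        cnt = hi - lo
        for c in range(1, count_cap + 1):
            m = cnt == c
            if not m.any():
                continue
            ridx = np.flatnonzero(m)
            base = lo[m]
            for j in range(c):
                rid_parts.append(ridx)
                start_parts.append(pos_sorted[base + j] - off)
    if not rid_parts:
        return (np.empty(0, dtype=np.int64),) * 2
    rid = np.concatenate(rid_parts)
    start = np.concatenate(start_parts)
    ok = (start >= 0) & (start + L <= ref.codes.size)
    return rid[ok], start[ok]


def _verify(reduced_reads: np.ndarray, ref_reduced: np.ndarray,
            rid: np.ndarray, start: np.ndarray, chunk: int = 200_000):
    """Hamming distance of each candidate window (N in ref counts)."""
    L = reduced_reads.shape[1]
    mm = np.empty(rid.size, dtype=np.int32)
    ar = np.arange(L)
    for s in range(0, rid.size, chunk):
        e = min(s + chunk, rid.size)
        win = ref_reduced[start[s:e, None] + ar]
        mm[s:e] = (win != reduced_reads[rid[s:e]]).sum(axis=1)
    return mm


def _align_batch(seqs: Sequence[str], ref: BisulfiteReference,
                 non_directional: bool, max_mismatch_rate: float,
                 seed_step: int, count_cap: int):
    """Align equal-length reads; returns per-read result arrays.

    Result: (aligned, start, config_idx, mm, multi) where ``aligned``
    means a unique minimal-mismatch placement under the rate threshold
    and ``multi`` flags reads rejected for ambiguity.
    """
    n = len(seqs)
    L = len(seqs[0])
    out_aligned = np.zeros(n, dtype=bool)
    out_multi = np.zeros(n, dtype=bool)
    out_start = np.full(n, -1, dtype=np.int64)
    out_cfg = np.full(n, -1, dtype=np.int8)
    out_mm = np.full(n, L + 1, dtype=np.int32)
    if n == 0 or L < ref.seed_k:
        return out_aligned, out_start, out_cfg, out_mm, out_multi

    mat = np.frombuffer("".join(seqs).encode("ascii"),
                        dtype=np.uint8).reshape(n, L)
    mat = _seq._CODE[mat]
    configs = CONFIGS if non_directional else ("OT", "CTOT")
    reduced_by_cfg = {}
    rid_all, start_all, cfg_all = [], [], []
    for ci, cfg in enumerate(CONFIGS):
        if cfg not in configs:
            continue
        is_rc, reduction = _CONFIG_DEF[cfg]
        oriented = _seq.revcomp_codes(mat) if is_rc else mat
        red = _seq.reduce_ct(oriented) if reduction == "CT" \
            else _seq.reduce_ga(oriented)
        reduced_by_cfg[ci] = red
        rid, start = _candidates_for_config(red, ref, reduction,
                                            seed_step, count_cap)
        rid_all.append(rid)
        start_all.append(start)
        cfg_all.append(np.full(rid.size, ci, dtype=np.int8))
    rid = np.concatenate(rid_all)
    start = np.concatenate(start_all)
    cfg = np.concatenate(cfg_all)
    if rid.size == 0:
        return out_aligned, out_start, out_cfg, out_mm, out_multi

    # deduplicate (read, config, start)
    order = np.lexsort((start, cfg, rid))
    rid, start, cfg = rid[order], start[order], cfg[order]
    keep = np.ones(rid.size, dtype=bool)
    keep[1:] = (np.diff(rid) != 0) | (np.diff(cfg) != 0) \
        | (np.diff(start) != 0)
    rid, start, cfg = rid[keep], start[keep], cfg[keep]

    mm = np.empty(rid.size, dtype=np.int32)
    for ci, red in reduced_by_cfg.items():
        m = cfg == ci
        if m.any():
            ref_red = ref.reduced(_CONFIG_DEF[CONFIGS[ci]][1])
            mm[m] = _verify(red, ref_red, rid[m], start[m])

    best = np.full(n, L + 1, dtype=np.int32)
    np.minimum.at(best, rid, mm)
    at_best = mm == best[rid]
    n_best = np.zeros(n, dtype=np.int64)
    np.add.at(n_best, rid[at_best], 1)

    max_mm = int(np.floor(max_mismatch_rate * L))
    first = np.full(n, -1, dtype=np.int64)
    idx_best = np.flatnonzero(at_best)
    # reversed so earlier candidates win the (irrelevant) tie-store
    first[rid[idx_best][::-1]] = idx_best[::-1]
    has = first >= 0
    sel = first[has]
    out_start[has] = start[sel]
    out_cfg[has] = cfg[sel]
    out_mm[has] = mm[sel]
    ok = has & (best <= max_mm)
    uniq = ok & (n_best == 1)
    out_aligned[:] = uniq
    out_multi[:] = ok & (n_best > 1)
    return out_aligned, out_start, out_cfg, out_mm, out_multi


def align_bisulfite(
    reads: Sequence[tuple[str, str]],
    reference: BisulfiteReference,
    non_directional: bool = True,
    max_mismatch_rate: float = 0.1,
    seed_step: int = 16,
    count_cap: int = 64,
) -> list[BisulfiteAlignment]:
    """Align single-end reads; only unique hits have ``unique=True``."""
    by_len: dict[int, list[int]] = {}
    for i, (_, s) in enumerate(reads):
        by_len.setdefault(len(s), []).append(i)
    results: list[BisulfiteAlignment | None] = [None] * len(reads)
    for L, idxs in by_len.items():
        seqs = [reads[i][1] for i in idxs]
        aligned, start, cfgi, mm, multi = _align_batch(
            seqs, reference, non_directional, max_mismatch_rate,
            seed_step, count_cap)
        for j, i in enumerate(idxs):
            if start[j] < 0:
                continue
            chrom, pos = reference.to_chrom_pos(np.array([start[j]]))
            results[i] = BisulfiteAlignment(
                read_id=reads[i][0], chrom=chrom[0], start=int(pos[0]),
                end=int(pos[0]) + L, strand_config=CONFIGS[cfgi[j]],
                n_mismatches=int(mm[j]), unique=bool(aligned[j]),
            )
    return [r for r in results if r is not None]


def align_pairs(
    pairs: Sequence[ReadPair],
    reference: BisulfiteReference,
    non_directional: bool = True,
    max_mismatch_rate: float = 0.1,
    max_insert: int = 2000,
    seed_step: int = 16,
    count_cap: int = 64,
) -> pd.DataFrame:
    """Align both mates of each pair; enforce pair consistency.

    A pair is kept when both mates align uniquely in the same reduction
    (OT/CTOT or OB/CTOB), in opposite orientations, within
    ``max_insert`` of each other.  Returns one row per *aligned* pair
    with mate start/length/config columns.
    """
    n = len(pairs)
    res = {}
    for mate in (1, 2):
        seqs = [p.seq1 if mate == 1 else p.seq2 for p in pairs]
        by_len: dict[int, list[int]] = {}
        for i, s in enumerate(seqs):
            by_len.setdefault(len(s), []).append(i)
        aligned = np.zeros(n, dtype=bool)
        start = np.full(n, -1, dtype=np.int64)
        cfgi = np.full(n, -1, dtype=np.int8)
        mm = np.full(n, -1, dtype=np.int32)
        ln = np.array([len(s) for s in seqs], dtype=np.int32)
        for L, idxs in by_len.items():
            a, st, cf, m, _ = _align_batch(
                [seqs[i] for i in idxs], reference, non_directional,
                max_mismatch_rate, seed_step, count_cap)
            ii = np.asarray(idxs)
            aligned[ii], start[ii], cfgi[ii], mm[ii] = a, st, cf, m
        res[mate] = (aligned, start, cfgi, mm, ln)

    a1, s1, c1, m1, l1 = res[1]
    a2, s2, c2, c2mm, l2 = res[2][0], res[2][1], res[2][2], res[2][3], res[2][4]
    red1 = np.where(c1 < 0, -1, (c1 >= 2).astype(np.int8))  # 0=CT, 1=GA
    red2 = np.where(c2 < 0, -1, (c2 >= 2).astype(np.int8))
    rc1 = np.isin(c1, (1, 2))  # CTOT, OB are revcomp-oriented
    rc2 = np.isin(c2, (1, 2))
    ok = a1 & a2 & (red1 == red2) & (rc1 != rc2) \
        & (np.abs(s1 - s2) <= max_insert)
    idx = np.flatnonzero(ok)
    return pd.DataFrame({
        "pair_idx": idx,
        "read_id": [pairs[i].read_id for i in idx],
        "start1": s1[idx], "len1": l1[idx],
        "config1": [CONFIGS[c] for c in c1[idx]],
        "mm1": m1[idx],
        "start2": s2[idx], "len2": l2[idx],
        "config2": [CONFIGS[c] for c in c2[idx]],
        "mm2": c2mm[idx],
    })


# --------------------------------------------------------------------------
# methylation extraction
# --------------------------------------------------------------------------

def extract_methylation(
    aligned: pd.DataFrame,
    pairs: Sequence[ReadPair],
    reference: BisulfiteReference,
) -> pd.DataFrame:
    """Per-cytosine calls from uniquely aligned pairs.

    Every reference cytosine (top strand for OT/CTOT, bottom for
    OB/CTOB) covered by a read yields one call; context comes from the
    reference, state from the read base (C retained = methylated on the
    assayed strand).  A cytosine covered by both mates is counted once
    (first mate wins).  Returns a frame with columns pair_idx, mate,
    gpos (concatenated-genome coordinate), strand, context, methylated.
    """
    frames = []
    for mate in (1, 2):
        sub = aligned
        starts = sub[f"start{mate}"].to_numpy()
        lens = sub[f"len{mate}"].to_numpy()
        cfgs = sub[f"config{mate}"].to_numpy()
        pidx = sub["pair_idx"].to_numpy()
        for L in np.unique(lens):
            for cfg in CONFIGS:
                m = (lens == L) & (cfgs == cfg)
                if not m.any():
                    continue
                is_rc, reduction = _CONFIG_DEF[cfg]
                rows = pidx[m]
                seqs = [pairs[i].seq1 if mate == 1 else pairs[i].seq2
                        for i in rows]
                matrix = _seq._CODE[np.frombuffer(
                    "".join(seqs).encode("ascii"), dtype=np.uint8
                ).reshape(len(seqs), L)]
                if is_rc:
                    matrix = _seq.revcomp_codes(matrix)
                st = starts[m]
                win = st[:, None] + np.arange(L)
                refc = reference.codes[win]
                if reduction == "CT":
                    target = refc == _seq.C
                    meth_base, unmeth_base = _seq.C, _seq.T
                    ctx_arr = reference._ctx_top
                    strand = "+"
                else:
                    target = refc == _seq.G
                    meth_base, unmeth_base = _seq.G, _seq.A
                    ctx_arr = reference._ctx_bot
                    strand = "-"
                readable = target & ((matrix == meth_base)
                                     | (matrix == unmeth_base))
                gpos = win[readable]
                frames.append(pd.DataFrame({
                    "pair_idx": np.repeat(rows, readable.sum(axis=1)),
                    "mate": np.int8(mate),
                    "gpos": gpos,
                    "strand": strand,
                    "context": ctx_arr[gpos],
                    "methylated": matrix[readable] == meth_base,
                }))
    if not frames:
        return pd.DataFrame(columns=["pair_idx", "mate", "gpos", "strand",
                                     "context", "methylated"])
    calls = pd.concat(frames, ignore_index=True)
    calls.sort_values(["pair_idx", "gpos", "mate"], inplace=True,
                      kind="stable")
    calls = calls.drop_duplicates(["pair_idx", "gpos"], keep="first")
    return calls.reset_index(drop=True)


def cov_from_calls(calls: pd.DataFrame,
                   reference: BisulfiteReference) -> pd.DataFrame:
    """Aggregate CpG calls into a Bismark-dialect coverage table.

    Columns: chrom, pos (1-based), meth_percent, count_methylated,
    count_unmethylated.  Positions are per-strand cytosine coordinates.
    """
    cpg = calls[calls["context"] == CTX_CPG]
    if len(cpg) == 0:
        return pd.DataFrame(columns=["chrom", "pos", "meth_percent",
                                     "count_methylated",
                                     "count_unmethylated"])
    grp = cpg.groupby("gpos")["methylated"].agg(["sum", "count"])
    gpos = grp.index.to_numpy()
    cm = grp["sum"].to_numpy().astype(np.int64)
    tot = grp["count"].to_numpy().astype(np.int64)
    chroms, pos0 = reference.to_chrom_pos(gpos)
    return pd.DataFrame({
        "chrom": chroms,
        "pos": pos0 + 1,
        "meth_percent": 100.0 * cm / tot,
        "count_methylated": cm,
        "count_unmethylated": tot - cm,
    })


# --------------------------------------------------------------------------
# per-cell estimate, QC, stability
# --------------------------------------------------------------------------

def count_unique_annotations(chrom_pos: pd.DataFrame,
                             annotations: Sequence[TEAnnotation]) -> int:
    """Distinct annotation elements overlapped by >= 1 covered site.

    ``chrom_pos`` needs chrom and 1-based pos columns; intervals are
    0-based half-open.
    """
    trees: dict[str, IntervalTree] = {}
    for a in annotations:
        trees.setdefault(a.chrom, IntervalTree()).addi(
            a.start, a.end, a.element_id)
    hit: set[str] = set()
    for chrom, grp in chrom_pos.groupby("chrom", observed=True):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for p in np.unique(grp["pos"].to_numpy()):
            for iv in tree.at(int(p) - 1):
                hit.add(iv.data)
    return len(hit)


def cell_methylation(
    cov: pd.DataFrame,
    annotations: Sequence[TEAnnotation],
    te_site_threshold: int = 1000,
    cell_id: str = "",
    chg_rate: float = float("nan"),
    chh_rate: float = float("nan"),
    n_aligned_reads: int = 0,
) -> CellMethylation:
    """Site-mean methylation estimate with element-coverage QC.

    The estimator is the unweighted mean over covered CpG sites of each
    site's methylation percent; the read-weighted mean is carried as a
    diagnostic.  ``qc_pass`` requires at least ``te_site_threshold``
    distinct annotated elements overlapped (1000 by default, 500 in the
    low-coverage preset).
    """
    n_sites = len(cov)
    if n_sites == 0:
        return CellMethylation(cell_id, float("nan"), float("nan"), 0, 0,
                               chg_rate, chh_rate, n_aligned_reads, False)
    mean_site = float(cov["meth_percent"].mean())
    cm = cov["count_methylated"].sum()
    cu = cov["count_unmethylated"].sum()
    read_weighted = 100.0 * cm / (cm + cu)
    n_annot = count_unique_annotations(cov[["chrom", "pos"]], annotations)
    return CellMethylation(
        cell_id=cell_id,
        mean_site_methylation=mean_site,
        read_weighted_methylation=read_weighted,
        n_unique_te_annotations=n_annot,
        n_covered_cpg_sites=n_sites,
        chg_rate=chg_rate,
        chh_rate=chh_rate,
        n_aligned_reads=n_aligned_reads,
        qc_pass=n_annot >= te_site_threshold,
    )


def conversion_qc(calls: pd.DataFrame, ceiling: float = 2.0
                  ) -> tuple[float, float, bool]:
    """Non-CpG methylation rates as a bisulfite-conversion check.

    Returns (chg_rate%, chh_rate%, flag); the flag is raised when the
    CHG rate exceeds the ceiling or no non-CpG calls exist.
    """
    chg = calls[calls["context"] == CTX_CHG]
    chh = calls[calls["context"] == CTX_CHH]
    if len(chg) == 0 and len(chh) == 0:
        return float("nan"), float("nan"), True
    chg_rate = 100.0 * chg["methylated"].mean() if len(chg) else float("nan")
    chh_rate = 100.0 * chh["methylated"].mean() if len(chh) else float("nan")
    flag = bool(not np.isfinite(chg_rate) or chg_rate > ceiling)
    return float(chg_rate), float(chh_rate), flag


def _site_mean_from_subset(gpos: np.ndarray, meth: np.ndarray) -> float:
    """Unweighted site-mean methylation (%) from flat CpG call arrays."""
    if gpos.size == 0:
        return float("nan")
    uniq, inv = np.unique(gpos, return_inverse=True)
    sums = np.bincount(inv, weights=meth.astype(np.float64))
    cnts = np.bincount(inv)
    return float(100.0 * np.mean(sums / cnts))


def bootstrap_stability(
    calls: pd.DataFrame,
    depths: Sequence[int],
    n_reps: int = 20,
    seed: int = 0,
    with_replacement: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Depth-stability of the site-mean estimate by read subsampling.

    Aligned read pairs are subsampled (without replacement by default,
    rarefaction semantics) at each depth, ``n_reps`` times, and the
    site-mean CpG methylation recomputed.  Returns (long table with
    depth/replicate/estimate, per-depth range table).  Depths exceeding
    the available pair count are skipped with a warning.
    """
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    cpg = calls[calls["context"] == CTX_CPG]
    pair_ids = calls["pair_idx"].to_numpy()
    uniq_pairs = np.unique(pair_ids)
    n_avail = uniq_pairs.size
    cpg_pairs = cpg["pair_idx"].to_numpy()
    cpg_gpos = cpg["gpos"].to_numpy()
    cpg_meth = cpg["methylated"].to_numpy()
    lookup_size = int(uniq_pairs.max()) + 1 if n_avail else 1

    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > n_avail:
            warnings.warn(f"depth {depth} exceeds available aligned pairs "
                          f"({n_avail}); skipped")
            continue
        for rep in range(n_reps):
            chosen = rng.choice(uniq_pairs, size=depth,
                                replace=with_replacement)
            mask = np.zeros(lookup_size, dtype=bool)
            mask[chosen] = True
            sel = mask[cpg_pairs]
            est = _site_mean_from_subset(cpg_gpos[sel], cpg_meth[sel])
            rows.append((depth, rep, est, depth))
    table = pd.DataFrame(rows, columns=["depth", "replicate", "estimate",
                                        "n_pairs"])
    if len(table):
        rng_tbl = table.groupby("depth")["estimate"] \
            .agg(lambda s: s.max() - s.min()).rename("range").reset_index()
    else:
        rng_tbl = pd.DataFrame(columns=["depth", "range"])
    return table, rng_tbl


def bulk_tile_methylation(cov: pd.DataFrame, tile_size: int = 3000
                          ) -> tuple[pd.DataFrame, float]:
    """Fixed-tile averaging of site methylation, plus the global mean.

    The genome is partitioned into ``tile_size`` bp tiles from
    coordinate 0; the global value is the mean over tiles containing at
    least one covered site (the convention used for genome-wide
    bisulfite libraries).
    """
    if tile_size < 1:
        raise InvalidParameterError("tile_size must be >= 1")
    if len(cov) == 0:
        return pd.DataFrame(columns=["chrom", "tile", "meth_percent",
                                     "n_sites"]), float("nan")
    df = cov.copy()
    df["tile"] = (df["pos"] - 1) // tile_size
    tiles = df.groupby(["chrom", "tile"], observed=True)["meth_percent"] \
        .agg(["mean", "count"]).reset_index()
    tiles.columns = ["chrom", "tile", "meth_percent", "n_sites"]
    return tiles, float(tiles["meth_percent"].mean())


def surrogate_validation(
    covs: dict[str, pd.DataFrame],
    annotations: Sequence[TEAnnotation],
    family: str,
) -> dict[str, float]:
    """Regress per-cell TE-family methylation on global methylation.

    For each cell the global site-mean and the site-mean restricted to
    annotations of ``family`` are computed; an OLS fit of TE on global
    across cells quantifies how well TE methylation tracks the global
    level (slope, intercept, r2, p).
    """
    if len(covs) < 3:
        raise InsufficientDataError("surrogate validation needs >= 3 cells")
    fam = [a for a in annotations if a.family == family]
    trees: dict[str, IntervalTree] = {}
    for a in fam:
        trees.setdefault(a.chrom, IntervalTree()).addi(a.start, a.end)
    g_vals, t_vals = [], []
    for cell, cov in covs.items():
        if len(cov) == 0:
            continue
        g_vals.append(float(cov["meth_percent"].mean()))
        in_fam = np.zeros(len(cov), dtype=bool)
        for i, (c, p) in enumerate(zip(cov["chrom"], cov["pos"])):
            tree = trees.get(c)
            if tree is not None and tree.overlaps_point(int(p) - 1):
                in_fam[i] = True
        sub = cov.loc[in_fam, "meth_percent"]
        t_vals.append(float(sub.mean()) if len(sub) else float("nan"))
    x = np.asarray(g_vals)
    y = np.asarray(t_vals)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise InsufficientDataError("fewer than 3 cells with coverage")
    if np.allclose(y[ok], y[ok][0]) and np.allclose(x[ok], x[ok][0]):
        # degenerate: identical points; identity fit by convention
        return {"slope": 1.0, "intercept": 0.0, "r2": 1.0, "p": 0.0,
                "n_cells": int(ok.sum())}
    fit = stats.linregress(x[ok], y[ok])
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r2": float(fit.rvalue ** 2), "p": float(fit.pvalue),
            "n_cells": int(ok.sum())}
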