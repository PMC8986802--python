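"""Synthetic scTEM-seq libraries and matched expression matrices.

The simulator emulates the statistical structure of amplicon bisulfite
sequencing of SINE elements in single cells:

* per-cell, per-CpG methylation states drawn once (one epiallele per
  locus) at the cell's true methylation level;
* single-molecule bisulfite chemistry — unmethylated C converted to T
  with failure rate ``conversion_failure``, methylated C erroneously
  converted with rate ``inappropriate_conversion`` — fixed per site
  because a single cell contributes one template molecule per locus;
* methylation-dependent amplification bias: template loci are drawn
  with weight (1 + amp_bias)**m where m is the number of methylated
  CpGs in the template;
* the read layout index(8) + spacer(0-5 N) + priming sequence +
  bisulfite-converted insert, with mate roles swapped in reversed
  wells;
* uniform per-base sequencing error.

All randomness flows from per-cell seeds; pooling derives per-cell
seeds from a single master seed so fixtures are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import _seq
from .errors import ConfigurationError, InvalidParameterError
from .reference import PrimerPlate, TEAnnotation

READ_LEN_DEFAULT = 150
QUAL_CHAR = "I"  # constant Phred+33 quality (Q40)


class ReadPair(NamedTuple):
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


@dataclass
class CellSimParams:
    """Ground-truth generative parameters for one cell's library."""

    cell_id: str
    well_id: str
    true_methylation: float
    conversion_failure: float = 0.007
    inappropriate_conversion: float = 0.005
    amp_bias: float = 0.1
    n_read_pairs: int = 20000
    seq_error: float = 0.001
    read_len: int = READ_LEN_DEFAULT
    seed: int = 0

    def __post_init__(self):
        for name in ("true_methylation", "conversion_failure",
                     "inappropriate_conversion", "seq_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")
        if self.amp_bias < 0:
            raise InvalidParameterError("amp_bias must be >= 0")
        if self.n_read_pairs < 0:
            raise InvalidParameterError("n_read_pairs must be >= 0")


@dataclass
class CellTruth:
    """Realized ground truth for one simulated cell.

    ``site_pos`` are genome coordinates (0-based) of CpG cytosines in
    amplifiable inserts; ``site_methylated`` is the pre-chemistry
    epiallele state and ``site_observed`` the post-chemistry base
    identity (True = reads show C).  ``provenance`` maps each read id
    to its template element and coordinates.
    """

    cell_id: str
    true_methylation: float
    chrom: str
    site_pos: np.ndarray
    site_methylated: np.ndarray
    site_observed: np.ndarray
    provenance: pd.DataFrame

    @property
    def realized_methylation(self) -> float:
        """Mean pre-chemistry methylation over simulated CpG sites."""
        if self.site_pos.size == 0:
            return float("nan")
        return float(self.site_methylated.mean())

    @property
    def site_states(self) -> dict[tuple[str, int], bool]:
        return {
            (self.chrom, int(p)): bool(m)
            for p, m in zip(self.site_pos, self.site_methylated)
        }


def _apply_seq_errors(seq_codes: np.ndarray, n_err: int,
                      rng: np.random.Generator) -> np.ndarray:
    pos = rng.choice(seq_codes.size, size=n_err, replace=False)
    out = seq_codes.copy()
    out[pos] = (out[pos] + rng.integers(1, 4, size=n_err)) % 4
    return out


def simulate_cell(
    genome: dict[str, str],
    annotations: Sequence[TEAnnotation],
    plate: PrimerPlate,
    params: CellSimParams,
) -> tuple[list[ReadPair], CellTruth]:
    """Generate one cell's paired amplicon bisulfite reads plus truth."""
    if params.well_id not in plate.wells:
        raise ConfigurationError(f"unknown well {params.well_id!r}")
    well = plate.wells[params.well_id]
    rng = np.random.default_rng(params.seed)

    chroms = {a.chrom for a in annotations}
    if len(chroms) > 1:
        raise ConfigurationError("simulate_cell expects a single contig")
    chrom = chroms.pop() if chroms else next(iter(genome))
    codes = _seq.encode(genome[chrom])
    cpg_start = np.zeros(codes.size, dtype=bool)
    cpg_start[:-1] = (codes[:-1] == _seq.C) & (codes[1:] == _seq.G)

    f0, f1 = plate.anchor_f
    r0, r1 = plate.anchor_r
    insert_len = r0 - f1

    # amplifiable loci: annotated copies whose amplicon fits the contig
    loci = [a for a in annotations
            if a.start + f0 >= 0 and a.start + r1 <= codes.size
            and insert_len > 0]
    empty_truth = CellTruth(
        params.cell_id, params.true_methylation, chrom,
        np.empty(0, dtype=np.int64), np.empty(0, dtype=bool),
        np.empty(0, dtype=bool),
        pd.DataFrame(columns=["read_id", "element_id", "insert_start",
                              "insert_end", "well_id"]),
    )
    if not loci or params.n_read_pairs == 0:
        if not loci:
            warnings.warn(f"cell {params.cell_id}: no amplifiable loci; "
                          "emitting empty library")
        return [], empty_truth

    # --- per-copy methylation states and converted inserts -------------
    conv_inserts: list[np.ndarray] = []
    m_counts = np.zeros(len(loci), dtype=np.int64)
    all_pos: list[np.ndarray] = []
    all_meth: list[np.ndarray] = []
    all_obs: list[np.ndarray] = []
    for k, a in enumerate(loci):
        t0, t1 = a.start + f1, a.start + r0
        ins = codes[t0:t1].copy()
        c_off = np.flatnonzero(ins == _seq.C)
        is_cpg = cpg_start[t0 + c_off]
        cpg_off = c_off[is_cpg]
        other_off = c_off[~is_cpg]
        meth = rng.random(cpg_off.size) < params.true_methylation
        # post-chemistry observed base at each C (True = stays C)
        obs_cpg = meth & (rng.random(cpg_off.size)
                          >= params.inappropriate_conversion)
        # unmethylated CpG C escapes conversion at the failure rate
        obs_cpg |= (~meth) & (rng.random(cpg_off.size)
                              < params.conversion_failure)
        obs_other = rng.random(other_off.size) < params.conversion_failure
        ins[cpg_off[~obs_cpg]] = _seq.T
        ins[other_off[~obs_other]] = _seq.T
        conv_inserts.append(ins)
        m_counts[k] = int(meth.sum())
        all_pos.append(t0 + cpg_off)
        all_meth.append(meth)
        all_obs.append(obs_cpg)

    truth = CellTruth(
        params.cell_id, params.true_methylation, chrom,
        np.concatenate(all_pos), np.concatenate(all_meth),
        np.concatenate(all_obs), pd.DataFrame(),
    )

    # --- draw template loci with amplification bias ---------------------
    w = (1.0 + params.amp_bias) ** m_counts.astype(np.float64)
    p = w / w.sum()
    drawn = rng.choice(len(loci), size=params.n_read_pairs, p=p)

    # --- assemble reads -------------------------------------------------
    reversed_well = well.orientation == "reversed"
    idx_f = _seq.encode(well.index_f)
    idx_r = _seq.encode(well.index_r)
    prime_f = _seq.encode(well.prime_f)
    prime_r = _seq.encode(well.prime_r)

    fwd_payload_len = params.read_len - _seq_len(idx_f) - well.spacer_f
    rev_payload_len = params.read_len - _seq_len(idx_r) - well.spacer_r

    # per-copy payloads (primer + converted insert, truncated to fit)
    fwd_payloads = [
        np.concatenate([prime_f, ins])[:fwd_payload_len]
        for ins in conv_inserts
    ]
    rev_payloads = [
        np.concatenate([prime_r, _seq.revcomp_codes(ins)])[:rev_payload_len]
        for ins in conv_inserts
    ]

    n = params.n_read_pairs
    spacer_f_bases = rng.integers(0, 4, size=(n, well.spacer_f)).astype(np.uint8)
    spacer_r_bases = rng.integers(0, 4, size=(n, well.spacer_r)).astype(np.uint8)
    # expected errors per read are small; draw counts then place
    len_f = _seq_len(idx_f) + well.spacer_f + len(fwd_payloads[0])
    len_r = _seq_len(idx_r) + well.spacer_r + len(rev_payloads[0])
    nerr_f = rng.binomial(len_f, params.seq_error, size=n)
    nerr_r = rng.binomial(len_r, params.seq_error, size=n)

    pairs: list[ReadPair] = []
    prov_rows = []
    for i in range(n):
        k = drawn[i]
        fwd = np.concatenate([idx_f, spacer_f_bases[i], fwd_payloads[k]])
        rev = np.concatenate([idx_r, spacer_r_bases[i], rev_payloads[k]])
        if nerr_f[i]:
            fwd = _apply_seq_errors(fwd, nerr_f[i], rng)
        if nerr_r[i]:
            rev = _apply_seq_errors(rev, nerr_r[i], rng)
        read_id = f"{params.cell_id}:{i:06d}"
        if reversed_well:
            r1, r2 = rev, fwd
        else:
            r1, r2 = fwd, rev
        pairs.append(ReadPair(
            read_id,
            _seq.decode(r1), QUAL_CHAR * r1.size,
            _seq.decode(r2), QUAL_CHAR * r2.size,
        ))
        a = loci[k]
        prov_rows.append((read_id, a.element_id, a.start + f1, a.start + r0,
                          params.well_id))
    truth.provenance = pd.DataFrame(
        prov_rows,
        columns=["read_id", "element_id", "insert_start", "insert_end",
                 "well_id"],
    )
    return pairs, truth


def _seq_len(arr: np.ndarray) -> int:
    return int(arr.size)


def derive_cell_seed(master_seed: int, index: int) -> int:
    """Deterministic per-cell seed from a master seed (stays < 2**31)."""
    return int(np.random.SeedSequence([master_seed, index])
               .generate_state(1)[0] % (2 ** 31))


def simulate_plate(
    genome: dict[str, str],
    annotations: Sequence[TEAnnotation],
    plate: PrimerPlate,
    per_cell_params: Sequence[CellSimParams],
    include_negatives: int = 0,
    contamination_pairs: int = 0,
    seed: int = 0,
) -> tuple[list[ReadPair], pd.DataFrame, dict[str, CellTruth]]:
    """Pool several cells' libraries in seeded random order.

    Returns the shuffled pooled read pairs, a truth table mapping every
    read id to its cell/well/template, and the per-cell CellTruth
    objects.  Negative-control wells are unused wells that contribute
    ``contamination_pairs`` low-level contaminating read pairs each
    (default none).
    """
    wells_used = [p.well_id for p in per_cell_params]
    if len(set(wells_used)) != len(wells_used):
        raise ConfigurationError("duplicate well assignment across cells")

    all_pairs: list[ReadPair] = []
    rows: list[pd.DataFrame] = []
    truths: dict[str, CellTruth] = {}
    for params in per_cell_params:
        pairs, truth = simulate_cell(genome, annotations, plate, params)
        all_pairs.extend(pairs)
        truths[params.cell_id] = truth
        if len(truth.provenance):
            df = truth.provenance.copy()
            df["cell_id"] = params.cell_id
            rows.append(df)

    free = [w for w in plate.wells if w not in set(wells_used)]
    if include_negatives > len(free):
        raise ConfigurationError("not enough free wells for negatives")
    for j in range(include_negatives):
        wid = free[j]
        if contamination_pairs > 0:
            neg = CellSimParams(
                cell_id=f"neg_{wid}", well_id=wid, true_methylation=0.85,
                n_read_pairs=contamination_pairs,
                seed=derive_cell_seed(seed, 10_000 + j),
            )
            pairs, truth = simulate_cell(genome, annotations, plate, neg)
            all_pairs.extend(pairs)
            truths[neg.cell_id] = truth
            if len(truth.provenance):
                df = truth.provenance.copy()
                df["cell_id"] = neg.cell_id
                rows.append(df)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(all_pairs))
    pooled = [all_pairs[i] for i in order]
    truth_table = (
        pd.concat(rows, ignore_index=True)
        if rows else pd.DataFrame(columns=["read_id", "element_id",
                                           "insert_start", "insert_end",
                                           "well_id", "cell_id"])
    )
    return pooled, truth_table, truths


# --------------------------------------------------------------------------
# matched expression matrices
# --------------------------------------------------------------------------

_TE_EXPR_FAMILIES = (
    ("Alu", "SINE"), ("L1", "LINE"), ("ERV1", "LTR"), ("ERVL", "LTR"),
    ("MIR", "SINE"), ("L2", "LINE"), ("TcMar-Tigger", "DNA"),
)


def te_feature_id(index: int, family: str, te_class: str) -> str:
    return f"te{index:05d}|{family}:{te_class}"


def simulate_expression(
    n_genes: int,
    n_tes: int,
    cells: Sequence[tuple[str, float]] | Sequence[CellTruth],
    planted: Sequence[tuple[int, int, float]] = (),
    library_size: int = 1_000_000,
    seed: int = 0,
    dispersion: float = 0.3,
) -> pd.DataFrame:
    """Negative-binomial counts with optional methylation-linked features.

    ``cells`` is a list of (cell_id, methylation fraction) tuples or
    CellTruth objects.  ``planted`` entries are (feature_index, sign,
    effect): feature_index addresses the concatenated gene+TE feature
    list, sign is +1/-1, and effect is the natural-log fold change per
    unit change in methylation fraction.  Unplanted features are
    independent of methylation.  Expected column sums equal
    ``library_size``.
    """
    cell_items = [
        (c.cell_id, c.true_methylation) if isinstance(c, CellTruth) else c
        for c in cells
    ]
    cell_ids = [c[0] for c in cell_items]
    meth = np.array([c[1] for c in cell_items], dtype=float)
    rng = np.random.default_rng(seed)

    features = [f"gene{i:05d}" for i in range(n_genes)]
    fam_draw = rng.integers(0, len(_TE_EXPR_FAMILIES), size=n_tes)
    features += [
        te_feature_id(i, *_TE_EXPR_FAMILIES[fam_draw[i]]) for i in range(n_tes)
    ]
    n_feat = n_genes + n_tes
    for idx, sign, effect in planted:
        if not (0 <= idx < n_feat):
            raise InvalidParameterError(f"planted feature index {idx} invalid")
        if sign not in (-1, 1):
            raise InvalidParameterError("planted sign must be +1 or -1")
        if effect < 0:
            raise InvalidParameterError("planted effect must be >= 0")

    base = rng.normal(2.0, 1.5, size=n_feat)
    logmu = np.tile(base[:, None], (1, len(cell_ids))).astype(float)
    centred = meth - meth.mean()
    for idx, sign, effect in planted:
        logmu[idx] += sign * effect * centred
    mu = np.exp(logmu)
    mu *= library_size / mu.sum(axis=0, keepdims=True)
    if dispersion > 0:
        lam = rng.gamma(1.0 / dispersion, mu * dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)
    return pd.DataFrame(counts, index=features, columns=cell_ids)
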