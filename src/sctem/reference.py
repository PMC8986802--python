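"""TE consensus, synthetic mini-genome and primer-plate models.

The assay targets a high-copy SINE consensus (AluYa5-like): one pair of
bisulfite-space primers amplifies thousands of diverged genomic copies
at once, and per-well internal dual indexes identify the cell.  This
module builds desk-scale stand-ins for the three reference artefacts:

* a consensus sequence with a controlled CpG density,
* a mini-genome of diverged consensus copies with BED-style annotations,
* a 96-well primer plate carrying 8 bp dual indexes, 0-5 N spacers and
  per-well amplicon orientation.

A user-supplied consensus FASTA or plate sheet (TSV) drops in unchanged
through :mod:`sctem.io`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import _seq
from .errors import GenerationError, InvalidParameterError

# Fixed partial adaptors added 5' of the internal index during library
# prep; they are upstream of the sequenced insert and never appear in
# reads, but are carried on the plate model for completeness.
ADAPTOR_F = "CTACACGACGCTCTTCCGATCT"
ADAPTOR_R = "CAGACGTGTGCTCTTCCGATCT"

TE_FAMILIES = ("AluY", "AluSx", "AluYa5", "AluSq")
TE_FAMILY_WEIGHTS = (0.55, 0.2, 0.15, 0.1)

INDEX_LEN = 8
MAX_SPACER = 5


@dataclass(frozen=True)
class TEConsensus:
    """A TE consensus sequence with pre-computed CpG offsets."""

    name: str
    sequence: str
    cpg_positions: tuple[int, ...]

    @classmethod
    def from_sequence(cls, name: str, sequence: str) -> "TEConsensus":
        sequence = sequence.upper()
        if len(sequence) < 100:
            raise InvalidParameterError(
                f"consensus length {len(sequence)} < 100"
            )
        if set(sequence) - set("ACGT"):
            raise InvalidParameterError("consensus must be over A/C/G/T")
        return cls(name, sequence, tuple(_seq.find_cpg_positions(sequence)))

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class TEAnnotation:
    """One annotated TE copy: 0-based half-open interval on a contig."""

    chrom: str
    start: int
    end: int
    strand: str
    family: str
    element_id: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InvalidParameterError(
                f"bad interval {self.start}-{self.end} for {self.element_id}"
            )
        if self.strand not in "+-":
            raise InvalidParameterError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class PrimerPair:
    """One well of the plate: indexes, spacers, priming sequences."""

    well_id: str
    index_f: str
    index_r: str
    spacer_f: int
    spacer_r: int
    prime_f: str
    prime_r: str
    adaptor_f: str = ADAPTOR_F
    adaptor_r: str = ADAPTOR_R
    orientation: str = "forward"

    def __post_init__(self):
        if len(self.index_f) != INDEX_LEN or len(self.index_r) != INDEX_LEN:
            raise InvalidParameterError("indexes must be 8 nt")
        if not (0 <= self.spacer_f <= MAX_SPACER
                and 0 <= self.spacer_r <= MAX_SPACER):
            raise InvalidParameterError("spacer length must be 0-5")
        if self.orientation not in ("forward", "reversed"):
            raise InvalidParameterError(
                f"unknown orientation {self.orientation!r}"
            )


@dataclass
class PrimerPlate:
    """A plate of uniquely indexed primer pairs sharing amplicon anchors.

    ``anchor_f``/``anchor_r`` are the 0-based half-open windows on the
    consensus where the forward and reverse primers anneal; the amplified
    insert between the primer 3' ends is ``[anchor_f[1], anchor_r[0])``.
    """

    wells: dict[str, PrimerPair]
    anchor_f: tuple[int, int]
    anchor_r: tuple[int, int]
    n_internal_combinations: int = 0

    def __post_init__(self):
        if not self.n_internal_combinations:
            self.n_internal_combinations = len(self.wells)

    def min_index_distance(self) -> int:
        """Minimum pairwise Hamming distance of concatenated index pairs."""
        concats = [w.index_f + w.index_r for w in self.wells.values()]
        if len(concats) < 2:
            return 2 * INDEX_LEN
        return min(
            _hamming(a, b) for a, b in itertools.combinations(concats, 2)
        )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def well_ids(n: int) -> list[str]:
    """Row-major 96-well ids A1..H12, truncated to the first n."""
    ids = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]
    return ids[:n]


def build_consensus(length: int, cpg_density: float, seed: int,
                    name: str = "AluYa5-like") -> TEConsensus:
    """Generate a random consensus with ~``cpg_density * length`` CpGs.

    The backbone is drawn CpG-free and the requested number of CG
    dinucleotides is then planted at positions spaced >= 2 apart, so the
    realized CpG count equals the target exactly.
    """
    if length < 100:
        raise InvalidParameterError(f"length {length} < 100")
    if not (0.0 < cpg_density < 0.5):
        raise InvalidParameterError(f"cpg_density {cpg_density} out of (0, 0.5)")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length).astype(np.uint8)
    # scrub accidental CG dinucleotides from the backbone
    for _ in range(100):
        cg = np.flatnonzero((codes[:-1] == _seq.C) & (codes[1:] == _seq.G))
        if cg.size == 0:
            break
        codes[cg + 1] = rng.choice([_seq.A, _seq.C, _seq.T], size=cg.size)
    else:  # pragma: no cover - effectively unreachable
        raise GenerationError("could not scrub backbone CpGs")

    n_cpg = int(round(cpg_density * length))
    order = rng.permutation(length - 1)
    planted: list[int] = []
    for p in order:
        if all(abs(p - q) >= 2 for q in planted):
            planted.append(int(p))
            if len(planted) == n_cpg:
                break
    if len(planted) < n_cpg:
        raise GenerationError("could not place requested CpG count")
    for p in planted:
        codes[p] = _seq.C
        codes[p + 1] = _seq.G
    # planting a C cannot create a CG start at p-1 (needs G at p) and a
    # planted G cannot start one, so the CpG set is exactly `planted`
    return TEConsensus.from_sequence(name, _seq.decode(codes))


def synth_genome(
    consensus: TEConsensus,
    n_copies: int,
    divergence: float,
    flank_len: int = 60,
    seed: int = 0,
    chrom: str = "te_contig",
) -> tuple[dict[str, str], list[TEAnnotation]]:
    """Concatenate diverged consensus copies separated by random flanks.

    Each copy is an independently substituted version of the consensus
    (per-base substitution probability ``divergence``); annotations span
    the inserted copies exactly, sorted and non-overlapping.
    """
    if n_copies < 1:
        raise InvalidParameterError("n_copies must be >= 1")
    if not (0.0 <= divergence <= 0.2):
        raise InvalidParameterError(f"divergence {divergence} out of [0, 0.2]")
    rng = np.random.default_rng(seed)
    cons = _seq.encode(consensus.sequence)
    L = cons.size
    parts: list[np.ndarray] = []
    annots: list[TEAnnotation] = []
    pos = 0
    fam_idx = rng.choice(
        len(TE_FAMILIES), size=n_copies, p=np.asarray(TE_FAMILY_WEIGHTS)
    )
    for i in range(n_copies):
        flank = rng.integers(0, 4, size=flank_len).astype(np.uint8)
        parts.append(flank)
        pos += flank_len
        copy = cons.copy()
        if divergence > 0:
            hit = np.flatnonzero(rng.random(L) < divergence)
            # substitute with one of the three other bases
            copy[hit] = (copy[hit] + rng.integers(1, 4, size=hit.size)) % 4
        parts.append(copy)
        annots.append(
            TEAnnotation(
                chrom=chrom,
                start=pos,
                end=pos + L,
                strand="+",
                family=TE_FAMILIES[fam_idx[i]],
                element_id=f"te{i:06d}",
            )
        )
        pos += L
    parts.append(rng.integers(0, 4, size=flank_len).astype(np.uint8))
    genome = _seq.decode(np.concatenate(parts))
    return {chrom: genome}, annots


def _best_primer_window(consensus: TEConsensus, lo: int, hi: int,
                        primer_len: int, prefer_right: bool) -> tuple[int, int]:
    """Window in [lo, hi) of primer_len with the fewest CpG cytosines."""
    cpg = set(consensus.cpg_positions)
    best = None
    starts = range(lo, hi - primer_len + 1)
    for s in starts:
        n = sum(1 for p in cpg if s <= p < s + primer_len)
        key = (n, -(s) if prefer_right else s)
        if best is None or key < best[0]:
            best = (key, s)
    if best is None:
        raise GenerationError("consensus too short for primer window")
    s = best[1]
    return s, s + primer_len


def design_plate(
    consensus: TEConsensus,
    n_wells: int = 96,
    seed: int = 0,
    primer_len: int = 24,
    max_mismatch: int = 1,
) -> PrimerPlate:
    """Design an indexed primer plate against the consensus.

    Priming sequences are the fully bisulfite-converted consensus at two
    fixed anchor windows (forward: C->T top strand; reverse: reverse
    complement, G->A), the windows chosen to minimise CpG overlap.  Each
    well receives a unique 8+8 bp index pair with concatenated pairwise
    Hamming distance > 2*max_mismatch, a 0-5 N spacer cycled across
    wells, and exactly ``n_wells // 2`` wells flagged as sequenced in
    reversed orientation.
    """
    if not (1 <= n_wells <= 96):
        raise InvalidParameterError("n_wells must be in 1..96")
    rng = np.random.default_rng(seed)
    L = len(consensus.sequence)
    anchor_f = _best_primer_window(consensus, 0, L // 3, primer_len, False)
    anchor_r = _best_primer_window(
        consensus, 2 * L // 3, L, primer_len, True
    )
    prime_f = _seq.ct_convert(consensus.sequence[anchor_f[0]:anchor_f[1]])
    prime_r = _seq.ga_convert(
        _seq.revcomp(consensus.sequence[anchor_r[0]:anchor_r[1]])
    )

    min_dist = 2 * max_mismatch + 1
    accepted: list[str] = []
    pairs: list[tuple[str, str]] = []
    attempts = 0
    while len(pairs) < n_wells:
        attempts += 1
        if attempts > 20000:
            raise GenerationError(
                "index generation failed at the requested mismatch tolerance"
            )
        idx_f = _seq.decode(rng.integers(0, 4, size=INDEX_LEN).astype(np.uint8))
        idx_r = _seq.decode(rng.integers(0, 4, size=INDEX_LEN).astype(np.uint8))
        concat = idx_f + idx_r
        if all(_hamming(concat, a) >= min_dist for a in accepted):
            accepted.append(concat)
            pairs.append((idx_f, idx_r))

    wells: dict[str, PrimerPair] = {}
    for i, wid in enumerate(well_ids(n_wells)):
        wells[wid] = PrimerPair(
            well_id=wid,
            index_f=pairs[i][0],
            index_r=pairs[i][1],
            spacer_f=i % (MAX_SPACER + 1),
            spacer_r=(i + 3) % (MAX_SPACER + 1),
            prime_f=prime_f,
            prime_r=prime_r,
            orientation="reversed" if i % 2 == 1 else "forward",
        )
    return PrimerPlate(wells=wells, anchor_f=anchor_f, anchor_r=anchor_r)
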