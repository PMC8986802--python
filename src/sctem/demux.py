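"""Internal dual-index demultiplexing of pooled amplicon read pairs.

Each well of the primer plate is identified by an 8+8 bp index pair
read at the very start of R1 and R2.  Forward wells carry index_f on
R1; reversed wells (half the plate) carry index_r on R1.  Matching is
substitution-only and anchored at position 0; a pair is assigned to the
single well whose two indexes both match within ``max_mismatch``
substitutions, ties between equally close wells are reported as
ambiguous, everything else as unassigned.  Assigned reads then have
index + declared spacer + priming sequence stripped from the 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .reference import INDEX_LEN, PrimerPlate
from .simulate import ReadPair


@dataclass
class DemuxReport:
    assigned: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0
    ambiguous: int = 0
    total: int = 0
    mean_mismatches: dict[str, float] = field(default_factory=dict)
    dropped_short: int = 0

    def conserved(self) -> bool:
        return sum(self.assigned.values()) + self.unassigned \
            + self.ambiguous == self.total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"well_id": w, "assigned_pairs": n,
             "mean_index_mismatches": self.mean_mismatches.get(w, 0.0)}
            for w, n in sorted(self.assigned.items())
        ]
        return pd.DataFrame(
            rows, columns=["well_id", "assigned_pairs",
                           "mean_index_mismatches"])


def _well_expected(plate: PrimerPlate):
    """Per well: the (R1 index, R2 index, R1 trim, R2 trim) contract."""
    out = {}
    for wid, w in plate.wells.items():
        f_trim = INDEX_LEN + w.spacer_f + len(w.prime_f)
        r_trim = INDEX_LEN + w.spacer_r + len(w.prime_r)
        if w.orientation == "forward":
            out[wid] = (w.index_f, w.index_r, f_trim, r_trim)
        else:
            out[wid] = (w.index_r, w.index_f, r_trim, f_trim)
    return out


def _hamming8(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    pairs: Iterable[ReadPair] | Sequence[ReadPair],
    plate: PrimerPlate,
    max_mismatch: int = 1,
) -> tuple[dict[str, list[ReadPair]], DemuxReport]:
    """Assign read pairs to wells and strip index/spacer/primer.

    ``pairs`` is any iterable of :class:`~sctem.simulate.ReadPair`
    (file-based input goes through :func:`sctem.io.read_fastq_pairs`,
    which raises a format error on desynchronized mates).
    Returns per-well trimmed pairs and a conservation-checked report.
    """
    if not (0 <= max_mismatch <= 2):
        raise InvalidParameterError("max_mismatch must be in 0..2")
    expected = _well_expected(plate)
    exact = {(e[0], e[1]): wid for wid, e in expected.items()}

    out: dict[str, list[ReadPair]] = {wid: [] for wid in plate.wells}
    report = DemuxReport(assigned={wid: 0 for wid in plate.wells})
    mm_sum: dict[str, int] = {wid: 0 for wid in plate.wells}

    for pair in pairs:
        report.total += 1
        k1 = pair.seq1[:INDEX_LEN]
        k2 = pair.seq2[:INDEX_LEN]
        wid = exact.get((k1, k2))
        mm = 0
        if wid is None:
            # mismatch-tolerant scan over all wells
            best_wid, best_mm, best_count = None, None, 0
            if max_mismatch > 0:
                for cand, (e1, e2, _, _) in expected.items():
                    d1 = _hamming8(k1, e1)
                    if d1 > max_mismatch:
                        continue
                    d2 = _hamming8(k2, e2)
                    if d2 > max_mismatch:
                        continue
                    d = d1 + d2
                    if best_mm is None or d < best_mm:
                        best_wid, best_mm, best_count = cand, d, 1
                    elif d == best_mm:
                        best_count += 1
            if best_wid is None:
                report.unassigned += 1
                continue
            if best_count > 1:
                report.ambiguous += 1
                continue
            wid, mm = best_wid, best_mm
        _, _, t1, t2 = expected[wid]
        report.assigned[wid] += 1
        mm_sum[wid] += mm
        out[wid].append(ReadPair(
            pair.read_id,
            pair.seq1[t1:], pair.qual1[t1:],
            pair.seq2[t2:], pair.qual2[t2:],
        ))
    report.mean_mismatches = {
        wid: (mm_sum[wid] / n if n else 0.0)
        for wid, n in report.assigned.items()
    }
    assert report.conserved()
    return out, report


def trim_insert_ends(pair_or_read, n5: int = 10, n3: int = 10):
    """Trim n5/n3 bases from the 5'/3' ends of a read or both mates.

    Applied after index/spacer/primer removal to strip residual adapter
    bases.  Reads shorter than ``n5 + n3 + 1`` are dropped (returns
    None); callers count drops.
    """
    if n5 < 0 or n3 < 0:
        raise InvalidParameterError("trim lengths must be >= 0")

    def _trim(seq: str, qual: str):
        if len(seq) < n5 + n3 + 1:
            return None
        end = len(seq) - n3
        return seq[n5:end], qual[n5:end]

    if isinstance(pair_or_read, ReadPair):
        a = _trim(pair_or_read.seq1, pair_or_read.qual1)
        b = _trim(pair_or_read.seq2, pair_or_read.qual2)
        if a is None or b is None:
            return None
        return ReadPair(pair_or_read.read_id, a[0], a[1], b[0], b[1])
    seq, qual = pair_or_read
    return _trim(seq, qual)


def trim_all(pairs: Sequence[ReadPair], n5: int = 10, n3: int = 10
             ) -> tuple[list[ReadPair], int]:
    """Trim every pair; returns (kept pairs, dropped count)."""
    kept, dropped = [], 0
    for p in pairs:
        t = trim_insert_ends(p, n5, n3)
        if t is None:
            dropped += 1
        else:
            kept.append(t)
    return kept, dropped
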