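"""Misincorporation (RT mismatch) profiling at base-modified positions.

Modifications on the Watson–Crick face of a base make reverse transcriptase
misread it, so the mismatch fraction at a position is a proxy for the
modification level.  Fractions across replicates are summarized as the
distribution-free 95% confidence interval of the median built from order
statistics of the binomial(n, 1/2) distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pysam
from scipy import stats

from .references import ReferenceSet, ValidationError
from .end_counting import DEFAULT_MAX_LEN, DEFAULT_MIN_LEN

__all__ = ["MisincRecord", "misinc_fractions", "median_ci"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MisincRecord:
    """Depth and mismatch tally at one reference position."""

    sample_id: str
    replicate: int
    molecule: str
    position: int  # 1-based
    depth: int
    mismatch_count: int

    @property
    def fraction(self) -> Optional[float]:
        """Mismatch fraction; None at zero depth."""
        if self.depth == 0:
            return None
        return self.mismatch_count / self.depth


def _canon(b: str) -> str:
    b = b.upper()
    return "U" if b == "T" else b


def misinc_fractions(
    alignments: Union[str, "pysam.AlignmentFile"],
    refs: ReferenceSet,
    positions: Iterable[tuple[str, int]],
    sample_id: str = "sample",
    replicate: int = 1,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_mapq: int = 0,
    deletions_as_mismatch: bool = True,
    count_insertions: bool = False,
) -> list[MisincRecord]:
    """Tally mismatches at given 1-based (molecule, position) pairs.

    Depth counts aligned read bases (and, when ``deletions_as_mismatch``,
    deletions) covering the position in primary mapped reads passing the
    same length/MAPQ filters as end counting.  Mismatches are read bases
    differing from the reference; deletions count as mismatches by default
    (an RT drop/skip is itself a modification signal); insertions adjacent
    to the position are ignored unless ``count_insertions``.
    """
    targets: dict[str, dict[int, list[int]]] = {}
    for mol, pos in positions:
        if mol not in refs:
            raise ValidationError(f"unknown molecule {mol!r} in positions")
        if not 1 <= pos <= refs.length(mol):
            raise ValidationError(f"position {pos} out of range on {mol!r}")
        targets.setdefault(mol, {})[pos - 1] = [0, 0]  # [depth, mismatches]

    own = False
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True
    try:
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            mol = read.reference_name
            if mol not in targets:
                continue
            alen = read.reference_end - read.reference_start
            if not min_len <= alen <= max_len:
                continue
            wanted = targets[mol]
            span = {p for p in wanted if read.reference_start <= p < read.reference_end}
            if not span:
                continue
            seq = read.query_sequence
            ref_seq = refs[mol]
            for qpos, rpos in read.get_aligned_pairs():
                if rpos is None:
                    if count_insertions:
                        pass  # insertions have no reference anchor; ignored
                    continue
                if rpos not in wanted:
                    continue
                cell = wanted[rpos]
                if qpos is None:  # deletion over the position
                    if deletions_as_mismatch:
                        cell[0] += 1
                        cell[1] += 1
                    continue
                cell[0] += 1
                if _canon(seq[qpos]) != _canon(ref_seq[rpos]):
                    cell[1] += 1
        records = []
        for mol in targets:
            for rpos, (depth, mism) in sorted(targets[mol].items()):
                rec = MisincRecord(
                    sample_id, replicate, mol, rpos + 1, depth, mism
                )
                if depth == 0:
                    logger.warning(
                        "zero depth at %s:%d; mismatch fraction undefined",
                        mol,
                        rpos + 1,
                    )
                records.append(rec)
        return records
    finally:
        if own:
            alignments.close()


def median_ci(
    values, level: float = 0.95, method: str = "order", n_boot: int = 2000, seed: int = 0
) -> tuple[float, float, float]:
    """Median with a confidence interval, default distribution-free.

    The order-statistic interval takes the largest k with
    P[Binomial(n, 1/2) <= k] <= (1 - level)/2 and returns the (k+1)-th and
    (n-k)-th order statistics; its coverage is exact and at least ``level``
    for continuous data.  When n is too small for nominal coverage, the
    full range (min, max) is returned with a warning.  ``method="bootstrap"``
    gives a seeded percentile-bootstrap interval instead.
    """
    v = np.sort(np.asarray(list(values), dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("median_ci of empty input")
    med = float(np.median(v))
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        meds = np.median(rng.choice(v, size=(n_boot, n), replace=True), axis=1)
        alpha = 1 - level
        lo, hi = np.quantile(meds, [alpha / 2, 1 - alpha / 2])
        return med, float(lo), float(hi)
    if method != "order":
        raise ValueError("method must be 'order' or 'bootstrap'")
    alpha2 = (1 - level) / 2
    # largest k (cut count from each tail) with cdf(k-1) <= alpha/2 and k >= 1
    ks = np.arange(0, n // 2 + 1)
    ok = stats.binom.cdf(ks - 1, n, 0.5) <= alpha2 + 1e-15
    k = int(ks[ok].max()) if ok.any() else 0
    if k == 0:
        logger.warning(
            "n=%d too small for %g%% coverage of the median; returning (min, max)",
            n,
            100 * level,
        )
        return med, float(v[0]), float(v[-1])
    return med, float(v[k - 1]), float(v[n - k])
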