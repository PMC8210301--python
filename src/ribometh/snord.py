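"""Box C/D snoRNA (SNORD) expression from RiboMeth-seq libraries.

The libraries are whole-cell small-RNA sequencing, so besides rRNA
fragments they sample the snoRNA guides at intermediate abundance —
a low-coverage RNA-seq usable for RPKM quantification:

    RPKM = reads * 1e9 / (length_nt * total_mapped_reads)

The denominator is all retained mapped reads library-wide (rRNA + SNORD)
by default, switchable to SNORD-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Union

import numpy as np
import pandas as pd
import pysam

from .references import ReferenceSet, ValidationError
from .end_counting import DEFAULT_MAX_LEN, DEFAULT_MIN_LEN

__all__ = ["SnordExpression", "count_snord_reads", "rpkm", "quantify_snords", "expression_summary"]


@dataclass
class SnordExpression:
    """Per-SNORD read counts and RPKM for one (sample, replicate)."""

    sample_id: str
    replicate: int
    frame: pd.DataFrame  # columns: snord, count, length, rpkm


def count_snord_reads(
    alignments: Union[str, "pysam.AlignmentFile"],
    refs: ReferenceSet,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_mapq: int = 0,
) -> dict[str, int]:
    """Tally primary mapped reads per SNORD reference.

    Applies the same aligned-length and MAPQ filters as end counting.
    Every SNORD in ``refs.snords`` appears in the result (zero when no
    reads mapped).  Multi-mapping to paralogs is resolved upstream by the
    aligner's primary-alignment choice; only primary records are counted.
    """
    own = False
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True
    try:
        counts = {name: 0 for name in refs.snords}
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            name = read.reference_name
            if name not in refs:
                raise ValidationError(
                    f"alignment references unknown molecule {name!r}"
                )
            if name not in counts:
                continue
            alen = read.reference_end - read.reference_start
            if min_len <= alen <= max_len:
                counts[name] += 1
        return counts
    finally:
        if own:
            alignments.close()


def rpkm(read_count: float, length_nt: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if length_nt <= 0:
        raise ValueError("length must be > 0")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be > 0")
    return read_count * 1e9 / (length_nt * total_mapped_reads)


def quantify_snords(
    counts: dict[str, int],
    refs: ReferenceSet,
    total_mapped_reads: int,
    sample_id: str = "sample",
    replicate: int = 1,
    denominator: str = "all",
) -> SnordExpression:
    """Build an RPKM table from per-SNORD counts.

    ``denominator`` chooses the total for the RPKM formula: "all" uses the
    library-wide retained read count given, "snord" uses the sum of the
    SNORD counts themselves.
    """
    if denominator == "snord":
        total = sum(counts.values())
    elif denominator == "all":
        total = total_mapped_reads
    else:
        raise ValueError("denominator must be 'all' or 'snord'")
    rows = [
        dict(
            snord=name,
            count=c,
            length=len(refs.snords[name]),
            rpkm=rpkm(c, len(refs.snords[name]), total) if total > 0 else np.nan,
        )
        for name, c in sorted(counts.items())
    ]
    return SnordExpression(sample_id, replicate, pd.DataFrame(rows))


def expression_summary(
    expressions: Iterable[SnordExpression], groups: dict[str, str]
) -> pd.DataFrame:
    """Group means ± SEM of RPKM per SNORD.

    ``groups`` maps sample_id -> group label.  SEM = sd / sqrt(n) with the
    sample (n-1) standard deviation; absent (NaN) when a group has a single
    observation.  Replicates of one sample each count as an observation.
    """
    rows = []
    for e in expressions:
        grp = groups.get(e.sample_id)
        if grp is None:
            raise ValueError(f"sample {e.sample_id!r} has no group label")
        f = e.frame.copy()
        f["group"] = grp
        rows.append(f[["group", "snord", "rpkm"]])
    if not rows:
        raise ValueError("no expression tables given")
    long = pd.concat(rows, ignore_index=True)
    out = (
        long.groupby(["group", "snord"])["rpkm"]
        .agg(
            mean="mean",
            sem=lambda v: np.std(v, ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
            n="size",
        )
        .reset_index()
    )
    return out
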