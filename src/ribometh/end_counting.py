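"""Cleavage-end counting from alignments of size-selected RNA fragments.

Partial alkaline hydrolysis cuts RNA at phosphodiester bonds; a 2'-O-methyl
group on nucleotide i protects the bond 3' of i.  Each sequenced fragment
therefore witnesses two cleavage events: one at the bond just upstream of
its biological 5' end and one at the bond just downstream of its 3' end.

Bond convention (1-based): bond i sits between nucleotides i and i+1, so a
molecule of length L has bonds 1..L-1.  A cleavage at bond i is observed as
a 5' read end at position i+1 or a 3' read end at position i; both are
summed into ``cleavage[i]``.  The score for site i reads the signal at bond
i.  Read ends at the very first/last nucleotide of a molecule correspond to
transcript termini rather than hydrolysis and are tallied separately.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import pysam

from .references import ReferenceSet, ValidationError

__all__ = ["EndCountProfile", "count_read_ends", "load_end_counts", "save_end_counts"]

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 20
DEFAULT_MAX_LEN = 40


@dataclass
class EndCountProfile:
    """Per-bond cleavage-end counts for one (sample, replicate, molecule).

    ``cleavage`` is indexed by bond (0-based array index k = bond k+1) and
    has length L-1.  ``five_prime`` / ``three_prime`` are per-position raw
    end counts (length L, index k = position k+1), kept for diagnostics;
    they are ``None`` on profiles reconstructed from a cleavage-only table.
    Counts become reals after bias correction.
    """

    sample_id: str
    replicate: int
    molecule: str
    cleavage: np.ndarray
    five_prime: Optional[np.ndarray] = None
    three_prime: Optional[np.ndarray] = None
    total_mapped_reads: int = 0
    terminal_ends: int = 0  # read ends at position 1 or L (transcript termini)

    def __post_init__(self) -> None:
        self.cleavage = np.asarray(self.cleavage, dtype=float)
        if np.any(self.cleavage < 0):
            raise ValidationError("negative cleavage counts")
        if self.five_prime is not None and self.three_prime is not None:
            five = np.asarray(self.five_prime)
            three = np.asarray(self.three_prime)
            expect = five[1:] + three[:-1]
            if expect.shape != self.cleavage.shape or not np.allclose(
                expect, self.cleavage
            ):
                raise ValidationError(
                    "cleavage counts inconsistent with 5'/3' end arrays"
                )

    @property
    def length(self) -> int:
        """Molecule length (number of nucleotides)."""
        return len(self.cleavage) + 1

    @classmethod
    def from_end_arrays(
        cls,
        sample_id: str,
        replicate: int,
        molecule: str,
        five_prime: np.ndarray,
        three_prime: np.ndarray,
        total_mapped_reads: int = 0,
    ) -> "EndCountProfile":
        five = np.asarray(five_prime, dtype=float)
        three = np.asarray(three_prime, dtype=float)
        cleavage = five[1:] + three[:-1]
        terminal = int(five[0] + three[-1])
        return cls(
            sample_id=sample_id,
            replicate=replicate,
            molecule=molecule,
            cleavage=cleavage,
            five_prime=five,
            three_prime=three,
            total_mapped_reads=total_mapped_reads,
            terminal_ends=terminal,
        )


def count_read_ends(
    alignments: Union[str, "pysam.AlignmentFile"],
    refs: ReferenceSet,
    sample_id: str = "sample",
    replicate: int = 1,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_mapq: int = 0,
    ends: str = "both",
    molecules: Optional[Iterable[str]] = None,
    return_tally: bool = False,
):
    """Count fragment ends per reference position from a SAM/BAM stream.

    Retains primary, mapped reads with aligned reference length within
    [min_len, max_len] and MAPQ >= min_mapq.  Soft-clipped bases are outside
    the aligned span.  Strand-aware: for a reverse-strand read the
    biological 5' end is the rightmost aligned reference position.

    ``ends`` selects which end types enter the cleavage profile: "both"
    (default), "five" or "three" — a sensitivity-analysis switch.

    Returns a list of :class:`EndCountProfile`, one per molecule that reads
    were mapped to (all molecules in ``molecules`` if given).  With
    ``return_tally=True`` also returns a Counter of filtering decisions.
    """
    if ends not in ("both", "five", "three"):
        raise ValueError(f"ends must be both/five/three, got {ends!r}")
    own = False
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True
    try:
        five: dict[str, np.ndarray] = {}
        three: dict[str, np.ndarray] = {}
        tally: Counter = Counter()
        names = list(molecules) if molecules is not None else []
        for name in names:
            L = refs.length(name)
            five[name] = np.zeros(L, dtype=np.int64)
            three[name] = np.zeros(L, dtype=np.int64)
        total = 0
        for read in alignments:
            if read.is_unmapped:
                tally["unmapped"] += 1
                continue
            if read.is_secondary or read.is_supplementary:
                tally["secondary_or_supplementary"] += 1
                continue
            if read.mapping_quality < min_mapq:
                tally["mapq-filtered"] += 1
                continue
            ref_name = read.reference_name
            if ref_name not in refs:
                raise ValidationError(
                    f"alignment references unknown molecule {ref_name!r}"
                )
            left = read.reference_start  # 0-based leftmost aligned position
            right = read.reference_end - 1  # 0-based rightmost
            alen = right - left + 1
            if not min_len <= alen <= max_len:
                tally["length-filtered"] += 1
                continue
            if ref_name not in five:
                L = refs.length(ref_name)
                five[ref_name] = np.zeros(L, dtype=np.int64)
                three[ref_name] = np.zeros(L, dtype=np.int64)
            if read.is_reverse:
                p5, p3 = right, left
            else:
                p5, p3 = left, right
            five[ref_name][p5] += 1
            three[ref_name][p3] += 1
            tally["retained"] += 1
            total += 1
        profiles = []
        for name in sorted(five):
            f = five[name].astype(float)
            t = three[name].astype(float)
            if ends == "five":
                cleav_f, cleav_t = f, np.zeros_like(t)
            elif ends == "three":
                cleav_f, cleav_t = np.zeros_like(f), t
            else:
                cleav_f, cleav_t = f, t
            prof = EndCountProfile(
                sample_id=sample_id,
                replicate=replicate,
                molecule=name,
                cleavage=cleav_f[1:] + cleav_t[:-1],
                five_prime=f if ends == "both" else None,
                three_prime=t if ends == "both" else None,
                total_mapped_reads=total,
                terminal_ends=int(f[0] + t[-1]),
            )
            profiles.append(prof)
        if tally["unmapped"] or tally["secondary_or_supplementary"]:
            logger.info("skipped alignments: %s", dict(tally))
        if return_tally:
            return profiles, tally
        return profiles
    finally:
        if own:
            alignments.close()


def save_end_counts(profiles: Iterable[EndCountProfile], tsv_path) -> None:
    """Write nonzero cleavage-bond counts as a sparse TSV."""
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("sample\treplicate\tmolecule\tposition\tcount\ttotal_reads\tlength\n")
        for p in profiles:
            nz = np.nonzero(p.cleavage)[0]
            if len(nz) == 0:
                # keep an explicit row so length/total survive the round trip
                fh.write(
                    f"{p.sample_id}\t{p.replicate}\t{p.molecule}\t1\t0"
                    f"\t{p.total_mapped_reads}\t{p.length}\n"
                )
                continue
            for k in nz:
                c = p.cleavage[k]
                c_str = f"{int(c)}" if float(c).is_integer() else f"{c:.6g}"
                fh.write(
                    f"{p.sample_id}\t{p.replicate}\t{p.molecule}\t{k + 1}\t{c_str}"
                    f"\t{p.total_mapped_reads}\t{p.length}\n"
                )


def load_end_counts(tsv_path, refs: Optional[ReferenceSet] = None) -> list[EndCountProfile]:
    """Load cleavage-bond counts from TSV; unlisted bonds default to 0.

    Molecule length comes from ``refs`` when provided, else from the
    ``length`` column, else from the largest bond index seen.
    """
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    required = {"sample", "replicate", "molecule", "position", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"end-count table missing columns {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ValidationError("negative counts in end-count table")
    profiles = []
    for (sample, rep, mol), grp in df.groupby(
        ["sample", "replicate", "molecule"], sort=True
    ):
        if refs is not None and mol in refs:
            L = refs.length(mol)
        elif "length" in grp.columns and grp["length"].notna().any():
            L = int(grp["length"].iloc[0])
        else:
            L = int(grp["position"].max()) + 1
        cleavage = np.zeros(L - 1, dtype=float)
        pos = grp["position"].to_numpy(dtype=int)
        if (pos < 1).any() or (pos > L - 1).any():
            raise ValidationError(
                f"bond index out of range 1..{L - 1} for molecule {mol!r}"
            )
        np.add.at(cleavage, pos - 1, grp["count"].to_numpy(dtype=float))
        total = int(grp["total_reads"].iloc[0]) if "total_reads" in grp.columns else 0
        profiles.append(
            EndCountProfile(
                sample_id=str(sample),
                replicate=int(rep),
                molecule=str(mol),
                cleavage=cleavage,
                total_mapped_reads=total,
            )
        )
    return profiles
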