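"""RMS scoring: the "fraction methylated" (score C) estimator.

A 2'-O-methyl group at nucleotide i protects bond i from alkaline
hydrolysis, so the cleavage-end count n[i] at a fully methylated site drops
to zero while the flanking bonds keep cleaving normally.  Score C compares
n[i] with a weighted average of its flanking bonds:

    left  = sum_j w_j * n[i-j] / sum_j w_j      (j = 1..l, within the array)
    right = sum_j w_j * n[i+j] / sum_j w_j
    mu    = (left + right) / 2
    score = clip(1 - n[i] / mu, 0, 1)           (0 when mu == 0)

with half-width l = 6 and linearly decaying weights w_j = l - j + 1 by
default.  Under the linear-protection model (a fraction f of molecules
fully protect the bond) the expected score equals f, the methylated
fraction.  mu doubles as a local-coverage measure: sites with mu below a
minimum coverage are flagged invalid instead of reporting a noisy score.

An optional end-nucleotide bias correction compensates ligation/barcode
preferences: cleavage counts at bonds whose 5' nucleotide is b are scaled
by a per-base factor estimated from non-site bonds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .end_counting import EndCountProfile
from .references import ReferenceSet, SiteAnnotation, ValidationError

__all__ = [
    "RMSProfile",
    "BiasCorrection",
    "score_c",
    "profile_scores",
    "estimate_bias",
    "apply_bias",
    "default_weights",
]

logger = logging.getLogger(__name__)

DEFAULT_HALF_WIDTH = 6
DEFAULT_MIN_COVERAGE = 10.0


def default_weights(half_width: int) -> np.ndarray:
    """Linear-decay weights w_j = l - j + 1 for j = 1..l."""
    return np.arange(half_width, 0, -1, dtype=float)


def score_c(
    counts: np.ndarray,
    bond: int,
    half_width: int = DEFAULT_HALF_WIDTH,
    weights: Optional[Sequence[float]] = None,
) -> tuple[float, float]:
    """Score one bond; returns ``(score, local_coverage)``.

    ``counts`` is the cleavage array (index k = bond k+1); ``bond`` is the
    1-based bond index.  Windows truncate at array edges but at least one
    neighbor must exist on each side.
    """
    counts = np.asarray(counts, dtype=float)
    n_bonds = len(counts)
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    if not 1 <= bond <= n_bonds:
        raise IndexError(f"bond {bond} out of range 1..{n_bonds}")
    w = default_weights(half_width) if weights is None else np.asarray(weights, float)
    if len(w) != half_width or np.any(w <= 0):
        raise ValueError("weights must have length half_width and be positive")
    i = bond - 1
    n_left = min(half_width, i)
    n_right = min(half_width, n_bonds - 1 - i)
    if n_left < 1 or n_right < 1:
        raise IndexError(f"bond {bond} has an empty flank (array edge)")
    wl = w[:n_left]
    wr = w[:n_right]
    left = float(np.dot(wl, counts[i - 1 :: -1][:n_left]) / wl.sum())
    right = float(np.dot(wr, counts[i + 1 : i + 1 + n_right]) / wr.sum())
    mu = 0.5 * (left + right)
    if mu == 0.0:
        return 0.0, 0.0
    score = float(np.clip(1.0 - counts[i] / mu, 0.0, 1.0))
    return score, mu


@dataclass
class RMSProfile:
    """Per-site scores for one (sample, replicate); tabular access via ``frame``."""

    sample_id: str
    replicate: int
    frame: pd.DataFrame  # columns: site_id, molecule, position, score, coverage, valid, error

    def valid_scores(self) -> pd.DataFrame:
        return self.frame[self.frame["valid"]]


def profile_scores(
    profile: EndCountProfile,
    sites: Union[Iterable[SiteAnnotation], str] = "ALL",
    half_width: int = DEFAULT_HALF_WIDTH,
    weights: Optional[Sequence[float]] = None,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> RMSProfile:
    """Apply score C at every requested site of one end-count profile.

    ``sites`` is a list of annotations (those on other molecules yield
    per-site error records, not a crash) or ``"ALL"`` to score every bond
    of the profile's molecule that has a non-empty flank on both sides.
    Sites with local coverage below ``min_coverage`` are flagged invalid.
    """
    rows = []
    if isinstance(sites, str):
        if sites != "ALL":
            raise ValueError("sites must be a list of SiteAnnotation or 'ALL'")
        targets = [
            (f"{profile.molecule}:{b}", profile.molecule, b)
            for b in range(1, profile.length)
        ]
    else:
        targets = [(s.site_id, s.molecule, s.position) for s in sites]
    for site_id, molecule, position in targets:
        if molecule != profile.molecule:
            rows.append(
                dict(
                    site_id=site_id,
                    molecule=molecule,
                    position=position,
                    score=np.nan,
                    coverage=np.nan,
                    valid=False,
                    error=f"molecule {molecule!r} not in this profile",
                )
            )
            continue
        try:
            score, cov = score_c(profile.cleavage, position, half_width, weights)
        except IndexError as exc:
            rows.append(
                dict(
                    site_id=site_id,
                    molecule=molecule,
                    position=position,
                    score=np.nan,
                    coverage=np.nan,
                    valid=False,
                    error=str(exc),
                )
            )
            continue
        rows.append(
            dict(
                site_id=site_id,
                molecule=molecule,
                position=position,
                score=score,
                coverage=cov,
                valid=bool(cov >= min_coverage),
                error="",
            )
        )
    frame = pd.DataFrame(
        rows,
        columns=["site_id", "molecule", "position", "score", "coverage", "valid", "error"],
    )
    return RMSProfile(profile.sample_id, profile.replicate, frame)


@dataclass
class BiasCorrection:
    """Multiplicative per-nucleotide cleavage-count corrections.

    Keyed by the identity of the nucleotide 5' of the bond; factors are
    positive and normalized to mean 1.
    """

    factors: dict[str, float]

    def __post_init__(self) -> None:
        for b, f in self.factors.items():
            if f <= 0:
                raise ValidationError(f"bias factor for {b!r} must be > 0")
        mean = float(np.mean(list(self.factors.values())))
        if abs(mean - 1.0) > 1e-9:
            self.factors = {b: f / mean for b, f in self.factors.items()}


_BASES = ("A", "C", "G", "U")


def _canon_base(b: str) -> str:
    b = b.upper()
    return "U" if b == "T" else b


def estimate_bias(
    profile: EndCountProfile,
    refs: ReferenceSet,
    exclude_sites: Iterable[SiteAnnotation] = (),
    min_bonds_per_class: int = 50,
) -> BiasCorrection:
    """Estimate per-5'-nucleotide correction factors from non-site bonds.

    factor(b) = grand mean of cleavage counts at non-site bonds
                / mean at non-site bonds whose 5' nucleotide is b,
    normalized to mean 1.  A nucleotide class with fewer than
    ``min_bonds_per_class`` usable bonds falls back to factor 1 with a
    warning.
    """
    seq = refs[profile.molecule]
    counts = profile.cleavage
    excluded = {
        s.position for s in exclude_sites if s.molecule == profile.molecule
    }
    bonds = np.array(
        [b for b in range(1, profile.length) if b not in excluded], dtype=int
    )
    base_of_bond = np.array([_canon_base(seq[b - 1]) for b in bonds])
    vals = counts[bonds - 1]
    grand = float(vals.mean()) if len(vals) else 0.0
    raw: dict[str, float] = {}
    for b in _BASES:
        mask = base_of_bond == b
        if mask.sum() < min_bonds_per_class or grand == 0.0:
            logger.warning(
                "bias estimation: only %d usable bonds for nucleotide %s; factor set to 1",
                int(mask.sum()),
                b,
            )
            raw[b] = 1.0
            continue
        class_mean = float(vals[mask].mean())
        raw[b] = grand / class_mean if class_mean > 0 else 1.0
    return BiasCorrection(factors=raw)


def apply_bias(
    profile: EndCountProfile, correction: BiasCorrection, refs: ReferenceSet
) -> EndCountProfile:
    """Scale cleavage counts by the factor of each bond's 5' nucleotide.

    Counts are kept as (non-negative) reals from here on; the per-position
    diagnostic end arrays are dropped as they no longer decompose the
    corrected signal.
    """
    seq = refs[profile.molecule]
    factors = np.array(
        [correction.factors.get(_canon_base(seq[b - 1]), 1.0) for b in range(1, profile.length)]
    )
    return EndCountProfile(
        sample_id=profile.sample_id,
        replicate=profile.replicate,
        molecule=profile.molecule,
        cleavage=profile.cleavage * factors,
        total_mapped_reads=profile.total_mapped_reads,
        terminal_ends=profile.terminal_ends,
    )


def scores_to_frame(profiles: Iterable[RMSProfile]) -> pd.DataFrame:
    """Concatenate per-replicate score tables into one long frame."""
    frames = []
    for p in profiles:
        f = p.frame.copy()
        f.insert(0, "sample", p.sample_id)
        f.insert(1, "replicate", p.replicate)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
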