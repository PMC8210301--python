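"""Ground-truth simulator for RiboMeth-seq style libraries.

Generative model of partial alkaline hydrolysis with methylation-dependent
protection: a fraction f of molecules carry the 2'-O-methyl group at a site
and fully protect the bond 3' of it, so the expected cleavage rate at that
bond scales by (1 - f).  Two generators are provided:

* :func:`simulate_end_counts` — per-bond independent Poisson counts,
  cleavage[i] ~ Poisson(lambda * (1 - f_i)), optionally gamma-mixed for
  replicate overdispersion and scaled by per-5'-nucleotide ligation bias.
  Fast; drives scoring and statistics tests.
* :func:`simulate_reads` — the stricter fragment-level model: each molecule
  copy is cut independently at every bond with probability p * (1 - f_i),
  fragments falling in the size-selection window (20-40 nt by default) are
  emitted as perfectly aligned SAM records, with optional targeted
  misincorporation and SNORD reads at chosen abundance weights.  Its truth
  tallies validate end counting exactly.

:func:`simulate_cohort` layers the study design on top: a control group at
the base methylation fractions and case groups with per-site effects, each
sample in replicate, plus a Ki-67-like proliferation index generated as a
stated monotone function of the sample's summed true methylation change so
correlation analyses have a known sign.

All randomness flows from explicit seeds; the same seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .references import ReferenceSet, SampleMeta, SiteAnnotation
from .end_counting import DEFAULT_MAX_LEN, DEFAULT_MIN_LEN, EndCountProfile

__all__ = [
    "SimTruth",
    "simulate_reference",
    "simulate_end_counts",
    "simulate_reads",
    "simulate_cohort",
]

_RNA = np.array(list("ACGU"))


@dataclass
class SimTruth:
    """True parameters behind a simulated dataset.

    ``f`` maps site_id -> methylated fraction in the control condition;
    ``group_effects`` maps group -> {site_id -> additive delta on f} (the
    control group is any group without an entry).  ``lam`` is the mean
    cleavage-event count per unprotected bond.  ``bias`` optionally scales
    cleavage at bonds by the identity of the bond's 5' nucleotide;
    ``overdispersion_cv`` > 0 gamma-mixes the Poisson rate per bond
    (coefficient of variation of the mixing distribution).
    """

    sites: list[SiteAnnotation]
    f: dict[str, float]
    lam: float = 500.0
    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    snord_weights: dict[str, float] = field(default_factory=dict)
    misinc_rates: dict[tuple[str, int], float] = field(default_factory=dict)
    bias: Optional[dict[str, float]] = None
    overdispersion_cv: float = 0.0
    frag_min: int = DEFAULT_MIN_LEN
    frag_max: int = DEFAULT_MAX_LEN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        for sid, fv in self.f.items():
            if not 0.0 <= fv <= 1.0:
                raise ValueError(f"f[{sid}] = {fv} outside [0, 1]")
        for grp, eff in self.group_effects.items():
            for sid, d in eff.items():
                tot = self.f.get(sid, 0.0) + d
                if not 0.0 <= tot <= 1.0:
                    raise ValueError(
                        f"f + delta = {tot} outside [0, 1] at {sid} in group {grp}"
                    )

    def f_for_group(self, group: Optional[str], scale: float = 1.0) -> dict[str, float]:
        """Per-site methylated fraction with the group effect applied."""
        eff = self.group_effects.get(group, {}) if group else {}
        return {
            sid: float(np.clip(fv + scale * eff.get(sid, 0.0), 0.0, 1.0))
            for sid, fv in self.f.items()
        }


def _canon(b: str) -> str:
    b = b.upper()
    return "U" if b == "T" else b


def simulate_reference(
    length: int,
    n_sites: int,
    seed: int,
    molecule: str = "SIM",
    half_width: int = 6,
) -> tuple[ReferenceSet, list[SiteAnnotation]]:
    """Random reference with methylation sites spaced so scoring windows
    never overlap (pairwise distance >= 2 * half_width + 1) and kept
    ``half_width`` bonds away from the molecule ends."""
    if length < 100:
        raise ValueError("length must be >= 100")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(_RNA, size=length))
    refs = ReferenceSet(molecules={molecule: seq})
    if n_sites == 0:
        return refs, []
    min_gap = 2 * half_width + 1
    lo, hi = half_width + 1, length - half_width - 1
    slack = (hi - lo) - (n_sites - 1) * min_gap
    if slack < 0:
        raise ValueError(
            f"cannot place {n_sites} sites {min_gap} apart on {length} nt"
        )
    offsets = np.sort(rng.integers(0, slack + 1, size=n_sites))
    positions = lo + np.arange(n_sites) * min_gap + offsets
    sites = [
        SiteAnnotation(
            site_id=f"{molecule}-{_canon(seq[p - 1])}{p}",
            molecule=molecule,
            position=int(p),
            base=seq[p - 1],
        )
        for p in positions
    ]
    return refs, sites


def _bond_fractions(refs: ReferenceSet, molecule: str, f_by_site: dict[str, float],
                    sites: Sequence[SiteAnnotation]) -> np.ndarray:
    L = refs.length(molecule)
    f = np.zeros(L - 1)
    for s in sites:
        if s.molecule == molecule and s.site_id in f_by_site:
            f[s.position - 1] = f_by_site[s.site_id]
    return f


def _bias_per_bond(refs: ReferenceSet, molecule: str, bias: Optional[dict[str, float]]) -> np.ndarray:
    L = refs.length(molecule)
    if not bias:
        return np.ones(L - 1)
    seq = refs[molecule]
    return np.array([bias.get(_canon(seq[k]), 1.0) for k in range(L - 1)])


def simulate_end_counts(
    refs: ReferenceSet,
    truth: SimTruth,
    sample_id: str = "sim",
    replicate: int = 1,
    group: Optional[str] = None,
    effect_scale: float = 1.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> list[EndCountProfile]:
    """Per-bond Poisson cleavage counts for every non-SNORD molecule."""
    if rng is None:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
    f_by_site = truth.f_for_group(group, effect_scale)
    profiles = []
    total = 0
    for molecule in refs.molecules:
        if molecule in refs.snords:
            continue
        f = _bond_fractions(refs, molecule, f_by_site, truth.sites)
        lam = truth.lam * (1.0 - f) * _bias_per_bond(refs, molecule, truth.bias)
        if truth.overdispersion_cv > 0:
            cv2 = truth.overdispersion_cv**2
            lam = lam * rng.gamma(shape=1.0 / cv2, scale=cv2, size=lam.shape)
        cleavage = rng.poisson(lam).astype(float)
        L = refs.length(molecule)
        five = np.concatenate([[0.0], cleavage])  # attribute each event to a 5' end
        three = np.zeros(L)
        profiles.append(
            EndCountProfile(
                sample_id=sample_id,
                replicate=replicate,
                molecule=molecule,
                cleavage=cleavage,
                five_prime=five,
                three_prime=three,
            )
        )
        total += int(cleavage.sum())
    for p in profiles:
        p.total_mapped_reads = total
    return profiles


def simulate_reads(
    refs: ReferenceSet,
    truth: SimTruth,
    n_fragments: int,
    sam_path,
    group: Optional[str] = None,
    n_snord_reads: int = 0,
    frac_reverse: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    cut_prob: Optional[float] = None,
) -> dict:
    """Fragment-level simulation emitting a SAM file plus truth tallies.

    Each molecule copy is cut at bond k with probability
    ``cut_prob * (1 - f_k)`` (default cut_prob gives a mean fragment length
    of about the middle of the size window); fragments whose length falls
    in [frag_min, frag_max] are written as perfectly aligned reads until
    ``n_fragments`` have been emitted per rRNA molecule set.  Targeted
    misincorporation substitutes a random non-reference base at annotated
    positions with the stated rate.  SNORD reads are drawn by abundance
    weight with uniform placement.

    Returns tallies: per-molecule five/three end arrays (recorded with the
    same strand convention end counting uses), per-target-position depth
    and mismatch counts, per-SNORD read counts, and the total read count.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
    window = (truth.frag_min, truth.frag_max)
    if window[0] < 1 or window[0] > window[1]:
        raise ValueError("infeasible fragment-length window")
    p_cut = cut_prob if cut_prob is not None else 2.0 / (window[0] + window[1])
    f_by_site = truth.f_for_group(group)

    rrna = [m for m in refs.molecules if m not in refs.snords]
    for m in rrna:
        if window[0] > refs.length(m):
            raise ValueError(f"fragment window exceeds molecule {m!r} length")
    five = {m: np.zeros(refs.length(m), dtype=np.int64) for m in refs.molecules}
    three = {m: np.zeros(refs.length(m), dtype=np.int64) for m in refs.molecules}
    mis_truth = {key: [0, 0] for key in truth.misinc_rates}  # [depth, mismatches]
    snord_counts = {s: 0 for s in refs.snords}
    records: list[tuple] = []  # (name, flag, molecule, start0, seq)

    def emit(molecule: str, start: int, end: int) -> None:
        """Register one fragment [start, end) (0-based) and its read."""
        idx = len(records)
        reverse = frac_reverse > 0 and rng.random() < frac_reverse
        if reverse:
            five[molecule][end - 1] += 1
            three[molecule][start] += 1
        else:
            five[molecule][start] += 1
            three[molecule][end - 1] += 1
        seq = list(refs[molecule][start:end])
        for (mol, pos), rate in truth.misinc_rates.items():
            if mol != molecule or not start < pos <= end:
                continue
            k = pos - 1 - start
            mis_truth[(mol, pos)][0] += 1
            if rng.random() < rate:
                ref_base = seq[k].upper()
                choices = [b for b in "ACGU" if b != _canon(ref_base)]
                seq[k] = choices[rng.integers(0, len(choices))]
                mis_truth[(mol, pos)][1] += 1
        flag = 16 if reverse else 0
        records.append((f"frag{idx}", flag, molecule, start, "".join(seq)))

    for molecule in rrna:
        L = refs.length(molecule)
        f = _bond_fractions(refs, molecule, f_by_site, truth.sites)
        p = p_cut * (1.0 - f)
        emitted = 0
        batch = max(4, int(math.ceil(n_fragments / max(1.0, L * p_cut * 0.2))))
        guard = 0
        while emitted < n_fragments:
            guard += 1
            if guard > 10_000:
                raise RuntimeError("fragment acceptance too low; check window")
            cuts = rng.random((batch, L - 1)) < p
            for row in cuts:
                bounds = np.concatenate([[0], np.nonzero(row)[0] + 1, [L]])
                lens = np.diff(bounds)
                for j in np.nonzero((lens >= window[0]) & (lens <= window[1]))[0]:
                    if emitted >= n_fragments:
                        break
                    emit(molecule, int(bounds[j]), int(bounds[j + 1]))
                    emitted += 1
                if emitted >= n_fragments:
                    break

    if n_snord_reads and refs.snords:
        names = sorted(truth.snord_weights or {s: 1.0 for s in refs.snords})
        w = np.array([max(0.0, (truth.snord_weights or {}).get(s, 1.0)) for s in names])
        if w.sum() <= 0:
            raise ValueError("SNORD weights sum to zero")
        w = w / w.sum()
        picks = rng.choice(len(names), size=n_snord_reads, p=w)
        for i in picks:
            name = names[i]
            Ls = refs.length(name)
            fl = int(rng.integers(window[0], min(window[1], Ls) + 1))
            start = int(rng.integers(0, Ls - fl + 1))
            emit(name, start, start + fl)
            snord_counts[name] += 1

    with open(sam_path, "w", encoding="utf-8") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for m in refs.molecules:
            fh.write(f"@SQ\tSN:{m}\tLN:{refs.length(m)}\n")
        for name, flag, molecule, start, seq in records:
            dna = seq.upper().replace("U", "T")
            fh.write(
                f"{name}\t{flag}\t{molecule}\t{start + 1}\t60\t{len(seq)}M"
                f"\t*\t0\t0\t{dna}\t*\n"
            )

    return dict(
        five_prime=five,
        three_prime=three,
        misincorporation={k: tuple(v) for k, v in mis_truth.items()},
        snord_counts=snord_counts,
        n_reads=len(records),
    )


def simulate_cohort(
    refs: ReferenceSet,
    truth: SimTruth,
    groups: dict[str, int],
    seed: int,
    n_replicates: int = 3,
    severity_range: tuple[float, float] = (0.4, 1.6),
    ki67_base: float = 20.0,
    ki67_slope: float = 15.0,
    ki67_noise_sd: float = 5.0,
):
    """Simulate a full study: control + case groups, replicates, Ki-67LI.

    ``groups`` maps group label -> number of samples; a group absent from
    ``truth.group_effects`` is a control (zero effect).  Case samples get a
    per-sample severity drawn uniformly from ``severity_range`` (mean 1)
    that scales every site effect, modelling inter-tumor heterogeneity.

    The Ki-67 labeling index is generated as
    ``clip(ki67_base + ki67_slope * severity * mean|effect| * 10 + noise, 0, 100)``
    — monotone increasing in the sample's summed true methylation change, so
    a positive Spearman correlation between summed |ΔRMS| and Ki-67LI is the
    planted signal.  Controls get severity 0.

    Returns (profiles, samples, truth_table) where ``profiles`` is a flat
    list of :class:`EndCountProfile` (one per sample x replicate x
    molecule), ``samples`` a list of :class:`SampleMeta`, and
    ``truth_table`` rows of (sample, group, site_id, f_true, delta_true).
    """
    rng = np.random.default_rng(seed)
    profiles: list[EndCountProfile] = []
    samples: list[SampleMeta] = []
    truth_rows: list[dict] = []
    for group in sorted(groups):
        n_samples = groups[group]
        eff = truth.group_effects.get(group, {})
        for k in range(1, n_samples + 1):
            sample_id = f"{group}{k}"
            if eff:
                severity = float(rng.uniform(*severity_range))
            else:
                severity = 0.0
            mean_abs = (
                float(np.mean([abs(d) for d in eff.values()])) if eff else 0.0
            )
            ki67 = float(
                np.clip(
                    ki67_base
                    + ki67_slope * severity * mean_abs * 10.0
                    + rng.normal(0.0, ki67_noise_sd),
                    0.0,
                    100.0,
                )
            )
            f_applied = truth.f_for_group(group if eff else None, severity)
            for rep in range(1, n_replicates + 1):
                profiles.extend(
                    simulate_end_counts(
                        refs,
                        truth,
                        sample_id=sample_id,
                        replicate=rep,
                        group=group if eff else None,
                        effect_scale=severity,
                        rng=rng,
                    )
                )
                samples.append(
                    SampleMeta(
                        sample_id=sample_id, group=group, replicate=rep, ki67li=ki67
                    )
                )
            for sid, fv in f_applied.items():
                truth_rows.append(
                    dict(
                        sample=sample_id,
                        group=group,
                        site_id=sid,
                        f_true=fv,
                        delta_true=fv - truth.f[sid],
                    )
                )
    return profiles, samples, pd.DataFrame(truth_rows)
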