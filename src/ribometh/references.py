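"""References, methylation-site annotations and sample metadata.

RiboMeth-seq libraries are mapped against a small set of reference molecules:
the mature rRNAs (SSU = 18S, LSU = 28S/5.8S) and the box C/D snoRNA (SNORD)
sequences present in the same whole-cell libraries.  Methylation sites are
annotated with 1-based positions on those molecules, matching the field's
site names (SSU-C1440 means the cytidine at position 1440 of the SSU rRNA).

RNA (U) and DNA (T) references are both accepted; base comparisons are
alphabet-agnostic throughout.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ReferenceSet",
    "SiteAnnotation",
    "SampleMeta",
    "FormatError",
    "ValidationError",
    "read_reference",
    "write_reference",
    "read_sites",
    "write_sites",
    "read_samples",
    "write_samples",
]

_ALLOWED = set("ACGTUN")


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


def _canon(base: str) -> str:
    """Uppercase and map T to U so RNA/DNA alphabets compare equal."""
    b = base.upper()
    return "U" if b == "T" else b


@dataclass
class ReferenceSet:
    """Named reference molecules plus SNORD guide sequences.

    ``molecules`` holds every sequence reads are mapped against (rRNA and
    SNORDs alike); ``snords`` names the subset that are guide RNAs, used by
    SNORD quantification.
    """

    molecules: dict[str, str]
    snords: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.molecules.items():
            if not seq:
                raise ValidationError(f"empty sequence for record {name!r}")
            bad = set(seq.upper()) - _ALLOWED
            if bad:
                raise FormatError(
                    f"record {name!r} contains illegal characters {sorted(bad)}"
                )
        for name, seq in self.snords.items():
            if name not in self.molecules:
                self.molecules[name] = seq

    def length(self, molecule: str) -> int:
        return len(self[molecule])

    def base_at(self, molecule: str, position: int) -> str:
        """Canonical (RNA-alphabet) base at a 1-based position."""
        seq = self[molecule]
        if not 1 <= position <= len(seq):
            raise ValidationError(
                f"position {position} out of range 1..{len(seq)} on {molecule!r}"
            )
        return _canon(seq[position - 1])

    def __getitem__(self, molecule: str) -> str:
        try:
            return self.molecules[molecule]
        except KeyError:
            raise KeyError(f"unknown reference molecule {molecule!r}") from None

    def __contains__(self, molecule: str) -> bool:
        return molecule in self.molecules


@dataclass(frozen=True)
class SiteAnnotation:
    """One annotated 2'-O-methylation site (1-based, closed coordinates)."""

    site_id: str
    molecule: str
    position: int
    base: str
    guide: Optional[str] = None
    host_gene: Optional[str] = None

    def validate(self, refs: ReferenceSet) -> None:
        ref_base = refs.base_at(self.molecule, self.position)
        if _canon(self.base) != ref_base:
            raise ValidationError(
                f"site {self.site_id}: annotated base {self.base!r} does not match "
                f"reference base {ref_base!r} at {self.molecule}:{self.position}"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Per-library metadata: group label, replicate, optional Ki-67LI and Cq."""

    sample_id: str
    group: str
    replicate: int
    ki67li: Optional[float] = None
    cq_values: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id}: replicate index must be >= 1"
            )
        if self.ki67li is not None and not 0.0 <= self.ki67li <= 100.0:
            raise ValidationError(
                f"sample {self.sample_id}: ki67li {self.ki67li} outside [0, 100]"
            )


def read_reference(fasta_path, snord_names: Iterable[str] = ()) -> ReferenceSet:
    """Read a FASTA of reference molecules into a :class:`ReferenceSet`.

    Records whose names appear in ``snord_names`` (or start with ``SNORD``)
    are additionally registered as guide RNAs.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {fasta_path}")
    molecules: dict[str, str] = {}
    for rec in records:
        if rec.id in molecules:
            raise FormatError(f"duplicate record name {rec.id!r}")
        seq = str(rec.seq)
        bad = set(seq.upper()) - _ALLOWED
        if bad:
            raise FormatError(
                f"record {rec.id!r} contains illegal characters {sorted(bad)}"
            )
        molecules[rec.id] = seq
    wanted = set(snord_names)
    snords = {
        n: s for n, s in molecules.items() if n in wanted or n.startswith("SNORD")
    }
    return ReferenceSet(molecules=molecules, snords=snords)


def write_reference(refs: ReferenceSet, fasta_path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in refs.molecules.items()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def _tsv_rows(path) -> tuple[list[str], list[dict[str, str]]]:
    """Read a tab-separated file with a header; '#'-prefixed lines ignored."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"empty table: {path}")
    reader = csv.DictReader(io.StringIO("".join(lines)), delimiter="\t")
    return list(reader.fieldnames or []), list(reader)


def read_sites(tsv_path, refs: ReferenceSet) -> list[SiteAnnotation]:
    """Read and validate a site-annotation table.

    Columns: site_id, molecule, position, base, guide, host_gene.  Every
    site's base is checked against the reference; the returned list is
    sorted by (molecule, position).
    """
    header, rows = _tsv_rows(tsv_path)
    required = {"site_id", "molecule", "position", "base"}
    missing = required - set(header)
    if missing:
        raise FormatError(f"site table missing columns {sorted(missing)}")
    sites: list[SiteAnnotation] = []
    seen_ids: set[str] = set()
    for row in rows:
        site = SiteAnnotation(
            site_id=row["site_id"],
            molecule=row["molecule"],
            position=int(row["position"]),
            base=row["base"],
            guide=row.get("guide") or None,
            host_gene=row.get("host_gene") or None,
        )
        if site.site_id in seen_ids:
            raise ValidationError(f"duplicate site id {site.site_id!r}")
        seen_ids.add(site.site_id)
        site.validate(refs)
        sites.append(site)
    sites.sort(key=lambda s: (s.molecule, s.position))
    return sites


def write_sites(sites: Iterable[SiteAnnotation], tsv_path) -> None:
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("site_id\tmolecule\tposition\tbase\tguide\thost_gene\n")
        for s in sites:
            fh.write(
                f"{s.site_id}\t{s.molecule}\t{s.position}\t{s.base}"
                f"\t{s.guide or ''}\t{s.host_gene or ''}\n"
            )


def read_samples(tsv_path) -> list[SampleMeta]:
    """Read sample metadata: sample_id, group, replicate [, ki67li, cq_*].

    Cq values come from any column named ``cq_<assay>`` (e.g. ``cq_U6``);
    empty cells mean "absent".
    """
    header, rows = _tsv_rows(tsv_path)
    required = {"sample_id", "group", "replicate"}
    missing = required - set(header)
    if missing:
        raise FormatError(f"sample table missing columns {sorted(missing)}")
    cq_cols = [c for c in header if c.startswith("cq_")]
    samples: list[SampleMeta] = []
    seen: set[tuple[str, int]] = set()
    for row in rows:
        rep = int(row["replicate"])
        key = (row["sample_id"], rep)
        if key in seen:
            raise ValidationError(f"duplicate (sample_id, replicate) pair {key}")
        seen.add(key)
        ki67 = row.get("ki67li")
        cq = {
            c[3:]: float(row[c]) for c in cq_cols if row.get(c) not in (None, "")
        }
        samples.append(
            SampleMeta(
                sample_id=row["sample_id"],
                group=row["group"],
                replicate=rep,
                ki67li=float(ki67) if ki67 not in (None, "") else None,
                cq_values=cq or None,
            )
        )
    return samples


def write_samples(samples: Iterable[SampleMeta], tsv_path) -> None:
    samples = list(samples)
    assays = sorted({a for s in samples if s.cq_values for a in s.cq_values})
    with open(tsv_path, "w", encoding="utf-8") as fh:
        cols = ["sample_id", "group", "replicate", "ki67li"] + [
            f"cq_{a}" for a in assays
        ]
        fh.write("\t".join(cols) + "\n")
        for s in samples:
            row = [
                s.sample_id,
                s.group,
                str(s.replicate),
                "" if s.ki67li is None else f"{s.ki67li:g}",
            ]
            for a in assays:
                v = (s.cq_values or {}).get(a)
                row.append("" if v is None else f"{v:g}")
            fh.write("\t".join(row) + "\n")
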