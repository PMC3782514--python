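"""Region data model and FASTA/GFF3/BED input-output.

All coordinates inside the package are 0-based half-open. GFF3 (1-based closed)
is converted exactly at the I/O boundary; BED is already half-open.

Residues are uppercase over the alphabet {A, C, G, T, N}; IUPAC ambiguity codes
and anything else collapse to ``N`` on read (the count of collapsed characters
is logged). ``N`` columns are excluded from every distance computation
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: feature categories recognised throughout the package
FEATURE_KINDS = frozenset(
    {
        "gene",
        "exon",
        "CDS",
        "five_prime_UTR",
        "three_prime_UTR",
        "TE",
        "LTR5",
        "LTR3",
        "SSR",
        "CNS",
        "other",
    }
)

_VALID = set("ACGTN")


@dataclass(frozen=True)
class FeatureInterval:
    """A typed interval on a region, 0-based half-open."""

    start: int
    end: int
    strand: str = "."
    kind: str = "other"
    name: str = ""
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "FeatureInterval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class GenomicRegion:
    """A named nucleotide sequence plus typed feature intervals."""

    id: str
    residues: str
    features: list[FeatureInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(
                f"region {self.id!r} contains non-ACGTN residues {sorted(bad)}; "
                "sanitise on read"
            )
        self.validate_features()

    @property
    def length(self) -> int:
        return len(self.residues)

    def validate_features(self) -> None:
        for f in self.features:
            if f.end > self.length:
                raise ValueError(
                    f"feature {f.name or f.kind} [{f.start}, {f.end}) exceeds "
                    f"region {self.id!r} length {self.length}"
                )
        # twin-LTR sub-intervals must annotate a TE that contains them
        tes = [f for f in self.features if f.kind == "TE"]
        for f in self.features:
            if f.kind in {"LTR5", "LTR3"} and not any(
                te.start <= f.start and f.end <= te.end for te in tes
            ):
                raise ValueError(
                    f"{f.kind} interval [{f.start}, {f.end}) in region "
                    f"{self.id!r} is not nested within any TE feature"
                )

    def features_of_kind(self, *kinds: str) -> list[FeatureInterval]:
        want = set(kinds)
        return [f for f in self.features if f.kind in want]

    def subsequence(self, start: int, end: int) -> str:
        if not (0 <= start <= end <= self.length):
            raise ValueError(f"[{start}, {end}) outside region of length {self.length}")
        return self.residues[start:end]


def sanitize_residues(raw: str) -> tuple[str, int]:
    """Uppercase and collapse non-ACGTN characters to N.

    Returns the cleaned string and the number of characters collapsed.
    """
    up = raw.upper()
    cleaned = []
    n_mapped = 0
    for ch in up:
        if ch in _VALID:
            cleaned.append(ch)
        else:
            cleaned.append("N")
            n_mapped += 1
    return "".join(cleaned), n_mapped


def read_fasta(path: str | Path) -> list[GenomicRegion]:
    """Read a multi-record FASTA into GenomicRegions.

    Lowercase residues are uppercased; ambiguity codes collapse to N with a
    logged warning count. Empty files and duplicate record ids are hard errors.
    """
    path = Path(path)
    regions: list[GenomicRegion] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues, n_mapped = sanitize_residues(str(rec.seq))
        if n_mapped:
            logger.warning(
                "record %s: %d non-ACGTN characters mapped to N", rec.id, n_mapped
            )
        if not residues:
            raise ValueError(f"FASTA record {rec.id!r} in {path} is empty")
        regions.append(GenomicRegion(id=rec.id, residues=residues))
    if not regions:
        raise ValueError(f"no FASTA records found in {path}")
    return regions


def write_fasta(regions: Iterable[GenomicRegion], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for r in regions:
            fh.write(f">{r.id}\n")
            for i in range(0, r.length, width):
                fh.write(r.residues[i : i + width] + "\n")


# --------------------------------------------------------------------------
# feature annotation I/O (GFF3 1-based closed; BED6 0-based half-open)

_GFF_COLS = 9


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    text = text.strip()
    if text in {"", "."}:
        return attrs
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"malformed GFF3 attribute {chunk!r}")
        k, v = chunk.split("=", 1)
        attrs[k] = v
    return attrs


def read_features(
    path: str | Path,
    dialect: str = "gff3",
    region_lengths: Mapping[str, int] | None = None,
) -> dict[str, list[FeatureInterval]]:
    """Read feature intervals per region id, normalised to 0-based half-open.

    GFF3 coordinates (1-based closed) are converted exactly; BED intervals pass
    through. With ``region_lengths``, out-of-bounds intervals raise an error
    naming the offending line.
    """
    path = Path(path)
    if dialect not in {"gff3", "bed"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    out: dict[str, list[FeatureInterval]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            cols = line.split("\t")
            if dialect == "gff3":
                if len(cols) != _GFF_COLS:
                    raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
                seqid, _src, ftype, start1, end1, _score, strand, _phase, attr_text = cols
                start = int(start1) - 1
                end = int(end1)
                attrs = _parse_gff3_attributes(attr_text)
                if "Name" in attrs:
                    name = attrs.pop("Name")
                elif "ID" in attrs:
                    name = attrs.pop("ID")
                else:
                    name = ""
                kind = ftype if ftype in FEATURE_KINDS else "other"
            else:
                if len(cols) < 6:
                    raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
                seqid, start_s, end_s, bed_name, _score, strand = cols[:6]
                start, end = int(start_s), int(end_s)
                if "|" in bed_name:
                    kind, name = bed_name.split("|", 1)
                else:
                    kind, name = "other", bed_name
                if kind not in FEATURE_KINDS:
                    kind = "other"
                attrs = {}
            if region_lengths is not None and seqid in region_lengths:
                if end > region_lengths[seqid] or start < 0:
                    raise ValueError(
                        f"{path}:{lineno}: interval [{start}, {end}) outside "
                        f"region {seqid!r} of length {region_lengths[seqid]}: {line!r}"
                    )
            out.setdefault(seqid, []).append(
                FeatureInterval(start=start, end=end, strand=strand, kind=kind,
                                name=name, attributes=attrs)
            )
    return out


def write_features(
    intervals: Mapping[str, list[FeatureInterval]],
    path: str | Path,
    dialect: str = "gff3",
    source: str = "syntevol",
) -> None:
    """Write feature intervals; read_features(write_features(x)) == x.

    The BED dialect stores ``kind|name`` in column 4 and cannot carry the
    attributes map; the exact round-trip holds for attribute-free intervals.
    """
    path = Path(path)
    if dialect not in {"gff3", "bed"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    with path.open("w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for seqid in intervals:
                for f in intervals[seqid]:
                    attrs = dict(f.attributes)
                    parts = []
                    if f.name:
                        parts.append(f"Name={f.name}")
                    parts += [f"{k}={v}" for k, v in attrs.items()]
                    attr_text = ";".join(parts) if parts else "."
                    fh.write(
                        "\t".join(
                            [seqid, source, f.kind, str(f.start + 1), str(f.end),
                             ".", f.strand, ".", attr_text]
                        )
                        + "\n"
                    )
        else:
            fh.write('track name="syntevol"\n')
            for seqid in intervals:
                for f in intervals[seqid]:
                    fh.write(
                        "\t".join(
                            [seqid, str(f.start), str(f.end),
                             f"{f.kind}|{f.name}", "0", f.strand]
                        )
                        + "\n"
                    )
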