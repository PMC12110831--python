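"""Core data model for annotated circular mitochondrial genomes.

Coordinates are 1-based and fully inclusive on the deposited heavy (H)
strand, so a feature's length is ``end - start + 1``.  A feature may wrap
the circular origin, encoded as ``start > end`` (it spans
``genome_length -> 1``); negative positions are never used.  Strands are
labelled ``H`` (forward / heavy) and ``L`` (reverse-complement / light).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import SeqIO

FEATURE_TYPES = ("PCG", "tRNA", "rRNA", "control")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

FEATURE_TABLE_COLUMNS = ("name", "ftype", "strand", "start", "end", "anticodon")


class FormatError(ValueError):
    """Input file does not conform to the expected format."""


class CoordinateError(ValueError):
    """A feature's coordinates are inconsistent with the genome."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """One annotated gene or region on a circular mitogenome.

    Parameters
    ----------
    name
        Gene label, e.g. ``"ND2"``, ``"tRNA-Ser(AGC)"``, ``"rrnL"``,
        ``"D-loop"``.
    ftype
        Functional class: ``"PCG"``, ``"tRNA"``, ``"rRNA"`` or
        ``"control"``.
    strand
        ``"H"`` for the deposited strand, ``"L"`` for its reverse
        complement.
    start, end
        1-based inclusive positions on the H strand.  ``start > end``
        encodes a feature wrapping the circular origin.
    anticodon
        3-mer (DNA alphabet, gene orientation) for tRNAs; ``None``
        otherwise.
    """

    name: str
    ftype: str
    strand: str
    start: int
    end: int
    anticodon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise CoordinateError(
                f"{self.name}: coordinates must be >= 1 (got {self.start}..{self.end})"
            )
        if self.anticodon is not None and self.ftype != "tRNA":
            raise ValueError(f"{self.name}: only tRNA features carry an anticodon")

    @property
    def wraps(self) -> bool:
        return self.start > self.end


@dataclass
class Mitogenome:
    """A circular mitochondrial genome with ordered feature annotations."""

    seq: str
    features: list[Feature] = field(default_factory=list)
    taxon: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        for f in self.features:
            if f.start > self.length or f.end > self.length:
                raise CoordinateError(
                    f"{f.name}: coordinates {f.start}..{f.end} exceed genome "
                    f"length {self.length}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.name))

    @property
    def length(self) -> int:
        return len(self.seq)

    def features_of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.ftype == ftype]

    @property
    def pcgs(self) -> list[Feature]:
        return self.features_of_type("PCG")

    @property
    def trnas(self) -> list[Feature]:
        return self.features_of_type("tRNA")


def feature_length(f: Feature, genome_length: int) -> int:
    """Length in bp of a feature, circular-aware."""
    if f.wraps:
        return genome_length - f.start + 1 + f.end
    return f.end - f.start + 1


def extract_feature_seq(g: Mitogenome, f: Feature) -> str:
    """Return the 5'->3' sequence of the strand a feature is encoded on.

    H-strand features are a direct slice of the deposited sequence;
    L-strand features are reverse-complemented.  Features wrapping the
    origin concatenate the tail of the genome with its head.
    """
    if f.start > g.length or f.end > g.length:
        raise CoordinateError(f"{f.name} lies beyond the sequence")
    if f.wraps:
        s = g.seq[f.start - 1 :] + g.seq[: f.end]
    else:
        s = g.seq[f.start - 1 : f.end]
    return reverse_complement(s) if f.strand == "L" else s


# ---------------------------------------------------------------------------
# GenBank reader
# ---------------------------------------------------------------------------

_GB_TYPE_MAP = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "control",
    "D_loop": "control",
}

_CONTROL_NAME_RE = re.compile(r"(d[-_]?loop|control)", re.IGNORECASE)


def _gb_feature_name(feat) -> str:
    for key in ("gene", "product", "note"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return feat.type


def _gb_anticodon(feat) -> Optional[str]:
    if "anticodon" in feat.qualifiers:
        raw = str(feat.qualifiers["anticodon"][0])
        m = re.search(r"seq\s*:\s*([acgtu]{3})", raw, re.IGNORECASE)
        if m:
            return m.group(1).upper().replace("U", "T")
        if re.fullmatch(r"[ACGTUacgtu]{3}", raw.strip()):
            return raw.strip().upper().replace("U", "T")
    if "note" in feat.qualifiers:
        m = re.search(
            r"anticodon\s*[:=]?\s*([ACGTUacgtu]{3})", str(feat.qualifiers["note"][0])
        )
        if m:
            return m.group(1).upper().replace("U", "T")
    return None


def read_genbank(path: str | Path) -> Mitogenome:
    """Read a GenBank flat file into a :class:`Mitogenome`.

    CDS features map to PCGs, ``tRNA``/``rRNA`` to their classes, and
    ``D-loop`` (or a ``misc_feature`` whose label mentions the control
    region) to the control class.  A ``join`` across the origin becomes a
    wrapping feature (``start > end``).
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper().replace("U", "T")
    if not seq:
        raise FormatError(f"{path}: GenBank record has no ORIGIN sequence")
    n = len(seq)
    features: list[Feature] = []
    for feat in record.features:
        ftype = _GB_TYPE_MAP.get(feat.type)
        name = _gb_feature_name(feat)
        if ftype is None:
            if feat.type == "misc_feature" and _CONTROL_NAME_RE.search(name):
                ftype = "control"
            else:
                continue
        strand = "L" if feat.location.strand == -1 else "H"
        parts = sorted(feat.location.parts, key=lambda p: int(p.start))
        if (
            len(parts) == 2
            and int(parts[1].end) == n
            and int(parts[0].start) == 0
        ):
            # join(x..n, 1..y): wraps the circular origin
            start, end = int(parts[1].start) + 1, int(parts[0].end)
        else:
            start, end = int(feat.location.start) + 1, int(feat.location.end)
        if end > n or start > n:
            raise CoordinateError(
                f"{path}: feature {name} at {start}..{end} exceeds sequence length {n}"
            )
        features.append(
            Feature(
                name=name,
                ftype=ftype,
                strand=strand,
                start=start,
                end=end,
                anticodon=_gb_anticodon(feat) if ftype == "tRNA" else None,
            )
        )
    return Mitogenome(seq=seq, features=features, taxon=record.annotations.get("organism", record.id))


# ---------------------------------------------------------------------------
# FASTA + TSV feature table
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Read a single-record FASTA; returns (name, sequence)."""
    record = SeqIO.read(str(path), "fasta")
    return record.id, str(record.seq).upper().replace("U", "T")


def write_fasta(path: str | Path, name: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def read_feature_table(fasta: str | Path, table: str | Path) -> Mitogenome:
    """Read a FASTA sequence plus a TSV feature table.

    The table has a header row with columns
    ``name  ftype  strand  start  end  anticodon`` (anticodon blank or
    ``-`` for non-tRNAs).  Rows may be in any order; features are
    re-sorted by linearized start.
    """
    taxon, seq = read_fasta(fasta)
    features: list[Feature] = []
    seen: set[tuple] = set()
    with open(table) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().lower() for h in header[:5]] != list(FEATURE_TABLE_COLUMNS[:5]):
            raise FormatError(
                f"{table}: expected header starting with "
                f"{FEATURE_TABLE_COLUMNS[:5]}, got {header[:5]}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if len(cells) < 5:
                raise FormatError(f"{table}:{lineno}: expected >=5 columns")
            name, ftype, strand = cells[0], cells[1], cells[2]
            if strand not in ("H", "L"):
                raise ValueError(
                    f"{table}:{lineno}: strand must be 'H' or 'L', got {strand!r}"
                )
            anticodon = cells[5].strip() if len(cells) > 5 else ""
            if anticodon in ("", "-", "."):
                anticodon = None
            key = (name, ftype, int(cells[3]), int(cells[4]))
            if key in seen:
                raise ValueError(f"{table}:{lineno}: duplicate feature {key}")
            seen.add(key)
            features.append(
                Feature(
                    name=name,
                    ftype=ftype,
                    strand=strand,
                    start=int(cells[3]),
                    end=int(cells[4]),
                    anticodon=anticodon,
                )
            )
    return Mitogenome(seq=seq, features=features, taxon=taxon)


def write_feature_table(path: str | Path, g: Mitogenome) -> None:
    """Write the TSV feature table that :func:`read_feature_table` reads."""
    with open(path, "w") as fh:
        fh.write("\t".join(FEATURE_TABLE_COLUMNS) + "\n")
        for f in g.features:
            fh.write(
                "\t".join(
                    [
                        f.name,
                        f.ftype,
                        f.strand,
                        str(f.start),
                        str(f.end),
                        f.anticodon or "-",
                    ]
                )
                + "\n"
            )


def require_features(g: Mitogenome) -> Mitogenome:
    """Reject an annotation-free genome (downstream stages need features)."""
    if not g.features:
        raise ValueError("mitogenome carries no feature annotations")
    return g
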