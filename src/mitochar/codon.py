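"""Codon usage under the invertebrate mitochondrial genetic code.

Codon extraction, start/stop calling (including the incomplete stops
``T`` / ``TA`` completed by polyadenylation), codon counts and
frequencies, relative synonymous codon usage (RSCU), per-strand amino
acid tallies, and anticodon correspondence.

RSCU of codon *c* in a synonymous family of size *k* with family total
*S* is ``n_c * k / S``: the observed count divided by the count expected
if all synonyms were used equally.  RSCU 1 means no bias.  Stop codons
(TAA/TAG) are excluded from all counts; the start codon is retained.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio.Data import CodonTable

from mitochar.model import Feature, Mitogenome, extract_feature_seq, reverse_complement

_AA_3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map with synonymous-family bookkeeping."""

    table_id: int
    forward: Mapping[str, str]  # codon (DNA) -> 3-letter amino acid
    stops: frozenset[str]

    @classmethod
    def from_ncbi(cls, table_id: int) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        forward = {c: _AA_3[aa] for c, aa in table.forward_table.items()}
        return cls(
            table_id=table_id,
            forward=forward,
            stops=frozenset(table.stop_codons),
        )

    def families(self) -> dict[str, list[str]]:
        """Amino acid -> sorted list of its synonymous codons."""
        fams: dict[str, list[str]] = {}
        for codon, aa in sorted(self.forward.items()):
            fams.setdefault(aa, []).append(codon)
        return fams

    def family_size(self, aa: str) -> int:
        return len(self.families()[aa])


#: NCBI translation table 5.  AGA/AGG encode Ser, ATA Met, TGA Trp;
#: stops are TAA/TAG only (giving Ser a family of 8 and Trp of 2).
INVERTEBRATE_MITO = GeneticCode.from_ncbi(5)


@dataclass(frozen=True)
class StartStopCall:
    gene: str
    start_codon: str
    stop_codon: str  # "TAA"/"TAG"/... or "T"/"TA"
    incomplete: bool
    warning: Optional[str] = None


def call_start_stop(cds: str, gene: str = "", code: GeneticCode = INVERTEBRATE_MITO) -> StartStopCall:
    """Call start and stop codons of a coding-strand CDS.

    The start is the first triplet.  If the CDS length is a multiple of
    3 the stop is the final triplet; otherwise the trailing 1-2 nt are
    reported as an incomplete stop (``T`` or ``TA``), the form completed
    to UAA on the transcript by polyadenylation.  A trailing remainder
    other than T/TA is still returned, with a warning attached.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) < 6:
        raise ValueError(f"{gene or 'CDS'}: too short to call start/stop ({len(cds)} nt)")
    start = cds[:3]
    rem = len(cds) % 3
    if rem == 0:
        stop = cds[-3:]
        warning = None if stop in code.stops else f"terminal codon {stop} is not a stop"
        return StartStopCall(gene, start, stop, incomplete=False, warning=warning)
    tail = cds[-rem:]
    warning = None if tail in ("T", "TA") else f"incomplete stop {tail!r} is not T/TA"
    return StartStopCall(gene, start, tail, incomplete=True, warning=warning)


@dataclass
class CodonExtraction:
    """Retained in-frame codons of one CDS plus what was set aside."""

    codons: list[str]
    terminal_stop: Optional[str] = None
    incomplete_tail: Optional[str] = None
    internal_stops: list[tuple[int, str]] = field(default_factory=list)


def extract_codons(cds: str, code: GeneticCode = INVERTEBRATE_MITO) -> CodonExtraction:
    """In-frame codons retained for usage counts.

    Reads triplets from position 1 of the coding strand.  The trailing
    incomplete codon (if the length is not a multiple of 3) is dropped,
    as is a terminal complete stop codon.  Internal stop codons are kept
    out of the counts and reported (with a warning) rather than raised,
    so mutated or synthetic inputs do not abort a run.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) < 6:
        raise ValueError(f"CDS too short ({len(cds)} nt)")
    rem = len(cds) % 3
    result = CodonExtraction(codons=[])
    if rem:
        result.incomplete_tail = cds[-rem:]
        cds = cds[: len(cds) - rem]
    triplets = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if triplets and triplets[-1] in code.stops:
        result.terminal_stop = triplets.pop()
    for i, t in enumerate(triplets):
        if t in code.stops:
            result.internal_stops.append((i + 1, t))
        else:
            result.codons.append(t)
    if result.internal_stops:
        warnings.warn(
            f"{len(result.internal_stops)} internal stop codon(s) excluded from counts"
        )
    return result


@dataclass(frozen=True)
class CodonUsageRow:
    codon: str  # DNA alphabet
    amino_acid: str
    n: int
    pct: float
    rscu: float

    @property
    def rna_codon(self) -> str:
        return self.codon.replace("T", "U")


@dataclass
class CodonUsageTable:
    rows: list[CodonUsageRow]
    n_total: int
    empty_families: list[str] = field(default_factory=list)

    def by_codon(self) -> dict[str, CodonUsageRow]:
        return {r.codon: r for r in self.rows}

    def family_rows(self, aa: str) -> list[CodonUsageRow]:
        return [r for r in self.rows if r.amino_acid == aa]

    def modal_codon(self, aa: str) -> Optional[str]:
        rows = self.family_rows(aa)
        if not rows or all(r.n == 0 for r in rows):
            return None
        return max(rows, key=lambda r: (r.n, r.codon)).codon


def rscu(counts: Mapping[str, int], code: GeneticCode = INVERTEBRATE_MITO) -> CodonUsageTable:
    """Build the codon-usage table (counts, % of total, RSCU).

    ``counts`` maps sense codons (DNA or RNA alphabet) to observed
    counts.  ``pct`` is 100 * n / N_total over all retained codons;
    RSCU is n * k / (family total), with every member of an unobserved
    family reported as 0 and the family flagged.
    """
    clean: dict[str, int] = {}
    for codon, n in counts.items():
        c = codon.upper().replace("U", "T")
        if c in code.stops:
            raise ValueError(f"stop codon {codon} in usage counts")
        if c not in code.forward:
            raise ValueError(f"unknown codon {codon!r}")
        clean[c] = clean.get(c, 0) + int(n)
    n_total = sum(clean.values())
    rows: list[CodonUsageRow] = []
    empty: list[str] = []
    for aa, fam in code.families().items():
        fam_total = sum(clean.get(c, 0) for c in fam)
        if fam_total == 0:
            empty.append(aa)
        k = len(fam)
        for c in fam:
            n = clean.get(c, 0)
            rows.append(
                CodonUsageRow(
                    codon=c,
                    amino_acid=aa,
                    n=n,
                    pct=(100.0 * n / n_total) if n_total else 0.0,
                    rscu=(n * k / fam_total) if fam_total else 0.0,
                )
            )
    rows.sort(key=lambda r: (r.amino_acid, r.codon))
    return CodonUsageTable(rows=rows, n_total=n_total, empty_families=sorted(empty))


def genome_codon_counts(g: Mitogenome, code: GeneticCode = INVERTEBRATE_MITO) -> Counter:
    """Retained codon counts pooled over all annotated PCGs."""
    counts: Counter = Counter()
    for f in g.pcgs:
        counts.update(extract_codons(extract_feature_seq(g, f), code).codons)
    return counts


def genome_usage_table(g: Mitogenome, code: GeneticCode = INVERTEBRATE_MITO) -> CodonUsageTable:
    return rscu(genome_codon_counts(g, code), code)


def strand_amino_acid_tally(
    g: Mitogenome, code: GeneticCode = INVERTEBRATE_MITO
) -> dict[str, Counter]:
    """Amino-acid counts of retained codons split by coding strand.

    On the typical lepidopteran map 9 PCGs sit on the H strand and 4 on
    the L strand, so the H tally dominates.
    """
    tally = {"H": Counter(), "L": Counter()}
    for f in g.pcgs:
        codons = extract_codons(extract_feature_seq(g, f), code).codons
        tally[f.strand].update(code.forward[c] for c in codons)
    return tally


@dataclass(frozen=True)
class AnticodonEntry:
    amino_acid: str
    trna: Optional[str]
    anticodon: Optional[str]
    expected_codon: Optional[str]  # reverse complement of the anticodon
    modal_codon: Optional[str]
    match: Optional[bool]


def anticodon_correspondence(
    usage: CodonUsageTable,
    trnas: Sequence[Feature],
    code: GeneticCode = INVERTEBRATE_MITO,
) -> list[AnticodonEntry]:
    """Compare each family's most-used codon with its tRNA anticodon.

    The codon a tRNA reads (at the wobble-free position) is the reverse
    complement of its anticodon; the report flags, per tRNA, whether the
    family's modal codon equals that expected codon.  Families without a
    cognate tRNA in the input appear as unmatched entries.
    """
    entries: list[AnticodonEntry] = []
    seen_aas: set[str] = set()
    for t in trnas:
        if not t.anticodon:
            continue
        expected = reverse_complement(t.anticodon.upper().replace("U", "T"))
        aa = code.forward.get(expected)
        if aa is None:
            entries.append(AnticodonEntry(
                amino_acid="?", trna=t.name, anticodon=t.anticodon,
                expected_codon=expected, modal_codon=None, match=None,
            ))
            continue
        seen_aas.add(aa)
        modal = usage.modal_codon(aa)
        entries.append(AnticodonEntry(
            amino_acid=aa, trna=t.name, anticodon=t.anticodon,
            expected_codon=expected, modal_codon=modal,
            match=None if modal is None else modal == expected,
        ))
    for aa in sorted(code.families()):
        if aa not in seen_aas:
            entries.append(AnticodonEntry(
                amino_acid=aa, trna=None, anticodon=None,
                expected_codon=None, modal_codon=usage.modal_codon(aa), match=None,
            ))
    return entries
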