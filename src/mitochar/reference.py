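"""Published annotation and summary tables for the *Aloa lactinea* mitogenome.

*Aloa lactinea* (red costate tiger moth, Lepidoptera: Erebidae: Arctiinae)
has a 15,380 bp circular mitogenome (GenBank accession PV288325) with the
ancestral lepidopteran gene arrangement: 13 protein-coding genes, 22 tRNAs,
2 rRNAs and one control region.  This module transcribes the published
gene ledger (coordinates, strands, start/stop codons, anticodons), the
per-region base-composition table, and the codon-usage counts, so that the
package's statistics can be exercised and cross-checked against the
printed values without downloading the accession.

The deposit labels the two rRNAs "18S"/"12S"; by length (1396 / 819 bp)
they are the mitochondrial large and small subunit rRNAs, normalized here
to ``rrnL`` / ``rrnS`` (original labels kept in ``RRNA_ORIGINAL_LABELS``).
"""

from __future__ import annotations

from mitochar.model import Feature, Mitogenome

GENOME_LENGTH = 15380

RRNA_ORIGINAL_LABELS = {"rrnL": "18S rRNA", "rrnS": "12S rRNA"}

# name, ftype, strand, start, end, anticodon, start_codon, stop_codon
_FEATURE_ROWS = [
    ("tRNA-Met", "tRNA", "H", 1, 67, "CAT", None, None),
    ("tRNA-Ile", "tRNA", "H", 70, 133, "GAT", None, None),
    ("tRNA-Gln", "tRNA", "L", 131, 199, "TTG", None, None),
    ("ND2", "PCG", "H", 252, 1262, None, "ATT", "TAA"),
    ("tRNA-Trp", "tRNA", "H", 1264, 1332, "TCA", None, None),
    ("tRNA-Cys", "tRNA", "L", 1325, 1389, "GCA", None, None),
    ("tRNA-Tyr", "tRNA", "L", 1390, 1457, "GTA", None, None),
    ("COI", "PCG", "H", 1495, 3000, None, "ATT", "TAA"),
    ("tRNA-Leu(TTA)", "tRNA", "H", 2996, 3062, "TAA", None, None),
    ("COII", "PCG", "H", 3063, 3744, None, "ATG", "T"),
    ("tRNA-Lys", "tRNA", "H", 3745, 3814, "CTT", None, None),
    ("tRNA-Asp", "tRNA", "H", 3815, 3881, "GTC", None, None),
    ("ATP8", "PCG", "H", 3882, 4043, None, "ATT", "TAA"),
    ("ATP6", "PCG", "H", 4037, 4714, None, "ATG", "TAA"),
    ("COIII", "PCG", "H", 4719, 5510, None, "ATG", "TAA"),
    ("tRNA-Gly", "tRNA", "H", 5514, 5578, "TCC", None, None),
    ("ND3", "PCG", "H", 5588, 5932, None, "ATA", "TAA"),
    ("tRNA-Ala", "tRNA", "H", 5932, 5999, "TGC", None, None),
    ("tRNA-Arg", "tRNA", "H", 6012, 6074, "TCG", None, None),
    ("tRNA-Asn", "tRNA", "H", 6076, 6140, "GTT", None, None),
    ("tRNA-Ser(AGC)", "tRNA", "H", 6151, 6216, "GCT", None, None),
    ("tRNA-Glu", "tRNA", "H", 6229, 6294, "TTC", None, None),
    ("tRNA-Phe", "tRNA", "L", 6301, 6367, "GAA", None, None),
    ("ND5", "PCG", "L", 6371, 8059, None, "ATA", "TAA"),
    ("tRNA-His", "tRNA", "L", 8111, 8177, "GTG", None, None),
    ("ND4", "PCG", "L", 8178, 9516, None, "ATG", "T"),
    ("ND4L", "PCG", "L", 9519, 9815, None, "ATA", "TAA"),
    ("tRNA-Thr", "tRNA", "H", 9822, 9886, "TGT", None, None),
    ("tRNA-Pro", "tRNA", "L", 9887, 9953, "TGG", None, None),
    ("ND6", "PCG", "H", 9961, 10491, None, "ATA", "TAA"),
    ("CYTB", "PCG", "H", 10499, 11650, None, "ATG", "TAA"),
    ("tRNA-Ser(TCA)", "tRNA", "H", 11680, 11747, "TGA", None, None),
    ("ND1", "PCG", "L", 11765, 12703, None, "ATG", "TAA"),
    ("tRNA-Leu(CTA)", "tRNA", "L", 12705, 12772, "TAG", None, None),
    ("rrnL", "rRNA", "L", 12795, 14190, None, None, None),
    ("tRNA-Val", "tRNA", "L", 14194, 14259, "TAC", None, None),
    ("rrnS", "rRNA", "L", 14259, 15077, None, None, None),
    ("D-loop", "control", "H", 15078, 15380, None, None, None),
]

#: Public view of the transcribed gene ledger rows.
FEATURE_ROWS = tuple(_FEATURE_ROWS)

#: Published start/stop codon calls per PCG (stop "T" = incomplete).
START_STOP = {
    row[0]: (row[6], row[7]) for row in _FEATURE_ROWS if row[1] == "PCG"
}


def features() -> list[Feature]:
    """The 38 published features as :class:`~mitochar.model.Feature`."""
    return [
        Feature(name=n, ftype=t, strand=s, start=a, end=b, anticodon=ac)
        for n, t, s, a, b, ac, _, _ in _FEATURE_ROWS
    ]


def annotation_only_genome(fill: str = "N") -> Mitogenome:
    """The published annotation over a placeholder sequence.

    The deposited nucleotide sequence is not bundled; architecture and
    geometry statistics (spacers, overlaps, gene order, lengths) depend
    only on coordinates and are exact on this object.  Composition and
    codon statistics require the real or a synthetic sequence.
    """
    return Mitogenome(
        seq=fill * GENOME_LENGTH, features=features(), taxon="Aloa lactinea"
    )


#: Per-region base composition (percent A, T, C, G) as published.
#: Keys follow the report row labels; values are (A, T, C, G).
BASE_COMPOSITION = {
    "Genome": (39.95, 41.05, 11.37, 7.62),
    "PCGs (total)": (34.48, 45.44, 9.65, 10.44),
    "ND2": (36.30, 48.66, 9.20, 5.84),
    "COI": (31.54, 41.10, 13.75, 13.61),
    "COII": (35.78, 41.50, 12.46, 10.26),
    "ATP8": (45.06, 48.77, 4.32, 1.85),
    "ATP6": (35.55, 43.81, 12.83, 7.82),
    "COIII": (33.08, 41.54, 13.51, 11.87),
    "ND3": (35.65, 46.96, 11.30, 6.09),
    "ND5": (35.70, 46.12, 6.10, 12.08),
    "ND4": (35.18, 47.27, 5.90, 11.65),
    "ND4L": (31.99, 54.55, 3.03, 10.44),
    "ND6": (37.10, 50.09, 8.10, 4.71),
    "CYTB": (33.33, 44.18, 12.67, 9.81),
    "ND1": (31.95, 47.28, 7.24, 13.53),
    "First site": (36.57, 45.66, 8.41, 9.33),
    "Secondary site": (35.06, 43.42, 10.44, 11.06),
    "Tertiary site": (31.75, 47.23, 10.09, 10.92),
    "tRNA gene": (41.38, 40.49, 7.57, 10.57),
    "rRNA gene": (43.12, 42.17, 4.74, 9.98),
    "D-loop zone": (32.01, 42.24, 11.88, 13.86),
}

#: Published AT/GC skews per region (for cross-checks of the skew formulas).
SKEWS = {
    "Genome": (-0.0136, -0.1975),
    "ND2": (-0.1455, -0.2234),
    "ND4L": (-0.2607, 0.5501),
    "CYTB": (-0.1400, -0.1272),
}

#: Published codon-usage counts over the 13 PCGs (DNA alphabet), with the
#: published percent-of-total and RSCU to 2 decimals.  3696 codons total;
#: stop codons excluded.  AGA/AGG are serine under the invertebrate
#: mitochondrial code.
CODON_USAGE = {
    # codon: (amino_acid, n, pct, rscu)
    "GCA": ("Ala", 48, 1.30, 1.51),
    "GCC": ("Ala", 3, 0.08, 0.09),
    "GCG": ("Ala", 2, 0.05, 0.06),
    "GCT": ("Ala", 74, 2.00, 2.33),
    "CGA": ("Arg", 39, 1.06, 3.00),
    "CGC": ("Arg", 0, 0.00, 0.00),
    "CGG": ("Arg", 2, 0.05, 0.15),
    "CGT": ("Arg", 11, 0.30, 0.85),
    "AAC": ("Asn", 10, 0.27, 0.08),
    "AAT": ("Asn", 238, 6.44, 1.92),
    "GAC": ("Asp", 1, 0.03, 0.03),
    "GAT": ("Asp", 62, 1.68, 1.97),
    "TGC": ("Cys", 0, 0.00, 0.00),
    "TGT": ("Cys", 29, 0.78, 2.00),
    "CAA": ("Gln", 62, 1.68, 2.00),
    "CAG": ("Gln", 0, 0.00, 0.00),
    "GAA": ("Glu", 73, 1.98, 1.90),
    "GAG": ("Glu", 4, 0.11, 0.10),
    "GGA": ("Gly", 111, 3.00, 2.24),
    "GGC": ("Gly", 0, 0.00, 0.00),
    "GGG": ("Gly", 25, 0.68, 0.51),
    "GGT": ("Gly", 62, 1.68, 1.25),
    "CAC": ("His", 9, 0.24, 0.28),
    "CAT": ("His", 56, 1.52, 1.72),
    "ATC": ("Ile", 16, 0.43, 0.07),
    "ATT": ("Ile", 451, 12.20, 1.93),
    "CTA": ("Leu", 16, 0.43, 0.18),
    "CTC": ("Leu", 2, 0.05, 0.02),
    "CTG": ("Leu", 0, 0.00, 0.00),
    "CTT": ("Leu", 43, 1.16, 0.47),
    "TTA": ("Leu", 475, 12.85, 5.20),
    "TTG": ("Leu", 12, 0.32, 0.13),
    "AAA": ("Lys", 98, 2.65, 1.90),
    "AAG": ("Lys", 5, 0.14, 0.10),
    "ATA": ("Met", 277, 7.49, 1.87),
    "ATG": ("Met", 20, 0.54, 0.13),
    "TTC": ("Phe", 21, 0.57, 0.12),
    "TTT": ("Phe", 323, 8.74, 1.88),
    "CCA": ("Pro", 31, 0.84, 0.98),
    "CCC": ("Pro", 7, 0.19, 0.22),
    "CCG": ("Pro", 2, 0.05, 0.06),
    "CCT": ("Pro", 86, 2.33, 2.73),
    "AGA": ("Ser", 88, 2.38, 2.23),
    "AGC": ("Ser", 0, 0.00, 0.00),
    "AGG": ("Ser", 0, 0.00, 0.00),
    "AGT": ("Ser", 26, 0.70, 0.66),
    "TCA": ("Ser", 78, 2.11, 1.98),
    "TCC": ("Ser", 9, 0.24, 0.23),
    "TCG": ("Ser", 0, 0.00, 0.00),
    "TCT": ("Ser", 114, 3.08, 2.90),
    "ACA": ("Thr", 61, 1.65, 1.64),
    "ACC": ("Thr", 14, 0.38, 0.37),
    "ACG": ("Thr", 1, 0.03, 0.03),
    "ACT": ("Thr", 73, 1.98, 1.96),
    "TGG": ("Trp", 1, 0.03, 0.02),
    "TGA": ("Trp", 95, 2.57, 1.98),
    "TAC": ("Tyr", 10, 0.27, 0.10),
    "TAT": ("Tyr", 187, 5.06, 1.90),
    "GTA": ("Val", 68, 1.84, 2.05),
    "GTC": ("Val", 2, 0.05, 0.06),
    "GTG": ("Val", 0, 0.00, 0.00),
    "GTT": ("Val", 63, 1.70, 1.89),
}

#: Total retained codons across the 13 PCGs as published.
TOTAL_CODONS = 3696

CODON_COUNTS = {c: v[1] for c, v in CODON_USAGE.items()}
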