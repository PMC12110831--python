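"""Base composition and strand-skew statistics.

Strand asymmetry is summarized by the two standard skew statistics

    AT skew = (A% - T%) / (A% + T%)
    GC skew = (G% - C%) / (G% + C%)

computed over the strand a region is encoded on.  Percentages are taken
over unambiguous A/C/G/T only; ambiguity codes are tallied in a separate
``other`` bucket and do not enter the denominators.  Reports round
percentages to 2 decimals and skews to 4; all arithmetic is done at full
precision internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from mitochar.model import Mitogenome, extract_feature_seq


class EmptyInputError(ValueError):
    pass


class UndefinedSkewError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class CompositionProfile:
    """Base percentages, A+T / G+C content, and skews for one region."""

    region: str
    pctA: float
    pctT: float
    pctC: float
    pctG: float
    at_content: float
    gc_content: float
    at_skew: float
    gc_skew: float
    n_bases: int = 0
    n_other: int = 0

    def rounded(self) -> dict:
        """Report-precision view (percentages 2 dp, skews 4 dp)."""
        return {
            "region": self.region,
            "A": round(self.pctA, 2),
            "T": round(self.pctT, 2),
            "C": round(self.pctC, 2),
            "G": round(self.pctG, 2),
            "A+T": round(self.at_content, 2),
            "G+C": round(self.gc_content, 2),
            "AT skew": round(self.at_skew, 4),
            "GC skew": round(self.gc_skew, 4),
        }


def at_skew(pctA: float, pctT: float) -> float:
    """(A% - T%) / (A% + T%); also valid on raw counts."""
    if pctA + pctT == 0:
        raise UndefinedSkewError("A + T is zero; AT skew undefined")
    return (pctA - pctT) / (pctA + pctT)


def gc_skew(pctG: float, pctC: float) -> float:
    """(G% - C%) / (G% + C%); also valid on raw counts."""
    if pctG + pctC == 0:
        raise UndefinedSkewError("G + C is zero; GC skew undefined")
    return (pctG - pctC) / (pctG + pctC)


def base_composition(seq: str, region: str = "") -> CompositionProfile:
    """Composition profile of a nucleotide string.

    Percentages are over A/C/G/T counts only; any other symbol (N, R, ...)
    is counted in ``n_other`` and excluded from the denominator.
    """
    if not seq:
        raise EmptyInputError("cannot profile an empty sequence")
    seq = seq.upper().replace("U", "T")
    a = seq.count("A")
    t = seq.count("T")
    c = seq.count("C")
    g = seq.count("G")
    n = a + t + c + g
    if n == 0:
        raise EmptyInputError(f"{region or 'sequence'}: no unambiguous A/C/G/T bases")
    pctA, pctT, pctC, pctG = (100.0 * x / n for x in (a, t, c, g))
    return CompositionProfile(
        region=region,
        pctA=pctA,
        pctT=pctT,
        pctC=pctC,
        pctG=pctG,
        at_content=pctA + pctT,
        gc_content=pctC + pctG,
        at_skew=at_skew(a, t) if a + t else 0.0,
        gc_skew=gc_skew(g, c) if g + c else 0.0,
        n_bases=n,
        n_other=len(seq) - n,
    )


def region_profiles(g: Mitogenome) -> list[CompositionProfile]:
    """Per-region composition profiles in the conventional report order.

    One profile each for: the whole genome (H strand as deposited), the
    pooled protein-coding genes (coding-strand sequences), every PCG
    individually, the pooled tRNAs, the pooled rRNAs, and the control
    region.  Absent classes are skipped with a warning.  Per-gene
    profiles use the sense strand, which is what makes the GC skew of
    L-strand genes (e.g. ND5/ND4/ND4L/ND1) come out positive while the
    genome-wide skew is negative.
    """
    if not g.features:
        raise ValueError("genome has no features to profile")
    profiles = [base_composition(g.seq, "Genome")]
    pcgs = g.pcgs
    if pcgs:
        pooled = "".join(extract_feature_seq(g, f) for f in pcgs)
        profiles.append(base_composition(pooled, "PCGs (total)"))
        for f in pcgs:
            profiles.append(base_composition(extract_feature_seq(g, f), f.name))
    else:
        warnings.warn("no PCG features; PCG profiles omitted")
    profiles.extend(codon_position_composition(g) if pcgs else [])
    for ftype, label in (("tRNA", "tRNA gene"), ("rRNA", "rRNA gene")):
        feats = g.features_of_type(ftype)
        if feats:
            pooled = "".join(extract_feature_seq(g, f) for f in feats)
            profiles.append(base_composition(pooled, label))
        else:
            warnings.warn(f"no {ftype} features; {label} profile omitted")
    control = g.features_of_type("control")
    if control:
        pooled = "".join(extract_feature_seq(g, f) for f in control)
        profiles.append(base_composition(pooled, "D-loop zone"))
    else:
        warnings.warn("no control region; D-loop profile omitted")
    return profiles


def codon_position_composition(g: Mitogenome) -> list[CompositionProfile]:
    """Composition at codon positions 1/2/3 pooled across all PCGs.

    Codons are read in frame from the first position of each PCG's
    coding-strand sequence; the trailing incomplete codon (length 1-2
    remainder from an incomplete stop) is excluded, as is a terminal
    complete stop codon, mirroring the codon-usage extraction rules.
    """
    from mitochar.codon import extract_codons  # local import avoids a cycle

    pcgs = g.pcgs
    if not pcgs:
        raise ValueError("no protein-coding genes annotated")
    pools = ["", "", ""]
    for f in pcgs:
        cds = extract_feature_seq(g, f)
        for codon in extract_codons(cds).codons:
            for i in range(3):
                pools[i] += codon[i]
    labels = ("First site", "Secondary site", "Tertiary site")
    return [base_composition(pool, label) for pool, label in zip(pools, labels)]


def profiles_to_rows(profiles: list[CompositionProfile]) -> list[dict]:
    """Rounded report rows (column order: A, T, C, G, A+T, G+C, skews)."""
    return [p.rounded() for p in profiles]
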