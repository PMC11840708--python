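"""Degenerate-primer in silico PCR against reference sequences.

A primer site "matches" a template window when every primer position is
IUPAC-compatible with the template base (base sets intersect), allowing up to
``max_mismatches`` incompatible positions. An amplicon is a forward site and a
downstream reverse-primer site (on the opposite strand) whose product length
falls inside the pair's length window. A genome counts as matched for a pair
when it yields at least one amplicon.

Coordinates are 0-based half-open on the plus strand throughout. No 3'-end
weighting or thermodynamic model is applied: degeneracy-aware exact matching
is the strictest reading of a primer "match".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import IUPAC_ALPHABET, SequenceRecord

#: IUPAC code -> set of concrete bases.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}

# 4-bit masks (A=1, C=2, G=4, T=8) for fast vectorized compatibility tests.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_MASK = np.zeros(256, dtype=np.uint8)
for _code, _bases in IUPAC_SETS.items():
    _MASK[ord(_code)] = sum(_BASE_BIT[b] for b in _bases)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


def iupac_compatible(primer_base: str, template_base: str) -> bool:
    """True iff the IUPAC base sets of the two characters intersect."""
    try:
        a = IUPAC_SETS[primer_base.upper()]
        b = IUPAC_SETS[template_base.upper()]
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r}") from None
    return bool(a & b)


def _seq_masks(seq: str) -> np.ndarray:
    return _MASK[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_one_strand(primer_mask: np.ndarray, tmpl_mask: np.ndarray,
                     max_mismatches: int) -> list[tuple[int, int]]:
    m, L = len(primer_mask), len(tmpl_mask)
    if L < m:
        return []
    n_win = L - m + 1
    mism = np.zeros(n_win, dtype=np.int32)
    for j in range(m):
        mism += (primer_mask[j] & tmpl_mask[j:j + n_win]) == 0
    starts = np.nonzero(mism <= max_mismatches)[0]
    return [(int(s), int(mism[s])) for s in starts]


def find_primer_sites(
    primer: str, template: SequenceRecord, max_mismatches: int = 0
) -> list[tuple[int, str, int]]:
    """All windows matching the primer on either strand of the template.

    Returns (start, strand, mismatches) tuples with 0-based plus-strand
    starts, sorted by start (then strand).
    """
    primer = primer.upper()
    for ch in primer:
        if ch not in IUPAC_ALPHABET:
            raise ValueError(f"non-IUPAC character {ch!r} in primer")
    pm = _seq_masks(primer)
    tm = _seq_masks(template.seq)
    L, m = len(tm), len(pm)
    sites = [(s, "+", mm) for s, mm in _scan_one_strand(pm, tm, max_mismatches)]
    rc = _seq_masks(reverse_complement(template.seq))
    for s, mm in _scan_one_strand(pm, rc, max_mismatches):
        sites.append((L - s - m, "-", mm))
    sites.sort(key=lambda t: (t[0], t[1]))
    return sites


@dataclass(frozen=True)
class PrimerPair:
    """A named degenerate primer pair with an amplicon length window.

    Both primers are given 5'->3' as synthesized: the forward primer matches
    the plus strand, the reverse primer the minus strand. When only
    ``expected_size`` is given the window defaults to +/- 30% around it, which
    suppresses spurious giant products on random sequence.
    """

    name: str
    forward: str
    reverse: str
    min_len: int = 0
    max_len: int = 0
    expected_size: int = 0

    def __post_init__(self) -> None:
        for primer, which in ((self.forward, "forward"), (self.reverse, "reverse")):
            p = primer.upper()
            object.__setattr__(self, which, p)
            if not 10 <= len(p) <= 40:
                raise ValueError(f"{which} primer length must be in [10, 40]")
            for ch in p:
                if ch not in IUPAC_ALPHABET:
                    raise ValueError(f"non-IUPAC character {ch!r} in {which} primer")
        if self.min_len == 0 and self.max_len == 0:
            if self.expected_size <= 0:
                raise ValueError(
                    f"pair {self.name!r}: give min_len/max_len or expected_size"
                )
            object.__setattr__(self, "min_len", round(0.7 * self.expected_size))
            object.__setattr__(self, "max_len", round(1.3 * self.expected_size))
        if not self.min_len < self.max_len:
            raise ValueError(f"pair {self.name!r}: min_len must be < max_len")


#: The two study pairs whose sequences the survey prints: the V4-V5 short-read
#: pair and the near-full-length long-read pair. Expected sizes follow the
#: E. coli numbering embedded in the primer names.
STUDY_PRIMER_PAIRS: tuple[PrimerPair, ...] = (
    PrimerPair(
        name="515YF/Y926R-jed",
        forward="GTGYCAGCMGCCGCGGTAA",
        reverse="CCGYCAATTYMTTTRAGTTT",
        expected_size=411,
    ),
    PrimerPair(
        name="27F/1492R",
        forward="AGRGTTYGATYMTGGCTCAG",
        reverse="RGYTACCTTGTTACGACTT",
        expected_size=1465,
    ),
)


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted amplicon: plus-strand coordinates and primer mismatches."""

    genome_id: str
    strand: str
    fwd_start: int
    rev_end: int
    product_len: int
    fwd_mismatches: int
    rev_mismatches: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.product_len != self.rev_end - self.fwd_start:
            raise ValueError("product_len must equal rev_end - fwd_start")


def amplify(
    pair: PrimerPair, template: SequenceRecord, max_mismatches: int = 0
) -> list[AmpliconHit]:
    """Predict all amplicons of a primer pair on a template (both strands)."""
    fwd_sites = find_primer_sites(pair.forward, template, max_mismatches)
    rev_sites = find_primer_sites(pair.reverse, template, max_mismatches)
    lf, lr = len(pair.forward), len(pair.reverse)

    hits: dict[tuple[int, int], AmpliconHit] = {}

    # Plus-strand product: forward primer on '+', reverse primer on '-',
    # reverse site fully downstream of the forward site.
    for fs, fstrand, fmm in fwd_sites:
        if fstrand != "+":
            continue
        for rs, rstrand, rmm in rev_sites:
            if rstrand != "-":
                continue
            if rs < fs + lf:
                continue
            product = rs + lr - fs
            if pair.min_len <= product <= pair.max_len:
                key = (fs, rs + lr)
                hits.setdefault(key, AmpliconHit(
                    genome_id=template.id, strand="+",
                    fwd_start=fs, rev_end=rs + lr, product_len=product,
                    fwd_mismatches=fmm, rev_mismatches=rmm,
                ))

    # Minus-strand product: forward primer on '-', reverse primer on '+',
    # the reverse-primer site upstream on the plus strand.
    for fs, fstrand, fmm in fwd_sites:
        if fstrand != "-":
            continue
        for rs, rstrand, rmm in rev_sites:
            if rstrand != "+":
                continue
            if fs < rs + lr:
                continue
            product = fs + lf - rs
            if pair.min_len <= product <= pair.max_len:
                key = (rs, fs + lf)
                hits.setdefault(key, AmpliconHit(
                    genome_id=template.id, strand="-",
                    fwd_start=rs, rev_end=fs + lf, product_len=product,
                    fwd_mismatches=fmm, rev_mismatches=rmm,
                ))

    return sorted(hits.values(), key=lambda h: (h.fwd_start, h.rev_end, h.strand))


@dataclass(frozen=True)
class PrimerReport:
    """Per-pair summary: genomes yielding >= 1 amplicon, and (separately)
    genomes where both primers have a site regardless of productive pairing."""

    pair_name: str
    n_genomes: int
    n_matched: int
    pct_matched: float
    n_with_both_sites: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_matched <= self.n_genomes:
            raise ValueError("n_matched out of range")
        expected = round(100.0 * self.n_matched / self.n_genomes, 2)
        if abs(self.pct_matched - expected) > 1e-9:
            raise ValueError("pct_matched inconsistent with counts")


def evaluate_primer_sets(
    pairs: Sequence[PrimerPair],
    genomes: Iterable[SequenceRecord],
    max_mismatches: int = 0,
) -> tuple[list[PrimerReport], pd.DataFrame]:
    """Score each primer pair against a genome set.

    Returns reports (input pair order) and a genomes x pairs boolean matrix of
    productive matches.
    """
    genomes = list(genomes)
    if not genomes:
        raise ValueError("empty genome set")
    if not pairs:
        raise ValueError("no primer pairs given")

    matrix = pd.DataFrame(
        False, index=[g.id for g in genomes], columns=[p.name for p in pairs]
    )
    reports: list[PrimerReport] = []
    for pair in pairs:
        n_matched = 0
        n_both_sites = 0
        for g in genomes:
            hits = amplify(pair, g, max_mismatches)
            if hits:
                n_matched += 1
                matrix.loc[g.id, pair.name] = True
            if (find_primer_sites(pair.forward, g, max_mismatches)
                    and find_primer_sites(pair.reverse, g, max_mismatches)):
                n_both_sites += 1
        reports.append(PrimerReport(
            pair_name=pair.name,
            n_genomes=len(genomes),
            n_matched=n_matched,
            pct_matched=round(100.0 * n_matched / len(genomes), 2),
            n_with_both_sites=n_both_sites,
        ))
    return reports, matrix


def write_primer_report(reports: Sequence[PrimerReport], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pair_name\tn_genomes\tn_matched\tpct_matched\tn_with_both_sites\n")
        for r in reports:
            fh.write(
                f"{r.pair_name}\t{r.n_genomes}\t{r.n_matched}"
                f"\t{r.pct_matched:.2f}\t{r.n_with_both_sites}\n"
            )
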