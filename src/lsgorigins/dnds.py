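"""Nei-Gojobori (1986) pathway-counting dN/dS with Jukes-Cantor correction.

Expected synonymous/nonsynonymous site counts are averaged over both
sequences; observed differences in multi-hit codons are averaged over all
orderings of single-step mutational paths, excluding paths that pass
through a stop codon.  Proportions are corrected with
``d = -3/4 * ln(1 - 4p/3)``; the ratio is undefined (None) when dS = 0
and flagged saturated when p >= 3/4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from .model import ValidationError
from .seqs import BASES, STOP_CODONS, translate


@dataclass
class DndsResult:
    pair: tuple[str, str]
    n_codons: int
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    dN: float | None
    dS: float | None
    ratio: float | None
    saturated: bool = False


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts for one codon.

    Each position contributes the fraction of its possible single-base
    changes that are synonymous; changes creating a stop codon are
    excluded and the fraction renormalized over the remaining changes.
    """
    if codon in STOP_CODONS or len(codon) != 3:
        raise ValidationError(f"cannot count sites for codon {codon!r}")
    aa = translate(codon)
    n_sites = 0.0
    s_sites = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if translate(mutant) == aa:
                syn += 1
        if valid:
            s_frac = syn / valid
        else:
            s_frac = 0.0
        s_sites += s_frac
        n_sites += 1.0 - s_frac
    return n_sites, s_sites


@lru_cache(maxsize=None)
def _codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) differences between two codons.

    Averaged over all orderings of single-step paths that avoid stop
    codons; if every ordering passes through a stop, all orderings are
    used (the conventional fallback).
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    fallback: list[tuple[float, float]] = []
    for order in permutations(diff_positions):
        current = codon_a
        nd = sd = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if translate(current) == translate(nxt):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        fallback.append((nd, sd))
        if not through_stop:
            paths.append((nd, sd))
    use = paths if paths else fallback
    nd = sum(p[0] for p in use) / len(use)
    sd = sum(p[1] for p in use) / len(use)
    return nd, sd


def _jukes_cantor(p: float) -> tuple[float | None, bool]:
    if p >= 0.75:
        return None, True
    if p == 0.0:
        return 0.0, False
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def compute_dnds(
    seq_a: str,
    seq_b: str,
    pair: tuple[str, str] = ("a", "b"),
) -> DndsResult:
    """NG86 dN/dS for a gap-free codon-aligned coding pair.

    Codons containing a gap or ambiguity character in either sequence are
    dropped pairwise; stop codons (terminal or otherwise) are skipped.
    Symmetric in its two sequences.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValidationError("compute_dnds: sequences differ in length")
    usable = len(seq_a) - len(seq_a) % 3
    n_codons = 0
    N_sites = S_sites = 0.0
    Nd = Sd = 0.0
    for i in range(0, usable, 3):
        codon_a, codon_b = seq_a[i : i + 3], seq_b[i : i + 3]
        if set(codon_a + codon_b) - set(BASES):
            continue
        if codon_a in STOP_CODONS or codon_b in STOP_CODONS:
            continue
        n_codons += 1
        na, sa = _codon_sites(codon_a)
        nb, sb = _codon_sites(codon_b)
        N_sites += (na + nb) / 2.0
        S_sites += (sa + sb) / 2.0
        nd, sd = _codon_differences(codon_a, codon_b)
        Nd += nd
        Sd += sd
    if n_codons == 0:
        raise ValidationError("compute_dnds: no comparable codons")
    pN = Nd / N_sites if N_sites else 0.0
    pS = Sd / S_sites if S_sites else 0.0
    dN, sat_n = _jukes_cantor(pN)
    dS, sat_s = _jukes_cantor(pS)
    saturated = sat_n or sat_s
    ratio = None
    if dN is not None and dS is not None and dS > 0.0:
        ratio = dN / dS
    elif dN == 0.0 and Sd > 0.0:
        # no nonsynonymous signal at all: the ratio is zero even when the
        # synonymous proportion is beyond the Jukes-Cantor range
        ratio = 0.0
    return DndsResult(
        pair=pair,
        n_codons=n_codons,
        N_sites=N_sites,
        S_sites=S_sites,
        Nd=Nd,
        Sd=Sd,
        dN=dN,
        dS=dS,
        ratio=ratio,
        saturated=saturated,
    )
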