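"""Protein-level feature extraction.

Sequon (N-X-S/T, X != P) scanning, cysteine-spacing domain classification
(IgV-type folds carry a long intrachain-bridge spacing), residue composition,
net charge and isoelectric point (Henderson-Hasselbalch sum over termini and
ionizable side chains, ProtParam-style pKa values, bisection root), and a
Kyte-Doolittle hydropathy window scan used as a simple transmembrane-segment
stand-in for dedicated TM predictors.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping

from Bio.Seq import Seq

from .errors import (
    AlphabetError,
    ConfigError,
    EmptyInputError,
    PatternNotFoundError,
)

log = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Bjellqvist-style pKa values (as used by ProtParam-class tools).
DEFAULT_PKA: Mapping[str, float] = {
    "Nterm": 7.50,
    "Cterm": 3.55,
    "K": 10.00,
    "R": 12.00,
    "H": 5.98,
    "D": 4.05,
    "E": 4.45,
    "C": 9.00,
    "Y": 10.00,
}

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def translate(cds: str) -> str:
    """Translate a CDS with the standard code, stopping at the first stop.

    Length must be divisible by 3.  Ambiguity codons become X (logged).
    """
    s = cds.upper()
    if len(s) % 3 != 0:
        raise ConfigError(f"CDS length {len(s)} not divisible by 3")
    peptide = str(Seq(s).translate(to_stop=True))
    if "X" in peptide:
        log.info("translation contains %d ambiguous residues", peptide.count("X"))
    return peptide


@dataclass(frozen=True)
class SequonHit:
    asn_position: int  # 1-based
    triplet: str

    @property
    def valid(self) -> bool:
        return (
            self.triplet[0] == "N"
            and self.triplet[1] != "P"
            and self.triplet[2] in "ST"
        )


def scan_sequons(prot: str, include_invalid: bool = False) -> list[SequonHit]:
    """All N-glycosylation sequons N-X-S/T (X != P); overlapping hits reported.

    With ``include_invalid`` every N with two downstream residues is reported
    and flagged; by default only valid sequons are returned.
    """
    s = prot.upper()
    hits = [
        SequonHit(i + 1, s[i : i + 3])
        for i in range(len(s) - 2)
        if s[i] == "N"
    ]
    if include_invalid:
        return hits
    return [h for h in hits if h.valid]


@dataclass(frozen=True)
class CysteinePattern:
    canonical_pair: tuple[int, int]  # 1-based positions
    small_pair: tuple[int, int] | None
    igv_like: bool

    @property
    def canonical_spacing(self) -> int:
        return self.canonical_pair[1] - self.canonical_pair[0] - 1

    @property
    def small_spacing(self) -> int | None:
        if self.small_pair is None:
            return None
        return self.small_pair[1] - self.small_pair[0] - 1

    @property
    def classification(self) -> str:
        return "IgV-like" if self.igv_like else "other"


def cysteine_pattern(domain: str, igv_min_spacing: int = 55) -> CysteinePattern:
    """Canonical (outermost) cysteine bridge plus an optional nested small pair.

    The canonical pair is the first and last cysteine of the domain; a nested
    pair spaced by exactly seven residues (a hallmark of pIgR-type IgV
    domains) is reported separately.  Classification is IgV-like when the
    canonical spacing (residues strictly between) reaches ``igv_min_spacing``.
    """
    s = domain.upper()
    positions = [i + 1 for i, aa in enumerate(s) if aa == "C"]
    if len(positions) < 2:
        raise PatternNotFoundError("domain contains fewer than two cysteines")
    first, last = positions[0], positions[-1]
    small = None
    inner = [p for p in positions if first < p < last]
    for a_idx in range(len(inner)):
        for b_idx in range(a_idx + 1, len(inner)):
            if inner[b_idx] - inner[a_idx] - 1 == 7:
                small = (inner[a_idx], inner[b_idx])
                break
        if small:
            break
    spacing = last - first - 1
    return CysteinePattern((first, last), small, spacing >= igv_min_spacing)


def composition(prot: str) -> dict[str, float]:
    """Per-residue fraction of the sequence; fractions sum to 1."""
    if not prot:
        raise EmptyInputError("empty protein")
    s = prot.upper()
    counts = Counter(s)
    total = len(s)
    return {aa: counts.get(aa, 0) / total for aa in sorted(counts)}


def charge_class(residue: str, include_histidine: bool = False) -> str:
    """K/R (+ optionally H) -> positive; D/E -> negative; else neutral."""
    r = residue.upper()
    if r not in AMINO_ACIDS:
        raise AlphabetError(f"nonstandard residue {residue!r}")
    positive = "KRH" if include_histidine else "KR"
    if r in positive:
        return "positive"
    if r in "DE":
        return "negative"
    return "neutral"


def net_charge(prot: str, ph: float, pka: Mapping[str, float] = DEFAULT_PKA) -> float:
    """Henderson-Hasselbalch net charge at a given pH."""
    s = prot.upper()
    counts = Counter(s)
    pos = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    for aa in "KRH":
        pos += counts.get(aa, 0) / (1.0 + 10 ** (ph - pka[aa]))
    neg = 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in "DECY":
        neg += counts.get(aa, 0) / (1.0 + 10 ** (pka[aa] - ph))
    return pos - neg


def theoretical_pi(
    prot: str,
    pka: Mapping[str, float] = DEFAULT_PKA,
    tol: float = 1e-4,
) -> float:
    """Isoelectric point: bisection root of the net charge on pH 0..14."""
    if not prot:
        raise EmptyInputError("empty protein")
    lo, hi = 0.0, 14.0
    # net charge is monotonically decreasing in pH
    if net_charge(prot, lo, pka) < 0:
        return lo
    if net_charge(prot, hi, pka) > 0:
        return hi
    while True:
        mid = (lo + hi) / 2.0
        q = net_charge(prot, mid, pka)
        if abs(q) < tol or hi - lo < 1e-9:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid


@dataclass(frozen=True)
class TmCandidate:
    start: int  # 1-based residue coordinates, inclusive
    end: int
    peak_hydropathy: float


def hydropathy_tm_scan(
    prot: str, window: int = 19, threshold: float = 1.6
) -> list[TmCandidate]:
    """Candidate transmembrane segments from windowed mean hydropathy.

    Maximal runs of window centers whose Kyte-Doolittle mean reaches the
    threshold are reported as candidates spanning the full window extent.
    This is a deliberately simple hydropathy scanner, not a trained TM
    topology predictor.  Sequences shorter than the window yield an empty
    result (logged).
    """
    s = prot.upper()
    if len(s) < window:
        log.info("protein (%d aa) shorter than window (%d)", len(s), window)
        return []
    values = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in s]
    means = [
        sum(values[i : i + window]) / window for i in range(len(s) - window + 1)
    ]
    candidates: list[TmCandidate] = []
    i = 0
    while i < len(means):
        if means[i] >= threshold:
            j = i
            while j + 1 < len(means) and means[j + 1] >= threshold:
                j += 1
            candidates.append(
                TmCandidate(
                    start=i + 1,
                    end=min(j + window, len(s)),
                    peak_hydropathy=max(means[i : j + 1]),
                )
            )
            i = j + 1
        else:
            i += 1
    return candidates


@dataclass(frozen=True)
class ProteinRegion:
    name: str
    start: int  # 1-based inclusive
    end: int

    def extract(self, prot: str) -> str:
        if not (1 <= self.start <= self.end <= len(prot)):
            raise ConfigError(
                f"region {self.name} [{self.start},{self.end}] outside protein"
            )
        return prot[self.start - 1 : self.end]


def read_regions(source) -> list[ProteinRegion]:
    """Read region definitions from a TSV with columns name, start, end."""
    import pandas as pd

    df = pd.read_csv(source, sep="\t")
    return [
        ProteinRegion(str(r["name"]), int(r["start"]), int(r["end"]))
        for _, r in df.iterrows()
    ]
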