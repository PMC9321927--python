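"""Nucleotide-level feature statistics.

Covers base composition, CpG-island (CGI) detection with the classic
sliding-window criteria (min length 200 nt, GC >= 50%, ObsCpG/ExpCpG >= 0.6),
polyadenylation-signal (PAS) scanning, fixed-motif occurrence/tandem
scanning with a Hamming mismatch budget, and cross-clade intron-length
comparison.

ObsCpG/ExpCpG follows the Gardiner-Garden & Frommer definition:
``(number of CpG dinucleotides * length) / (number of C * number of G)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, StructureError

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Common single-substitution variants of the canonical AATAAA hexamer.
DEFAULT_PAS_VARIANTS = (
    "ATTAAA",
    "TATAAA",
    "AGTAAA",
    "AATATA",
    "AATACA",
    "CATAAA",
    "GATAAA",
    "AATGAA",
    "TTTAAA",
    "ACTAAA",
    "AATAGA",
)

#: Fraction of N above which a window is skipped by window statistics.
MAX_N_FRACTION = 0.10


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def at_content(seq: str) -> float:
    """(A+T)/(A+T+G+C); N excluded from numerator and denominator."""
    if not seq:
        raise EmptyInputError("empty sequence")
    s = seq.upper()
    at = s.count("A") + s.count("T")
    gc = s.count("G") + s.count("C")
    if at + gc == 0:
        raise EmptyInputError("sequence contains no unambiguous bases")
    return at / (at + gc)


def gc_content(seq: str) -> float:
    return 1.0 - at_content(seq)


def obs_exp_cpg(seq: str) -> float:
    """(CpG count * length) / (C count * G count); 0 when C or G absent."""
    if not seq:
        raise EmptyInputError("empty sequence")
    s = seq.upper()
    c, g = s.count("C"), s.count("G")
    if c == 0 or g == 0:
        return 0.0
    return s.count("CG") * len(s) / (c * g)


@dataclass(frozen=True)
class CpGIsland:
    start: int  # 0-based, within the query sequence
    end: int  # exclusive
    n_cpg: int
    gc_fraction: float
    obs_exp: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _window_stats(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative counts of C, G, CpG starts and N along the sequence."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = arr == ord("N")
    cpg = np.zeros(len(arr), dtype=bool)
    if len(arr) > 1:
        cpg[:-1] = is_c[:-1] & is_g[1:]
    zeros = np.zeros(1, dtype=np.int64)
    cum = lambda x: np.concatenate([zeros, np.cumsum(x, dtype=np.int64)])
    return cum(is_c), cum(is_g), cum(cpg), cum(is_n)


def _qualifies(
    cums, start: int, end: int, min_gc: float, min_obs_exp: float
) -> bool:
    cc, cg, ccpg, cn = cums
    length = end - start
    n = int(cn[end] - cn[start])
    if n > MAX_N_FRACTION * length:
        return False
    c = int(cc[end] - cc[start])
    g = int(cg[end] - cg[start])
    effective = length - n
    if effective == 0 or (c + g) / effective < min_gc:
        return False
    # CpG pairs straddling the window end are not counted inside it.
    ncpg = int(ccpg[end - 1] - ccpg[start]) if end - 1 >= start else 0
    if c == 0 or g == 0:
        return False
    return ncpg * length / (c * g) >= min_obs_exp


def detect_cgi(
    seq: str,
    min_length: int = 200,
    min_gc: float = 0.50,
    min_obs_exp: float = 0.60,
) -> list[CpGIsland]:
    """Sliding-window CpG-island detector (Takai-Jones style).

    A ``min_length`` window slides with step 1; qualifying windows
    (GC >= ``min_gc`` and ObsCpG/ExpCpG >= ``min_obs_exp``) that overlap or
    are adjacent are merged, and each merged region is trimmed to its longest
    (leftmost on ties) sub-interval that still qualifies as a whole.  Windows
    with more than 10% N are skipped.  A sequence shorter than the window
    yields an empty result.
    """
    s = seq.upper()
    if len(s) < min_length:
        log.info("sequence (%d nt) shorter than CGI window (%d nt)", len(s), min_length)
        return []
    cums = _window_stats(s)
    starts = [
        i
        for i in range(len(s) - min_length + 1)
        if _qualifies(cums, i, i + min_length, min_gc, min_obs_exp)
    ]
    islands: list[CpGIsland] = []
    i = 0
    while i < len(starts):
        j = i
        # merge windows whose intervals overlap or touch
        while j + 1 < len(starts) and starts[j + 1] - starts[j] <= min_length:
            j += 1
        region = (starts[i], starts[j] + min_length)
        trimmed = _trim_region(cums, region, min_length, min_gc, min_obs_exp)
        if trimmed is not None:
            islands.append(_island_stats(s, *trimmed))
        i = j + 1
    return islands


def _trim_region(cums, region, min_length, min_gc, min_obs_exp):
    lo, hi = region
    for length in range(hi - lo, min_length - 1, -1):
        for start in range(lo, hi - length + 1):
            if _qualifies(cums, start, start + length, min_gc, min_obs_exp):
                return start, start + length
    return None


def _island_stats(seq: str, start: int, end: int) -> CpGIsland:
    sub = seq[start:end]
    n_cpg = sub.count("CG")
    return CpGIsland(
        start=start,
        end=end,
        n_cpg=n_cpg,
        gc_fraction=gc_content(sub),
        obs_exp=obs_exp_cpg(sub),
    )


# ---------------------------------------------------------------------------
# polyadenylation signals


@dataclass(frozen=True)
class PasHit:
    position: int  # 1-based start within the query
    hexamer: str
    canonical: bool

    @property
    def pas_class(self) -> str:
        return "canonical" if self.canonical else "non-canonical"


def scan_pas(
    seq: str, variant_set: Sequence[str] = DEFAULT_PAS_VARIANTS
) -> list[PasHit]:
    """Report every AATAAA (canonical) and variant hexamer (non-canonical).

    Positions are 1-based starts on the forward strand of the query.
    """
    for hexamer in variant_set:
        if len(hexamer) != 6:
            raise ConfigError(f"PAS variant {hexamer!r} is not a hexamer")
    s = seq.upper()
    hits = []
    for i in range(len(s) - 5):
        hexamer = s[i : i + 6]
        if hexamer == "AATAAA":
            hits.append(PasHit(i + 1, hexamer, True))
        elif hexamer in variant_set:
            hits.append(PasHit(i + 1, hexamer, False))
    return hits


def pas_disruption(
    hits: Sequence[PasHit], variant_positions: Sequence[int]
) -> list[tuple[PasHit, bool]]:
    """Flag hits whose hexamer (positions p..p+5) contains a variant site."""
    out = []
    for hit in hits:
        disrupted = any(hit.position <= v <= hit.position + 5 for v in variant_positions)
        out.append((hit, disrupted))
    return out


# ---------------------------------------------------------------------------
# fixed-motif scanning


@dataclass(frozen=True)
class MotifHit:
    position: int  # 0-based start on the forward strand
    strand: str
    mismatches: int
    tandem_group: int | None = None


def _hamming_hits(seq: str, motif: str, max_mismatch: int) -> list[tuple[int, int]]:
    """(start, mismatches) of all windows within the mismatch budget."""
    s = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    m = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    if len(s) < len(m):
        return []
    windows = np.lib.stride_tricks.sliding_window_view(s, len(m))
    mism = (windows != m).sum(axis=1)
    idx = np.nonzero(mism <= max_mismatch)[0]
    return [(int(i), int(mism[i])) for i in idx]


def scan_motif(
    seq: str,
    motif: str,
    max_mismatch: int = 0,
    tandem_gap: int = 10,
) -> list[MotifHit]:
    """Hamming-distance scan of both strands for a fixed motif.

    Hits (either strand) whose starts are separated by at most
    ``len(motif) + tandem_gap`` are grouped into one tandem group; groups
    require >= 2 hits, singletons carry ``tandem_group=None``.
    """
    if max_mismatch >= len(motif):
        raise ConfigError("max_mismatch must be smaller than the motif length")
    if len(motif) > len(seq):
        raise ConfigError("motif longer than sequence")
    s, m = seq.upper(), motif.upper()
    raw = [(pos, "+", mm) for pos, mm in _hamming_hits(s, m, max_mismatch)]
    raw += [(pos, "-", mm) for pos, mm in _hamming_hits(s, revcomp(m), max_mismatch)]
    raw.sort()
    hits: list[MotifHit] = []
    group_id = 0
    i = 0
    while i < len(raw):
        j = i
        while j + 1 < len(raw) and raw[j + 1][0] - raw[j][0] <= len(m) + tandem_gap:
            j += 1
        members = raw[i : j + 1]
        gid = group_id if len(members) > 1 else None
        if gid is not None:
            group_id += 1
        hits.extend(
            MotifHit(pos, strand, mm, gid) for pos, strand, mm in members
        )
        i = j + 1
    return hits


# ---------------------------------------------------------------------------
# cross-clade intron-length comparison


@dataclass(frozen=True)
class IntronComparison:
    index: int  # 1-based intron index
    focal_min: int
    focal_max: int
    comparison_min: int
    comparison_max: int

    @property
    def elongated(self) -> bool:
        """Focal clade introns strictly longer than every comparison intron."""
        return self.focal_min > self.comparison_max


def compare_introns(
    tables: Mapping[str, Sequence[int | None]],
    groups: Mapping[str, str],
) -> list[IntronComparison]:
    """Per-index focal vs comparison intron-length ranges and elongation flags.

    ``tables`` maps species to intron lengths (5'->3'); ``groups`` maps each
    species to ``"focal"`` or ``"comparison"``.  Missing values (None/NaN)
    are skipped and logged.
    """
    counts = {len(v) for v in tables.values()}
    if len(counts) != 1:
        raise StructureError(f"unequal intron counts across species: {sorted(counts)}")
    for group in ("focal", "comparison"):
        if not any(groups.get(sp) == group for sp in tables):
            raise StructureError(f"no species in group {group!r}")
    (n_introns,) = counts
    out = []
    for idx in range(n_introns):
        by_group: dict[str, list[int]] = {"focal": [], "comparison": []}
        for sp, lengths in tables.items():
            value = lengths[idx]
            if value is None or (isinstance(value, float) and np.isnan(value)):
                log.info("species %s missing intron %d; skipped", sp, idx + 1)
                continue
            group = groups.get(sp)
            if group not in by_group:
                raise StructureError(f"species {sp!r} has unknown group {group!r}")
            by_group[group].append(int(value))
        out.append(
            IntronComparison(
                index=idx + 1,
                focal_min=min(by_group["focal"]),
                focal_max=max(by_group["focal"]),
                comparison_min=min(by_group["comparison"]),
                comparison_max=max(by_group["comparison"]),
            )
        )
    return out


def read_intron_table(source) -> tuple[dict[str, list[int]], dict[str, str]]:
    """Read a TSV with columns species, group, i1..ik (and optional extras)."""
    df = pd.read_csv(source, sep="\t")
    intron_cols = [c for c in df.columns if c.startswith("i") and c[1:].isdigit()]
    intron_cols.sort(key=lambda c: int(c[1:]))
    if not intron_cols or "species" not in df.columns or "group" not in df.columns:
        raise StructureError("intron table needs species, group and i1..ik columns")
    tables = {
        row["species"]: [int(row[c]) for c in intron_cols] for _, row in df.iterrows()
    }
    groups = {row["species"]: row["group"] for _, row in df.iterrows()}
    return tables, groups
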