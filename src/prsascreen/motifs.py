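"""Degenerate motif scanning in promoter regions, on both strands.

Bacterial regulatory sites tolerate mismatches: a CssR operator is accepted
when a window shares at least 7 of the canonical octamer's 8 bases
(canonical TTTTCACA), and a housekeeping sigma-A promoter when its -35
(TTGACA) and -10 (TATAAT) hexamers each match at least 5 of 6 bases and are
separated by a 16-18 nt spacer.  All coordinates are 0-based, half-open
forward-strand intervals; a minus-strand hit reports the forward-strand
interval it occupies.  Overlapping hits are all reported — regulatory
sites genuinely overlap (an operator can sit on top of a -35 box).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .synthetic import reverse_complement

logger = logging.getLogger(__name__)

CSSR_BOX = "TTTTCACA"
SIGMA_A_MINUS35 = "TTGACA"
SIGMA_A_MINUS10 = "TATAAT"


@dataclass(frozen=True)
class MotifModel:
    """A canonical motif plus the minimum matched-base count to report."""

    name: str
    canonical: str
    min_matches: int

    def __post_init__(self) -> None:
        if not 0 < self.min_matches <= len(self.canonical):
            raise ValueError("min_matches must lie in (0, motif length]")


@dataclass(frozen=True)
class SigmaAModel:
    """Two-box sigma-A promoter model with a mismatch budget per box."""

    minus35: str = SIGMA_A_MINUS35
    minus10: str = SIGMA_A_MINUS10
    min_matches_per_box: int = 5
    spacer_range: tuple[int, int] = (16, 18)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence.

    ``start``/``end`` delimit the occupied forward-strand interval;
    ``offset_to_anchor`` is ``start - anchor`` (negative upstream of the
    anchor) when an anchor was supplied.
    """

    motif: str
    start: int
    end: int
    strand: str
    n_matches: int
    offset_to_anchor: int | None = None


@dataclass(frozen=True)
class PromoterHit:
    """A paired -35/-10 sigma-A promoter candidate.

    ``center`` is the midpoint of the full promoter (start of -35 through
    end of -10) by default, or of the -10 box alone; ``offset_upstream`` is
    ``anchor - center`` when an anchor (e.g. the start codon) was given, so
    a promoter "centered 60 bp upstream" reports 60.
    """

    minus35: MotifHit
    minus10: MotifHit
    spacer: int
    center: float
    center_convention: str
    offset_upstream: float | None = None


def count_matches(window: str, canonical: str) -> int:
    """Identical bases between two equal-length strings (case-insensitive).

    ``N`` never counts as a match on either side.
    """
    if len(window) != len(canonical):
        raise ValueError("window and canonical must have equal length")
    return sum(
        x == y and x != "N"
        for x, y in zip(window.upper(), canonical.upper())
    )


def scan_motif(
    region: str,
    model: MotifModel,
    both_strands: bool = True,
    anchor: int | None = None,
) -> list[MotifHit]:
    """Every window matching the motif at >= min_matches positions.

    Minus-strand windows are read as the reverse complement of the
    forward-strand slice they occupy.  Hits are sorted by start, plus
    strand first.
    """
    region = region.upper()
    k = len(model.canonical)
    if k > len(region):
        logger.warning(
            "scan_motif: motif %s (%d nt) longer than region (%d nt)",
            model.name,
            k,
            len(region),
        )
        return []
    hits = []
    for i in range(len(region) - k + 1):
        window = region[i : i + k]
        n = count_matches(window, model.canonical)
        if n >= model.min_matches:
            hits.append(
                MotifHit(
                    model.name, i, i + k, "+", n,
                    None if anchor is None else i - anchor,
                )
            )
        if both_strands:
            n = count_matches(reverse_complement(window), model.canonical)
            if n >= model.min_matches:
                hits.append(
                    MotifHit(
                        model.name, i, i + k, "-", n,
                        None if anchor is None else i - anchor,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_sigma_a(
    region: str,
    model: SigmaAModel | None = None,
    anchor: int | None = None,
    center_convention: str = "promoter_midpoint",
) -> list[PromoterHit]:
    """All -35/-10 box pairs with an admissible spacer, forward strand.

    The spacer is the gap between the end of the -35 box and the start of
    the -10 box.  The promoter center is, by convention, the midpoint of
    the full -35..-10 span (``promoter_midpoint``, default) or of the -10
    box (``minus10_midpoint``); the convention used is echoed in every hit.
    """
    if model is None:
        model = SigmaAModel()
    if center_convention not in ("promoter_midpoint", "minus10_midpoint"):
        raise ValueError(f"unknown center_convention {center_convention!r}")
    m35 = MotifModel("-35", model.minus35, model.min_matches_per_box)
    m10 = MotifModel("-10", model.minus10, model.min_matches_per_box)
    hits35 = scan_motif(region, m35, both_strands=False)
    hits10 = scan_motif(region, m10, both_strands=False)
    lo, hi = model.spacer_range
    pairs = []
    for h35 in hits35:
        for h10 in hits10:
            spacer = h10.start - h35.end
            if not lo <= spacer <= hi:
                continue
            if center_convention == "promoter_midpoint":
                center = (h35.start + h10.end) / 2.0
            else:
                center = (h10.start + h10.end) / 2.0
            pairs.append(
                PromoterHit(
                    h35,
                    h10,
                    spacer,
                    center,
                    center_convention,
                    None if anchor is None else anchor - center,
                )
            )
    pairs.sort(key=lambda p: (p.minus35.start, p.minus10.start))
    return pairs


def hits_to_bed(hits: list[MotifHit], sequence_name: str) -> pd.DataFrame:
    """BED-like table: sequence, start, end, name, n_matches, strand."""
    return pd.DataFrame(
        [
            (sequence_name, h.start, h.end, h.motif, h.n_matches, h.strand)
            for h in hits
        ],
        columns=["sequence", "start", "end", "name", "n_matches", "strand"],
    )


def format_report(hits: list[MotifHit], region_name: str = "region") -> str:
    lines = [f"Motif hits in {region_name}:"]
    if not hits:
        lines.append("  (none)")
    for h in hits:
        anchor = (
            "" if h.offset_to_anchor is None else f", offset {h.offset_to_anchor:+d} to anchor"
        )
        lines.append(
            f"  {h.motif} [{h.start},{h.end}) strand {h.strand}: "
            f"{h.n_matches} matched bases{anchor}"
        )
    return "\n".join(lines)
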