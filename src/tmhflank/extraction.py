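"""Orientation and flank extraction for transmembrane helices.

Every extracted helix is placed on a common cytoplasmic ("inside", negative
positions) to non-cytoplasmic ("outside", positive positions) axis.  A helix
whose cytoplasmic domain *follows* it in the sequence is reversed, so that
the stored core and flanks always read inside -> outside.

Four flank regimes are supported:

``db_no_overlap``
    Flanks extend outward from the annotated helix boundaries, at most
    ``max_flank`` residues.  A loop of length L shared with a neighbouring
    membrane feature contributes ``floor(L/2)`` residues to each adjoining
    flank; the middle residue of an odd loop belongs to neither flank.
``db_overlap``
    Flanks extend to ``max_flank`` regardless of neighbouring flanks, but
    never into a membrane core.
``db_viable``
    As ``db_no_overlap``, keeping only helices whose flanks on *both* sides
    reach ``ceil(viable_fraction * max_flank)`` residues.
``central``
    Helices are aligned on their central residue (position 0); the segment is
    the window of positions ``-central_half_width .. +central_half_width``,
    clipped at protein termini and at the no-overlap database flank limits.

INTRAMEM features truncate flanks exactly like TRANSMEM neighbours.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from .records import ProteinRecord, RecordError

logger = logging.getLogger(__name__)

REGIMES = ("db_no_overlap", "db_overlap", "db_viable", "central")


@dataclass(frozen=True)
class FlankConfig:
    """Parameters of flank extraction.

    ``max_flank`` is the maximum flank length in residues (5, 10 or 20 are
    the usual analysis choices).  ``viable_fraction`` is the fraction of
    ``max_flank`` both flanks must reach under ``db_viable`` (default 0.5,
    i.e. viable length 5 when ``max_flank`` is 10).  Under ``central``,
    ``central_half_width`` is the half-width of the aligned window and
    ``central_core_halfwidth`` marks the positions conventionally treated as
    the standardized helix (flanks are ``-W..-w`` and ``+w..+W``).
    ``even_center`` selects the central residue of an even-length core:
    ``"lower"`` picks the earlier (cytoplasmic-side) of the two middle
    residues, ``"upper"`` the later.
    """

    max_flank: int = 10
    regime: str = "db_no_overlap"
    viable_fraction: float = 0.5
    central_half_width: int = 20
    central_core_halfwidth: int = 10
    even_center: str = "lower"

    def __post_init__(self):
        if self.max_flank <= 0:
            raise ValueError("max_flank must be positive")
        if not (0 < self.viable_fraction <= 1):
            raise ValueError("viable_fraction must be in (0, 1]")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.even_center not in ("lower", "upper"):
            raise ValueError("even_center must be 'lower' or 'upper'")

    @property
    def viable_length(self) -> int:
        return math.ceil(self.viable_fraction * self.max_flank)


def center_index(n: int, even_center: str = "lower") -> int:
    """Index of the central residue of a core of length ``n``.

    For odd ``n`` this is the true middle; for even ``n`` the ``even_center``
    convention decides between the two middle residues.
    """
    if n <= 0:
        raise ValueError("core length must be positive")
    if n % 2 == 1 or even_center == "lower":
        return (n - 1) // 2
    return n // 2


@dataclass(frozen=True)
class OrientedTMH:
    """One TMH with its flanks on the inside -> outside axis.

    ``core``, ``inside_flank`` and ``outside_flank`` all read in the same
    inside -> outside direction; for helices whose source sequence ran
    outside -> inside, all three strings are already reversed.
    """

    accession: str
    tmh_index: int
    core: str
    inside_flank: str
    outside_flank: str
    pass_class: str  # "single" | "multi"
    regime: str
    inside_truncation: str  # "full" | "truncated" | "empty"
    outside_truncation: str
    n_tmh: int = 1  # TMH count of the parent protein (for stratification)

    def center(self, even_center: str = "lower") -> int:
        return center_index(len(self.core), even_center)

    @property
    def segment(self) -> str:
        """Full inside-flank + core + outside-flank string."""
        return self.inside_flank + self.core + self.outside_flank

    def central_positions(self, even_center: str = "lower") -> Iterator[tuple[int, str]]:
        """Yield ``(position, residue)`` with the core's central residue at 0."""
        c = self.center(even_center)
        start = -c - len(self.inside_flank)
        for i, aa in enumerate(self.segment):
            yield start + i, aa

    def boundary_positions(self, side: str) -> Iterator[tuple[int, str]]:
        """Yield ``(position, residue)`` anchored at a helix boundary.

        ``side="inside"``: position 0 is the first core residue, the inside
        flank occupies -1, -2, ...; core residues run 0, 1, ...
        ``side="outside"``: position 0 is the last core residue, the outside
        flank occupies +1, +2, ...; core residues run ..., -1, 0.
        """
        if side == "inside":
            n_in = len(self.inside_flank)
            for i, aa in enumerate(self.inside_flank + self.core):
                yield i - n_in, aa
        elif side == "outside":
            n_core = len(self.core)
            for i, aa in enumerate(self.core + self.outside_flank):
                yield i - (n_core - 1), aa
        else:
            raise ValueError("side must be 'inside' or 'outside'")


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def orient_tmh(record: ProteinRecord, tmh_index: int) -> str:
    """Resolve the orientation of one TMH: ``keep``, ``reverse`` or ``omit``.

    ``keep`` if the nearest preceding topology domain carries the
    "cytoplasmic" keyword (case-insensitive); ``reverse`` if the nearest
    following domain does; ``omit`` when neither side carries the keyword.
    Both adjacent domains cytoplasmic is a record-level inconsistency.
    """
    tmhs = record.transmem_features
    if not (0 <= tmh_index < len(tmhs)):
        raise IndexError(f"{record.accession}: no TRANSMEM feature {tmh_index}")
    f = tmhs[tmh_index]
    preceding = [d for d in record.domains if d.end <= f.start]
    following = [d for d in record.domains if d.start >= f.end]
    prev = max(preceding, key=lambda d: d.end, default=None)
    nxt = min(following, key=lambda d: d.start, default=None)
    prev_cyt = prev is not None and prev.is_cytoplasmic
    next_cyt = nxt is not None and nxt.is_cytoplasmic
    if prev_cyt and next_cyt:
        raise RecordError(
            record.accession,
            f"TMH {tmh_index}: both adjacent topology domains are cytoplasmic",
        )
    if prev_cyt:
        return "keep"
    if next_cyt:
        return "reverse"
    return "omit"


def filter_tmh_length(core_len: int, min_len: int = 16, max_len: int = 38) -> bool:
    """True iff the core length lies within the inclusive limits."""
    if core_len < 1:
        raise ValueError("core length must be at least 1")
    return min_len <= core_len <= max_len


# ---------------------------------------------------------------------------
# flank extraction
# ---------------------------------------------------------------------------

def _flank_allowances(
    record: ProteinRecord, tmh_index: int, cfg: FlankConfig
) -> tuple[int, int, bool, bool]:
    """Allowed flank lengths (left, right, in sequence order) for one TMH.

    Also returns whether each side is bounded by a neighbouring membrane
    feature (as opposed to the protein terminus).
    """
    f = record.transmem_features[tmh_index]
    feats = record.membrane_features
    left_nb = max((g for g in feats if g.end <= f.start), key=lambda g: g.end, default=None)
    right_nb = min((g for g in feats if g.start >= f.end), key=lambda g: g.start, default=None)
    gap_left = f.start - (left_nb.end if left_nb else 0)
    gap_right = (right_nb.start if right_nb else len(record.sequence)) - f.end

    if cfg.regime == "db_overlap":
        left = min(cfg.max_flank, gap_left)
        right = min(cfg.max_flank, gap_right)
    else:
        # Equal truncation: the shared loop contributes floor(L/2) to each
        # adjoining flank; the middle residue of an odd loop is unassigned.
        left = min(cfg.max_flank, gap_left // 2 if left_nb else gap_left)
        right = min(cfg.max_flank, gap_right // 2 if right_nb else gap_right)
    return left, right, left_nb is not None, right_nb is not None


def _truncation_note(length: int, max_flank: int) -> str:
    if length == 0:
        return "empty"
    return "full" if length >= max_flank else "truncated"


def extract_db_flanks(
    record: ProteinRecord, tmh_index: int, cfg: FlankConfig
) -> Optional[OrientedTMH]:
    """Extract one TMH with database-boundary flanks, or None on skip/omit."""
    if cfg.regime not in ("db_no_overlap", "db_overlap", "db_viable"):
        raise ValueError(f"extract_db_flanks cannot run regime {cfg.regime!r}")
    orientation = orient_tmh(record, tmh_index)
    if orientation == "omit":
        return None
    f = record.transmem_features[tmh_index]
    left, right, _, _ = _flank_allowances(record, tmh_index, cfg)
    if cfg.regime == "db_viable" and (left < cfg.viable_length or right < cfg.viable_length):
        return None
    seq = record.sequence
    core = seq[f.start : f.end]
    left_seq = seq[f.start - left : f.start]
    right_seq = seq[f.end : f.end + right]
    if orientation == "keep":
        inside, outside = left_seq, right_seq
    else:
        core = core[::-1]
        inside, outside = right_seq[::-1], left_seq[::-1]
    return OrientedTMH(
        accession=record.accession,
        tmh_index=tmh_index,
        core=core,
        inside_flank=inside,
        outside_flank=outside,
        pass_class=record.pass_class,
        regime=cfg.regime,
        inside_truncation=_truncation_note(len(inside), cfg.max_flank),
        outside_truncation=_truncation_note(len(outside), cfg.max_flank),
        n_tmh=len(record.transmem_features),
    )


def extract_central_flanks(
    record: ProteinRecord, tmh_index: int, cfg: FlankConfig
) -> Optional[OrientedTMH]:
    """Extract one TMH as a centrally aligned window, or None on omit.

    The window spans positions ``-central_half_width..+central_half_width``
    around the core's central residue.  Flank residues beyond the no-overlap
    database flank limit (``max_flank`` residues past the helix boundary) are
    absent, as are residues beyond the protein termini.
    """
    base_cfg = replace(cfg, regime="db_no_overlap")
    seg = extract_db_flanks(record, tmh_index, base_cfg)
    if seg is None:
        return None
    c = center_index(len(seg.core), cfg.even_center)
    w = cfg.central_half_width
    keep_inside = max(0, w - c)
    keep_outside = max(0, w - (len(seg.core) - 1 - c))
    inside = seg.inside_flank[len(seg.inside_flank) - min(len(seg.inside_flank), keep_inside):]
    outside = seg.outside_flank[: min(len(seg.outside_flank), keep_outside)]
    return replace(
        seg,
        regime="central",
        inside_flank=inside,
        outside_flank=outside,
        inside_truncation=_truncation_note(len(inside), keep_inside or 1),
        outside_truncation=_truncation_note(len(outside), keep_outside or 1),
    )


def split_leaflets(core: str, odd_center: str = "exclude") -> tuple[str, str]:
    """Split an inside->outside core into inner and outer leaflet halves.

    For odd-length cores the central residue belongs to neither half by
    default (``odd_center="exclude"``); ``odd_center="inner"`` assigns it to
    the inner half instead.
    """
    n = len(core)
    h = n // 2
    if n % 2 == 1 and odd_center == "inner":
        return core[: h + 1], core[h + 1 :]
    if odd_center not in ("exclude", "inner"):
        raise ValueError("odd_center must be 'exclude' or 'inner'")
    return core[:h], core[n - h :]


# ---------------------------------------------------------------------------
# cohort-level extraction with an audit ledger
# ---------------------------------------------------------------------------

@dataclass
class ExtractionLedger:
    """Per-TMH audit trail of extraction decisions."""

    rows: list[dict] = field(default_factory=list)

    def add(self, **kwargs) -> None:
        self.rows.append(kwargs)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for row in self.rows:
            out[row["decision"]] = out.get(row["decision"], 0) + 1
        return out


def extract_cohort(
    records: Iterable[ProteinRecord],
    cfg: FlankConfig,
    min_len: int = 16,
    max_len: int = 38,
) -> tuple[list[OrientedTMH], ExtractionLedger]:
    """Extract all TMHs of a cohort under one regime, with a decision ledger.

    The length filter is applied first, then orientation, then regime
    viability.  Ledger decisions are ``kept``, ``skipped`` (length or
    viability) and ``omitted`` (no or inconsistent orientation); their sum
    equals the total TMH count.
    """
    extract = extract_central_flanks if cfg.regime == "central" else extract_db_flanks
    segments: list[OrientedTMH] = []
    ledger = ExtractionLedger()
    for record in records:
        orientations: list[str] = []
        for i, f in enumerate(record.transmem_features):
            base = dict(
                accession=record.accession,
                tmh_index=i,
                regime=cfg.regime,
                core_len=len(f),
                inside_len=0,
                outside_len=0,
                inside_truncation="",
                outside_truncation="",
            )
            if not filter_tmh_length(len(f), min_len, max_len):
                ledger.add(**{**base, "decision": "skipped", "reason": "length"})
                continue
            try:
                seg = extract(record, i, cfg)
            except RecordError:
                ledger.add(
                    **{**base, "decision": "omitted", "reason": "inconsistent_topology"}
                )
                continue
            if seg is None:
                orientation = orient_tmh(record, i)
                if orientation == "omit":
                    ledger.add(
                        **{**base, "decision": "omitted", "reason": "no_orientation"}
                    )
                else:
                    orientations.append(orientation)
                    ledger.add(
                        **{**base, "decision": "skipped", "reason": "unviable_flanks"}
                    )
                continue
            orientations.append(orient_tmh(record, i))
            segments.append(seg)
            ledger.add(
                **{
                    **base,
                    "decision": "kept",
                    "reason": "",
                    "inside_len": len(seg.inside_flank),
                    "outside_len": len(seg.outside_flank),
                    "inside_truncation": seg.inside_truncation,
                    "outside_truncation": seg.outside_truncation,
                }
            )
        for a, b in zip(orientations, orientations[1:]):
            if a == b:
                logger.warning(
                    "%s: consecutive TMHs share orientation %r; topology does "
                    "not alternate",
                    record.accession,
                    a,
                )
                break
    return segments, ledger
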