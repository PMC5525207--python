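"""Per-position count matrices and the normalized profiles derived from them.

Given a set of oriented TMH segments aligned on a common axis, this module
tallies the occurrence ``a[i, r]`` of amino-acid type ``i`` at position
``r`` and derives:

* the **absolute relative occurrence** ``p[i, r] = a[i, r] / max_r(a_r)``,
  where the denominator is the maximal number of residues in any alignment
  column (the number of sequences at full coverage) — dominated by the most
  abundant residue types;
* the **relative percentage** ``q[i, r] = 100 * a[i, r] / a_i``, where
  ``a_i`` is the total abundance of residue type ``i`` over the whole
  segment region — it answers "if this residue occurs at all, where?", and
  sums to 100 over positions;
* the per-position **net charge** ``c_r = ((a_K + a_R) - (a_D + a_E)) / N``
  with ``N`` the number of segments (+1 per K/R, -1 per D/E, all other
  residues neutral);
* windowed **hydrophobicity** curves (unweighted sliding window, partial
  windows permitted at segment ends).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .extraction import OrientedTMH
from .records import AA_INDEX, AMINO_ACIDS
from .scales import HydrophobicityScale

ANCHORS = ("central", "boundary_inside", "boundary_outside")


class UndefinedProfileError(ValueError):
    """A profile is undefined (e.g. zero total abundance of the type)."""


@dataclass
class AlignedSegmentSet:
    """Per-position residue count matrix over a set of aligned segments.

    ``counts[i, j]`` counts residues of type ``AMINO_ACIDS[i]`` at position
    ``offset + j``.  ``coverage[j]`` counts all contributing residues at that
    position, including nonstandard letters (which are tallied in coverage
    but belong to no residue-type row).
    """

    anchor: str
    offset: int
    counts: np.ndarray  # (20, R) int
    coverage: np.ndarray  # (R,) int
    n_segments: int

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.offset, self.offset + self.counts.shape[1])

    def validate(self) -> None:
        if (self.counts < 0).any() or (self.coverage < 0).any():
            raise ValueError("negative counts")
        col = self.counts.sum(axis=0)
        if (col > self.coverage).any():
            raise ValueError("column sums exceed coverage")
        if (self.coverage > self.n_segments).any():
            raise ValueError("coverage exceeds the number of segments")

    def class_counts(self, residue_class: str) -> np.ndarray:
        """Per-position counts of a residue class (e.g. ``"E"`` or ``"KR"``)."""
        rows = [AA_INDEX[aa] for aa in residue_class]
        return self.counts[rows].sum(axis=0)

    def total_counts(self) -> dict[str, int]:
        """Total abundance of each residue type over the whole region."""
        totals = self.counts.sum(axis=1)
        return {aa: int(totals[i]) for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class PositionProfile:
    """One per-position numeric curve."""

    kind: str  # "p_abs" | "q_rel" | "net_charge" | "hydrophobicity"
    residue_class: Optional[str]
    positions: np.ndarray
    values: np.ndarray
    units: str
    n_segments: int = 0

    def value_at(self, position: int) -> float:
        idx = np.flatnonzero(self.positions == position)
        if idx.size == 0:
            raise KeyError(f"position {position} not covered by this profile")
        return float(self.values[idx[0]])

    def window_mean(self, lo: int, hi: int) -> float:
        """Unweighted mean over the inclusive position window ``lo..hi``."""
        mask = (self.positions >= lo) & (self.positions <= hi)
        if not mask.any():
            raise UndefinedProfileError(
                f"profile does not cover positions {lo}..{hi}"
            )
        return float(self.values[mask].mean())


def _segment_positions(
    seg: OrientedTMH,
    anchor: str,
    even_center: str,
    include: Sequence[str],
):
    if anchor == "central":
        pairs = seg.central_positions(even_center)
        n_in, n_core = len(seg.inside_flank), len(seg.core)
        parts = (
            ["inside"] * n_in + ["core"] * n_core + ["outside"] * len(seg.outside_flank)
        )
    elif anchor == "boundary_inside":
        pairs = seg.boundary_positions("inside")
        parts = ["inside"] * len(seg.inside_flank) + ["core"] * len(seg.core)
    elif anchor == "boundary_outside":
        pairs = seg.boundary_positions("outside")
        parts = ["core"] * len(seg.core) + ["outside"] * len(seg.outside_flank)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    for (pos, aa), part in zip(pairs, parts):
        if part in include:
            yield pos, aa


def count_occurrences(
    segments: Sequence[OrientedTMH],
    anchor: str = "central",
    even_center: str = "lower",
    include: Sequence[str] = ("inside", "core", "outside"),
    strict: bool = False,
) -> AlignedSegmentSet:
    """Tally residue occurrences over a set of aligned segments.

    Positions absent in a segment (truncated flanks) contribute nothing.
    Nonstandard residue letters count toward coverage only, unless ``strict``
    (then they raise).
    """
    segments = list(segments)
    if not segments:
        raise ValueError("cannot count occurrences of an empty segment list")
    lo = min(p for s in segments for p, _ in _segment_positions(s, anchor, even_center, include))
    hi = max(p for s in segments for p, _ in _segment_positions(s, anchor, even_center, include))
    width = hi - lo + 1
    counts = np.zeros((len(AMINO_ACIDS), width), dtype=np.int64)
    coverage = np.zeros(width, dtype=np.int64)
    for seg in segments:
        for pos, aa in _segment_positions(seg, anchor, even_center, include):
            j = pos - lo
            coverage[j] += 1
            idx = AA_INDEX.get(aa)
            if idx is None:
                if strict:
                    raise ValueError(
                        f"{seg.accession} TMH {seg.tmh_index}: nonstandard "
                        f"residue {aa!r} in strict mode"
                    )
                continue
            counts[idx, j] += 1
    out = AlignedSegmentSet(anchor, lo, counts, coverage, len(segments))
    out.validate()
    return out


def absolute_relative_occurrence(
    s: AlignedSegmentSet, residue_class: str
) -> PositionProfile:
    """Eq.-1-style normalization: per-position count over the maximal column
    total (the alignment depth), as a fraction in [0, 1]."""
    denom = int(s.coverage.max())
    if denom == 0:
        raise UndefinedProfileError("zero coverage everywhere")
    mask = s.coverage > 0
    values = s.class_counts(residue_class)[mask] / denom
    return PositionProfile(
        "p_abs", residue_class, s.positions[mask], values, "fraction", s.n_segments
    )


def relative_percentage(s: AlignedSegmentSet, residue_class: str) -> PositionProfile:
    """Eq.-2-style normalization: per-position count as a percentage of the
    total abundance of that residue class over the whole segment region.

    The values sum to 100 over positions.  Raises
    :class:`UndefinedProfileError` when the class never occurs (the curve is
    undefined, not zero).
    """
    a = s.class_counts(residue_class)
    a_i = int(a.sum())
    if a_i == 0:
        raise UndefinedProfileError(
            f"residue class {residue_class!r} absent from the segment region"
        )
    mask = s.coverage > 0
    values = 100.0 * a[mask] / a_i
    return PositionProfile(
        "q_rel", residue_class, s.positions[mask], values, "percent", s.n_segments
    )


def background_level(
    profile: PositionProfile,
    windows: tuple[tuple[int, int], tuple[int, int]] = ((-30, -25), (25, 30)),
) -> float:
    """Background estimate: unweighted mean over the two distal windows
    (inclusive; by default positions -30..-25 and 25..30)."""
    positions = []
    for lo, hi in windows:
        positions.extend(range(lo, hi + 1))
    try:
        vals = [profile.value_at(p) for p in positions]
    except KeyError as err:
        raise UndefinedProfileError(
            f"profile span too small for background windows {windows}"
        ) from err
    return float(np.mean(vals))


def flank_average(
    profile: PositionProfile,
    inside: tuple[int, int] = (-20, -10),
    outside: tuple[int, int] = (10, 20),
) -> tuple[float, float]:
    """Inclusive unweighted means over the inside and outside flank windows
    (11 positions each by default)."""
    return profile.window_mean(*inside), profile.window_mean(*outside)


def net_charge_profile(s: AlignedSegmentSet) -> PositionProfile:
    """Per-position mean net charge: (K+R counts minus D+E counts) / N."""
    if s.n_segments <= 0:
        raise ValueError("need at least one segment")
    charge = (s.class_counts("KR") - s.class_counts("DE")) / s.n_segments
    mask = s.coverage > 0
    return PositionProfile(
        "net_charge", "KR-DE", s.positions[mask], charge[mask],
        "charge per helix", s.n_segments,
    )


# ---------------------------------------------------------------------------
# hydrophobicity
# ---------------------------------------------------------------------------

def windowed_hydropathy(
    sequence: str,
    scale: HydrophobicityScale,
    window: int = 3,
    strict: bool = False,
) -> np.ndarray:
    """Sliding unweighted window means of scale values along a sequence.

    The window is centred on each residue and clipped at the sequence ends
    (partial windows are averaged over the residues available).  Unknown
    residues raise in strict mode and are excluded from the window mean
    otherwise; a window with no known residue yields NaN.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    half = window // 2
    values = np.full(len(sequence), np.nan)
    known = np.zeros(len(sequence), dtype=bool)
    for i, aa in enumerate(sequence):
        if aa in scale:
            values[i] = scale[aa]
            known[i] = True
        elif strict:
            raise ValueError(f"unknown residue {aa!r} in strict mode")
    out = np.full(len(sequence), np.nan)
    for i in range(len(sequence)):
        lo, hi = max(0, i - half), min(len(sequence), i + half + 1)
        vals = values[lo:hi][known[lo:hi]]
        if vals.size:
            out[i] = vals.mean()
    return out


@dataclass
class HydrophobicityProfile:
    """Mean windowed hydrophobicity per position, plus the raw per-segment
    windowed values at each position (needed for per-position tests)."""

    scale: str
    window: int
    positions: np.ndarray
    mean: np.ndarray
    values_by_position: dict[int, list[float]] = field(default_factory=dict)
    n_segments: int = 0

    def as_profile(self) -> PositionProfile:
        return PositionProfile(
            "hydrophobicity", None, self.positions, self.mean,
            f"{self.scale} units", self.n_segments,
        )


def hydrophobicity_profile(
    segments: Sequence[OrientedTMH],
    scale: HydrophobicityScale,
    window: int = 3,
    even_center: str = "lower",
    strict: bool = False,
) -> HydrophobicityProfile:
    """Windowed hydrophobicity averaged over segments at each central-
    alignment position.

    The window runs end to end over each segment slice (inside flank + core
    + outside flank), so flank residues inform core-edge windows and vice
    versa.  Stratification (e.g. by TMH-count class) is done by the caller
    by passing the relevant subset of segments.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("cannot profile an empty segment list")
    by_pos: dict[int, list[float]] = {}
    for seg in segments:
        vals = windowed_hydropathy(seg.segment, scale, window, strict=strict)
        c = seg.center(even_center)
        start = -c - len(seg.inside_flank)
        for i, v in enumerate(vals):
            if not np.isnan(v):
                by_pos.setdefault(start + i, []).append(float(v))
    positions = np.array(sorted(by_pos))
    mean = np.array([np.mean(by_pos[p]) for p in positions])
    return HydrophobicityProfile(
        scale.name, window, positions, mean, by_pos, len(segments)
    )


# ---------------------------------------------------------------------------
# small helpers and exports
# ---------------------------------------------------------------------------

def residue_percentage(count: int, total: int) -> float:
    """A residue-class count as a percentage of a residue total."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * count / total


def profiles_frame(profiles: Iterable[PositionProfile], **labels) -> pd.DataFrame:
    """Long-format table of profiles (directly plottable / writable as TSV)."""
    rows = []
    for prof in profiles:
        for pos, val in zip(prof.positions, prof.values):
            rows.append(
                {
                    **labels,
                    "kind": prof.kind,
                    "residue_class": prof.residue_class or "",
                    "position": int(pos),
                    "value": float(val),
                    "n_segments": prof.n_segments,
                }
            )
    return pd.DataFrame(rows)


def heatmap_matrix(s: AlignedSegmentSet, kind: str = "q_rel") -> pd.DataFrame:
    """Residue-by-position matrix of p or q values (heatmap-shaped export).

    Residue types with zero abundance yield all-NaN rows under ``q_rel``
    (their curve is undefined).
    """
    data = {}
    for aa in AMINO_ACIDS:
        try:
            prof = (
                relative_percentage(s, aa)
                if kind == "q_rel"
                else absolute_relative_occurrence(s, aa)
            )
            data[aa] = pd.Series(prof.values, index=prof.positions)
        except UndefinedProfileError:
            data[aa] = pd.Series(dtype=float)
    frame = pd.DataFrame(data).T
    frame.index.name = "residue"
    frame.columns.name = "position"
    return frame
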