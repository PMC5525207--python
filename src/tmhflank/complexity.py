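"""Simple / twilight / complex classification of TMH cores.

A TMH that is merely a hydrophobic membrane anchor tends to be strongly
hydrophobic and of low sequence complexity; helices with structural or
functional roles beyond anchorage tend to be more polar and more complex.
This module scores a core by its mean hydrophobicity and Shannon entropy
and applies a configurable linear decision rule with a twilight band.

The boundary shipped here is a documented approximation chosen for this
package: the classifier is a pluggable interface, and externally produced
three-way calls can be imported from TSV instead
(:func:`read_complexity_calls`).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np

from .records import AMINO_ACIDS
from .scales import HydrophobicityScale, get_scale

CALLS = ("simple", "twilight", "complex")


@dataclass(frozen=True)
class ComplexityBoundary:
    """Linear decision rule in the (mean hydrophobicity, entropy) plane.

    The score is ``meanH - entropy_weight * (entropy - entropy_ref)``:
    ``simple`` at or above ``simple_min``, ``complex`` at or below
    ``complex_max`` and ``twilight`` in between.
    """

    entropy_weight: float = 0.5
    entropy_ref: float = 2.0
    simple_min: float = 1.0
    complex_max: float = 0.0

    def __post_init__(self):
        if self.complex_max > self.simple_min:
            raise ValueError("complex_max must not exceed simple_min")

    def score(self, mean_hydrophobicity: float, entropy: float) -> float:
        return mean_hydrophobicity - self.entropy_weight * (entropy - self.entropy_ref)


DEFAULT_BOUNDARY = ComplexityBoundary()


@dataclass(frozen=True)
class ComplexityCall:
    mean_hydrophobicity: float
    shannon_entropy: float
    call: str
    boundary: ComplexityBoundary


def sequence_entropy(core: str) -> float:
    """Shannon entropy (bits) of the residue-type frequency distribution.

    Nonstandard letters are excluded from the frequency counts.
    """
    counts = np.array([core.count(aa) for aa in AMINO_ACIDS], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("core has no standard residues")
    freqs = counts[counts > 0] / total
    return float(-(freqs * np.log2(freqs)).sum())


def classify_from_features(
    mean_hydrophobicity: float,
    entropy: float,
    boundary: ComplexityBoundary = DEFAULT_BOUNDARY,
) -> str:
    s = boundary.score(mean_hydrophobicity, entropy)
    if s >= boundary.simple_min:
        return "simple"
    if s <= boundary.complex_max:
        return "complex"
    return "twilight"


def classify_complexity(
    core: str,
    scale: Optional[HydrophobicityScale] = None,
    boundary: ComplexityBoundary = DEFAULT_BOUNDARY,
) -> ComplexityCall:
    """Classify one TMH core as simple, twilight or complex.

    Both features are order-free, so the call is invariant under core
    reversal.  The entropy of the 20-type distribution is bounded by
    ``log2(20)`` bits.
    """
    if not core:
        raise ValueError("empty core")
    scale = scale or get_scale("kyte_doolittle")
    vals = [scale[aa] for aa in core if aa in scale]
    if not vals:
        raise ValueError("core has no standard residues")
    mean_h = float(np.mean(vals))
    entropy = sequence_entropy(core)
    assert 0.0 <= entropy <= log2(20) + 1e-12
    return ComplexityCall(
        mean_h, entropy, classify_from_features(mean_h, entropy, boundary), boundary
    )


# ---------------------------------------------------------------------------
# import/export of per-TMH calls
# ---------------------------------------------------------------------------

def write_complexity_calls(
    calls: Iterable[tuple[str, int, str]], path: Union[str, Path]
) -> None:
    """Write (accession, tmh_index, call) triples as TSV."""
    lines = ["accession\ttmh_index\tcall"]
    for accession, tmh_index, call in calls:
        if call not in CALLS:
            raise ValueError(f"unknown complexity call {call!r}")
        lines.append(f"{accession}\t{tmh_index}\t{call}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_complexity_calls(path: Union[str, Path]) -> dict[tuple[str, int], str]:
    """Read externally produced calls keyed by (accession, tmh_index)."""
    out: dict[tuple[str, int], str] = {}
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["accession", "tmh_index", "call"]:
        raise ValueError("complexity call table must have the documented header")
    for line in lines[1:]:
        if not line.strip():
            continue
        accession, idx, call = line.split("\t")
        if call not in CALLS:
            raise ValueError(f"unknown complexity call {call!r}")
        out[(accession, int(idx))] = call
    return out
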