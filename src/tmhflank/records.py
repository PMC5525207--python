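"""Core domain types: annotated protein records with membrane topology.

All coordinates held by these types are 0-based half-open.  The on-disk
formats (flat file, segment table) use 1-based inclusive coordinates and are
converted at the I/O boundary by :mod:`tmhflank.annotation_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 20 standard amino acids, one-letter codes, fixed order used for all
#: count matrices in this package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Letters that may appear in database sequences but carry no single
#: amino-acid identity (ambiguity codes and rare translated residues).
#: They contribute to position coverage but never to a residue-type count.
NONSTANDARD = set("BZXUO")

POSITIVE = "KR"
NEGATIVE = "DE"


class RecordError(ValueError):
    """A protein record failed validation; carries the accession."""

    def __init__(self, accession: str, message: str):
        super().__init__(f"{accession}: {message}")
        self.accession = accession


@dataclass(frozen=True)
class MembraneFeature:
    """A membrane-embedded feature (TRANSMEM helix or INTRAMEM segment)."""

    kind: str  # "TRANSMEM" | "INTRAMEM"
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __post_init__(self):
        if self.kind not in ("TRANSMEM", "INTRAMEM"):
            raise ValueError(f"unknown membrane feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad feature span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TopologyDomain:
    """A non-membrane topological domain (e.g. Cytoplasmic, Extracellular)."""

    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad domain span [{self.start}, {self.end})")

    @property
    def is_cytoplasmic(self) -> bool:
        # Orientation hinges on this single case-insensitive keyword match.
        return "cytoplasmic" in self.label.lower()


@dataclass
class ProteinRecord:
    """One annotated sequence with membrane features and topology domains."""

    accession: str
    sequence: str
    features: list[MembraneFeature] = field(default_factory=list)
    domains: list[TopologyDomain] = field(default_factory=list)
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self, strict: bool = False) -> None:
        """Check coordinate sanity; raise :class:`RecordError` on failure.

        In strict mode, nonstandard residue letters are also rejected.
        """
        n = len(self.sequence)
        if n == 0:
            raise RecordError(self.accession, "empty sequence")
        for f in self.features:
            if f.end > n:
                raise RecordError(
                    self.accession,
                    f"{f.kind} feature [{f.start}, {f.end}) exceeds sequence "
                    f"length {n}",
                )
        spans = sorted((f.start, f.end) for f in self.features)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise RecordError(
                    self.accession,
                    f"overlapping membrane features [{s1},{e1}) and [{s2},{e2})",
                )
        for d in self.domains:
            if d.end > n:
                raise RecordError(
                    self.accession,
                    f"domain [{d.start}, {d.end}) exceeds sequence length {n}",
                )
            for f in self.features:
                if d.start < f.end and f.start < d.end:
                    raise RecordError(
                        self.accession,
                        f"domain [{d.start},{d.end}) overlaps membrane "
                        f"feature [{f.start},{f.end})",
                    )
        if strict:
            bad = set(self.sequence) - set(AMINO_ACIDS)
            if bad:
                raise RecordError(
                    self.accession,
                    f"nonstandard residue letters {sorted(bad)} (strict mode)",
                )

    @property
    def transmem_features(self) -> list[MembraneFeature]:
        """TRANSMEM features only, in sequence order."""
        return sorted(
            (f for f in self.features if f.kind == "TRANSMEM"),
            key=lambda f: f.start,
        )

    @property
    def membrane_features(self) -> list[MembraneFeature]:
        """TRANSMEM and INTRAMEM features, in sequence order."""
        return sorted(self.features, key=lambda f: f.start)

    @property
    def pass_class(self) -> str:
        """``"single"`` iff the record has exactly one TRANSMEM feature."""
        return "single" if len(self.transmem_features) == 1 else "multi"

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProteinRecord):
            return NotImplemented
        return (
            self.accession == other.accession
            and self.sequence == other.sequence
            and sorted(self.features, key=lambda f: (f.start, f.kind))
            == sorted(other.features, key=lambda f: (f.start, f.kind))
            and sorted(self.domains, key=lambda d: d.start)
            == sorted(other.domains, key=lambda d: d.start)
            and self.meta == other.meta
        )
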