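"""Hydrophobicity scales, shipped as a versioned data table."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .records import AMINO_ACIDS

SCALE_NAMES = (
    "kyte_doolittle",
    "white_wimley_octanol",
    "hessa_biological",
    "eisenberg_consensus",
)


@dataclass(frozen=True)
class HydrophobicityScale:
    name: str
    mapping: tuple  # value per residue in AMINO_ACIDS order

    def __post_init__(self):
        if len(self.mapping) != len(AMINO_ACIDS):
            raise ValueError("scale must define all 20 standard residues")

    def __getitem__(self, residue: str) -> float:
        return self.mapping[AMINO_ACIDS.index(residue)]

    def __contains__(self, residue: str) -> bool:
        return residue in AMINO_ACIDS


def _load_table() -> dict[str, HydrophobicityScale]:
    text = (
        resources.files("tmhflank").joinpath("data/hydrophobicity_scales.tsv")
    ).read_text()
    rows = [
        line.split("\t")
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    header = rows[0]
    values = {row[0]: row[1:] for row in rows[1:]}
    scales = {}
    for j, name in enumerate(header[1:]):
        mapping = tuple(float(values[aa][j]) for aa in AMINO_ACIDS)
        scales[name] = HydrophobicityScale(name, mapping)
    return scales


_SCALES = _load_table()


def get_scale(name: str) -> HydrophobicityScale:
    """Look up a shipped hydrophobicity scale by name."""
    try:
        return _SCALES[name]
    except KeyError:
        raise KeyError(f"unknown scale {name!r}; available: {SCALE_NAMES}") from None
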