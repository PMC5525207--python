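"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import pytest

from tmhflank import MembraneFeature, ProteinRecord, TopologyDomain


def make_record(
    accession="P00001",
    inside_loop="KKKKKRRRRR",
    core="LLLLLLLLLLILLLLLLLLL",  # 20 residues
    outside_loop="DDDDDEEEEE",
    n_term_inside=True,
    inside_label="Cytoplasmic",
    outside_label="Extracellular",
):
    """Single-pass record: loop | core | loop, with labelled domains."""
    if n_term_inside:
        first, second = inside_loop, outside_loop
        first_label, second_label = inside_label, outside_label
    else:
        first, second = outside_loop, inside_loop
        first_label, second_label = outside_label, inside_label
    seq = first + core + second
    s = len(first)
    features = [MembraneFeature("TRANSMEM", s, s + len(core))]
    domains = []
    if first:
        domains.append(TopologyDomain(0, s, first_label))
    if second:
        domains.append(TopologyDomain(s + len(core), len(seq), second_label))
    return ProteinRecord(accession, seq, features, domains)


def make_multipass(
    accession="P00002",
    cores=("L" * 20, "V" * 21, "I" * 20),
    loops=("K" * 8, "D" * 7),
    n_tail="M" * 12,
    c_tail="S" * 12,
    n_term_inside=True,
    label_gaps=True,
):
    """Multi-pass record with alternating topology domains."""
    gap_seqs = [n_tail] + list(loops) + [c_tail]
    seq = ""
    features = []
    domains = []
    side_inside = n_term_inside
    pos = 0
    for k in range(len(cores) + 1):
        gap = gap_seqs[k]
        if gap:
            if label_gaps:
                label = "Cytoplasmic" if side_inside else "Extracellular"
                domains.append(TopologyDomain(pos, pos + len(gap), label))
            seq += gap
            pos += len(gap)
        if k < len(cores):
            core = cores[k]
            features.append(MembraneFeature("TRANSMEM", pos, pos + len(core)))
            seq += core
            pos += len(core)
            side_inside = not side_inside
    return ProteinRecord(accession, seq, features, domains)


@pytest.fixture
def single_pass_record():
    return make_record()


@pytest.fixture
def reversed_record():
    """Cytoplasmic side AFTER the helix: must be reversed on extraction."""
    return make_record(accession="P00003", n_term_inside=False)
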