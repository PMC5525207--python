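"""The two profile normalizations on a hand-built aligned segment set.

Positional residue counts can be normalized two ways, and they answer
different questions.  The absolute relative occurrence divides the count of
residue type i at aligned position r by the alignment depth: it tells you
how common the residue is at that position, and is dominated by abundant
types.  The relative percentage divides by the total abundance of type i
over the whole region: it tells you where the residue sits *given that it
occurs*, sums to 100 over positions, and makes rare residues visible.

Here we rebuild the classic worked example: 1705 aligned helices with 91
glutamates at position +12 (the outside flank), 22 at -12 (the inside
flank) and 615 glutamates in total.
"""

from tmhflank import (
    OrientedTMH,
    absolute_relative_occurrence,
    count_occurrences,
    relative_percentage,
)

segments = []
for i in range(1705):
    core = ["L"] * 25  # 25 residues align to central positions -12..+12
    if i < 91:
        core[24] = "E"  # position +12
    if i < 22:
        core[0] = "E"  # position -12
    if i < 502:
        core[12] = "E"  # position 0, bringing the total to 615
    segments.append(
        OrientedTMH(
            accession=f"S{i:04d}", tmh_index=0, core="".join(core),
            inside_flank="", outside_flank="", pass_class="single",
            regime="central", inside_truncation="empty",
            outside_truncation="empty",
        )
    )

counts = count_occurrences(segments, anchor="central")
print(f"aligned segments : {counts.n_segments}")
print(f"glutamates total : {counts.total_counts()['E']}")

p = absolute_relative_occurrence(counts, "E")
q = relative_percentage(counts, "E")
for pos in (+12, -12):
    print(
        f"position {pos:+3d}: absolute relative occurrence = "
        f"{p.value_at(pos):.3f}, relative percentage (fraction) = "
        f"{q.value_at(pos) / 100:.3f}"
    )

# The relative percentage always sums to 100 over the region:
print(f"sum of q over positions: {q.values.sum():.1f}")
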