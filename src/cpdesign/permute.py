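"""Construction of circular-permutant sequences.

A circular permutant joins the parent's original N- and C-termini through a
short linker (Gly-Gly-Gly by default — flexible and sterically undemanding)
and opens the chain at a new position.  The cut convention here places the
cut immediately N-terminal to ``new_start``, so the chosen residue (a loop
glycine, for designs produced by :mod:`cpdesign.sites`) becomes the new
N-terminus:

    permutant = parent[new_start .. last] + linker + parent[first .. new_start-1]

The permutant is numbered 1..len from its own N-terminus; bidirectional
coordinate maps between parent (author) numbering and permutant numbering
are kept so structural annotations can be carried across.  Linker residues
exist only in the permutant and map to nothing in the parent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_records import STANDARD_AA, SequenceRecord
from .sites import CleavageSite


@dataclass(frozen=True)
class PermutantDesign:
    """A circular permutant with bidirectional coordinate maps."""

    name: str
    parent_id: str
    new_start: int
    linker: str
    sequence: str
    wt_to_cp: dict[int, int]
    cp_to_wt: dict[int, int | None]

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def linker_positions(self) -> list[int]:
        """Permutant positions occupied by the linker."""
        return [p for p, wt in self.cp_to_wt.items() if wt is None]

    def to_record(self) -> SequenceRecord:
        """The permutant as a 1-numbered sequence record."""
        return SequenceRecord(id=self.name, residues=self.sequence, first_number=1)


def build_permutant(
    record: SequenceRecord,
    new_start: int,
    linker: str = "GGG",
    name: str | None = None,
) -> PermutantDesign:
    """Build the circular permutant whose new N-terminus is ``new_start``.

    ``new_start`` is in the parent's author numbering and must lie strictly
    inside the chain: cutting at the origin would reproduce the parent (plus
    a dangling linker), which is rejected as a degenerate design.  The linker
    may be empty (a pure rotation of the circularized chain).
    """
    if new_start == record.first_number:
        raise ValueError(
            "cut at origin produces the identity permutant; choose "
            f"new_start in {record.first_number + 1}..{record.last_number}"
        )
    if not record.first_number < new_start <= record.last_number:
        raise ValueError(
            f"new_start {new_start} out of range "
            f"({record.first_number + 1}..{record.last_number})"
        )
    bad = set(linker) - STANDARD_AA
    if bad:
        raise ValueError(
            f"linker {linker!r} contains non-standard residue(s): "
            f"{', '.join(sorted(bad))}"
        )

    c_fragment = [
        (pos, record.residue_at(pos))
        for pos in range(new_start, record.last_number + 1)
    ]
    n_fragment = [
        (pos, record.residue_at(pos))
        for pos in range(record.first_number, new_start)
    ]

    sequence_parts: list[str] = []
    wt_to_cp: dict[int, int] = {}
    cp_to_wt: dict[int, int | None] = {}
    cp_pos = 0
    for wt_pos, aa in c_fragment:
        cp_pos += 1
        sequence_parts.append(aa)
        wt_to_cp[wt_pos] = cp_pos
        cp_to_wt[cp_pos] = wt_pos
    for aa in linker:
        cp_pos += 1
        sequence_parts.append(aa)
        cp_to_wt[cp_pos] = None
    for wt_pos, aa in n_fragment:
        cp_pos += 1
        sequence_parts.append(aa)
        wt_to_cp[wt_pos] = cp_pos
        cp_to_wt[cp_pos] = wt_pos

    return PermutantDesign(
        name=name if name is not None else f"cp{new_start}",
        parent_id=record.id,
        new_start=new_start,
        linker=linker,
        sequence="".join(sequence_parts),
        wt_to_cp=wt_to_cp,
        cp_to_wt=cp_to_wt,
    )


def build_from_sites(
    record: SequenceRecord,
    sites: list[CleavageSite],
    linker: str = "GGG",
    offsets: dict[int, int] | None = None,
) -> list[PermutantDesign]:
    """One permutant per selected cleavage site, named ``cp<site position>``.

    ``offsets`` optionally shifts a site's actual cut point (``new_start =
    position + offset``) while keeping the site-derived name — the escape
    hatch for constructs whose fragment boundary sits a residue or two off
    the annotated glycine.
    """
    offsets = offsets or {}
    designs = []
    for site in sites:
        if site.status != "selected":
            continue
        new_start = site.position + offsets.get(site.position, 0)
        designs.append(
            build_permutant(record, new_start, linker, name=f"cp{site.position}")
        )
    return designs


def map_wt_to_cp(design: PermutantDesign, position: int) -> int:
    """Parent (author) residue number -> permutant position."""
    try:
        return design.wt_to_cp[position]
    except KeyError:
        raise IndexError(
            f"parent position {position} not in design {design.name!r}"
        ) from None


def map_cp_to_wt(design: PermutantDesign, position: int) -> int | None:
    """Permutant position -> parent residue number, or None on the linker."""
    try:
        return design.cp_to_wt[position]
    except KeyError:
        raise IndexError(
            f"permutant position {position} out of range 1..{len(design)}"
        ) from None


def design_manifest(designs: list[PermutantDesign]) -> str:
    """TSV manifest: name, parent, new_start, fragment boundaries, length."""
    lines = [
        "name\tparent\tnew_start\tc_fragment\tn_fragment\tlinker\tlength"
    ]
    for d in designs:
        wt_positions = [p for p in d.cp_to_wt.values() if p is not None]
        last = max(wt_positions)
        first = min(wt_positions)
        lines.append(
            f"{d.name}\t{d.parent_id}\t{d.new_start}\t"
            f"{d.new_start}-{last}\t{first}-{d.new_start - 1}\t"
            f"{d.linker}\t{len(d)}"
        )
    return "\n".join(lines) + "\n"
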