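"""Cleavage-site selection for circular permutation.

The strategy: a circular permutant's new termini should fall on a loop
glycine, away from the original chain ends, at a position whose intrinsic
disorder score — read from the *circular* profile — predicts how much the cut
will destabilize the fold.  Low disorder at the cut means the region is well
stabilized by intra-protein contacts, so opening the chain there costs
little; high disorder marks a weakly stabilized region where new, freely
fluctuating termini shed contacts and gain configurational entropy.

The selector inventories every glycine and applies three filters in order:

1. *loop filter* — the glycine must sit in a loop (3-state class L), so no
   regular secondary-structure element is cut;
2. *terminal exclusion* — glycines within ``terminal_margin`` residues of
   either original terminus are dropped (permuting next to the existing ends
   is pointless);
3. *proximity de-duplication* — within any cluster of surviving glycines
   closer than ``min_separation`` residues, a single representative is kept.

Every glycine is returned with a status and, if rejected, the first filter
that removed it, so selections are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .disorder import DisorderProfile, score_at
from .seq_records import SequenceRecord

#: DSSP 8-class to 3-class reduction: helices to H, strands/bridges to E,
#: everything else (turn, bend, coil) to L.
DSSP_TO_3 = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E",
    "T": "L", "S": "L", "-": "L", " ": "L", "C": "L", "P": "L",
}


@dataclass(frozen=True)
class SecondaryStructure:
    """Per-residue 3-state secondary structure (H helix, E strand, L loop)."""

    positions: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=int)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "classes", tuple(self.classes))
        if positions.size != len(self.classes) or positions.size == 0:
            raise ValueError("positions and classes must be non-empty and equal length")
        if positions.size > 1 and not np.all(np.diff(positions) == 1):
            raise ValueError("positions must be contiguous (step 1)")
        bad = set(self.classes) - {"H", "E", "L"}
        if bad:
            raise ValueError(f"secondary-structure classes must be H/E/L, got {bad}")

    @property
    def first_number(self) -> int:
        return int(self.positions[0])

    @property
    def last_number(self) -> int:
        return int(self.positions[-1])

    def class_of(self, position: int) -> str:
        if not self.first_number <= position <= self.last_number:
            raise KeyError(f"position {position} not covered by secondary structure")
        return self.classes[position - self.first_number]

    @classmethod
    def from_string(cls, hel: str, first_number: int = 1) -> "SecondaryStructure":
        """Build from a plain per-residue H/E/L string."""
        return cls(
            positions=np.arange(first_number, first_number + len(hel)),
            classes=tuple(hel.upper()),
        )

    @classmethod
    def from_dssp(cls, path: str | Path, chain: str | None = None) -> "SecondaryStructure":
        """Read a classic DSSP output file, reduced to 3 classes.

        Parses the fixed-width data block following the ``#  RESIDUE`` header
        line; chain breaks (``!`` rows) end the parsed run.  A simple
        whitespace table ``resnum chain aa class`` is also accepted.
        """
        lines = Path(path).read_text().splitlines()
        positions: list[int] = []
        classes: list[str] = []
        header_idx = next(
            (i for i, ln in enumerate(lines) if ln.lstrip().startswith("#  RESIDUE")),
            None,
        )
        if header_idx is not None:
            for line in lines[header_idx + 1 :]:
                if len(line) < 17 or line[13] == "!":
                    continue
                if chain is not None and line[11].strip() != chain:
                    continue
                positions.append(int(line[5:10]))
                classes.append(DSSP_TO_3.get(line[16], "L"))
        else:
            for line in lines:
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                if len(parts) < 4:
                    raise ValueError(
                        f"{path}: expected 'resnum chain aa class' columns, got {line!r}"
                    )
                if chain is not None and parts[1] != chain:
                    continue
                positions.append(int(parts[0]))
                classes.append(DSSP_TO_3.get(parts[3].upper(), "L"))
        if not positions:
            raise ValueError(f"{path}: no residues parsed")
        return cls(positions=np.array(positions), classes=tuple(classes))


@dataclass(frozen=True)
class CleavageSite:
    """One candidate permutation point with its filter provenance."""

    position: int
    residue: str
    disorder_score: float
    status: str  # "selected" | "rejected"
    reject_reason: str = "none"  # "not_loop" | "terminal" | "proximity" | "none"

    def __post_init__(self) -> None:
        if self.status not in ("selected", "rejected"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "selected" and self.reject_reason != "none":
            raise ValueError("selected site cannot carry a reject reason")


@dataclass(frozen=True)
class SelectionParams:
    """Tunables of the three-filter selector.

    ``terminal_margin`` — minimum distance (residues) from either original
    terminus; ``min_separation`` — two surviving glycines closer than this
    are considered duplicates of the same loop; ``proximity_keep`` — which
    duplicate survives: the lowest-disorder one (default, best serves the
    stability objective) or simply the lowest-numbered one.
    """

    terminal_margin: int = 12
    min_separation: int = 8
    loop_only: bool = True
    proximity_keep: str = "lowest_score"  # or "lowest_position"

    def __post_init__(self) -> None:
        if self.terminal_margin < 0 or self.min_separation < 0:
            raise ValueError("margins must be non-negative")
        if self.proximity_keep not in ("lowest_score", "lowest_position"):
            raise ValueError(f"bad proximity_keep {self.proximity_keep!r}")


def find_glycines(record: SequenceRecord) -> list[int]:
    """Author-numbered positions of every glycine, ascending."""
    return [
        record.first_number + i
        for i, aa in enumerate(record.residues)
        if aa == "G"
    ]


def select_cleavage_sites(
    record: SequenceRecord,
    ss: SecondaryStructure,
    profile: DisorderProfile,
    params: SelectionParams = SelectionParams(),
) -> list[CleavageSite]:
    """Run the glycine inventory through the three filters.

    Returns one :class:`CleavageSite` per glycine of the record (ascending
    position): selected, or rejected with the first filter that removed it.
    Disorder scores are single-residue values from ``profile``.
    """
    for cover, what in ((ss, "secondary structure"), (profile, "disorder profile")):
        if cover.first_number > record.first_number or cover.last_number < record.last_number:
            raise ValueError(
                f"{what} ({cover.first_number}..{cover.last_number}) does not "
                f"cover record {record.id!r} "
                f"({record.first_number}..{record.last_number})"
            )

    glycines = find_glycines(record)
    reasons: dict[int, str] = {}

    for pos in glycines:
        if params.loop_only and ss.class_of(pos) != "L":
            reasons[pos] = "not_loop"
        elif (
            pos - record.first_number < params.terminal_margin
            or record.last_number - pos < params.terminal_margin
        ):
            reasons[pos] = "terminal"

    # Proximity: cluster the survivors by gap < min_separation, keep one each.
    survivors = [p for p in glycines if p not in reasons]
    clusters: list[list[int]] = []
    for pos in survivors:
        if clusters and pos - clusters[-1][-1] < params.min_separation:
            clusters[-1].append(pos)
        else:
            clusters.append([pos])
    for cluster in clusters:
        if len(cluster) == 1:
            continue
        if params.proximity_keep == "lowest_score":
            keep = min(cluster, key=lambda p: (score_at(profile, p), p))
        else:
            keep = cluster[0]
        for pos in cluster:
            if pos != keep:
                reasons[pos] = "proximity"

    sites = []
    for pos in glycines:
        reason = reasons.get(pos, "none")
        sites.append(
            CleavageSite(
                position=pos,
                residue="G",
                disorder_score=score_at(profile, pos),
                status="selected" if reason == "none" else "rejected",
                reject_reason=reason,
            )
        )
    return sites


def rank_sites(sites: list[CleavageSite]) -> list[CleavageSite]:
    """Selected sites ordered by ascending disorder score (predicted
    most-stable permutant first); ties broken by position."""
    selected = [s for s in sites if s.status == "selected"]
    return sorted(selected, key=lambda s: (s.disorder_score, s.position))


def classify_sites(
    sites: list[CleavageSite], threshold: float = 0.5
) -> tuple[list[CleavageSite], list[CleavageSite]]:
    """Partition sites into predicted-stable (score < threshold) and
    predicted-unstable (score >= threshold) groups."""
    stable = [s for s in sites if s.disorder_score < threshold]
    unstable = [s for s in sites if s.disorder_score >= threshold]
    return stable, unstable


def sites_report(sites: list[CleavageSite]) -> str:
    """TSV report: position, residue, score, status, reason."""
    lines = ["position\tresidue\tdisorder_score\tstatus\treject_reason"]
    for s in sites:
        lines.append(
            f"{s.position}\t{s.residue}\t{s.disorder_score:.3f}\t{s.status}\t{s.reject_reason}"
        )
    return "\n".join(lines) + "\n"
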