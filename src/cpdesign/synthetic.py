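"""Synthetic apical-domain stand-in for offline pipeline demonstrations.

The real substrate of the design pipeline is a chaperonin apical domain
(residues 192-333 in full-length numbering) whose sequence lives in public
databases.  This module builds a *synthetic* 142-residue domain with the
same numbering and the same glycine geometry — thirteen glycines, of which
six sit in loops away from the termini at positions 211, 244, 256, 269, 282
and 297 — so the inventory/filter/rank/build chain can be exercised and
demonstrated without network access.  The inter-glycine background sequence,
the secondary-structure cartoon and the non-site disorder scores are
invented; only the numbering conventions, glycine layout and the six
published per-site disorder scores are meaningful.
"""

from __future__ import annotations

import numpy as np

from .disorder import DisorderProfile
from .seq_records import SequenceRecord
from .sites import SecondaryStructure

FIRST, LAST = 192, 333

#: The six loop glycines with their published per-residue disorder scores.
SITE_SCORES = {211: 0.31, 244: 0.40, 256: 0.66, 269: 0.23, 282: 0.38, 297: 0.69}

#: Glycines the selector should reject, with the expected reason.
REJECTED_GLYCINES = {
    196: "terminal", 201: "terminal", 325: "terminal", 330: "terminal",
    222: "not_loop", 260: "not_loop",
    213: "proximity",  # 2 residues from Gly211, which scores lower
}

_EXTRA_SCORES = {196: 0.50, 201: 0.40, 213: 0.45, 222: 0.30,
                 260: 0.20, 325: 0.50, 330: 0.60}

_BACKGROUND = "ADKERNLVTQISFYMWHPC"  # glycine-free filler, cycled
_HELICES = [(218, 226), (258, 264), (300, 310)]
_STRANDS = [(230, 236), (315, 320)]


def synthetic_apical_domain() -> tuple[SequenceRecord, SecondaryStructure, DisorderProfile]:
    """A deterministic synthetic domain: (record, secondary structure, profile).

    The record is numbered 192-333; the profile carries the six published
    site scores at their positions and smoothly varying invented values
    elsewhere; the secondary-structure cartoon places two glycines inside
    helices and leaves every candidate site in a loop.
    """
    length = LAST - FIRST + 1
    residues = [_BACKGROUND[i % len(_BACKGROUND)] for i in range(length)]
    for pos in list(SITE_SCORES) + list(REJECTED_GLYCINES):
        residues[pos - FIRST] = "G"
    record = SequenceRecord("AD-synthetic", "".join(residues), first_number=FIRST)

    classes = ["L"] * length
    for kind, spans in (("H", _HELICES), ("E", _STRANDS)):
        for lo, hi in spans:
            for pos in range(lo, hi + 1):
                classes[pos - FIRST] = kind
    ss = SecondaryStructure(
        positions=np.arange(FIRST, LAST + 1), classes=tuple(classes)
    )

    scores = np.array([0.15 + 0.1 * ((i * 37) % 97) / 96.0 for i in range(length)])
    for pos, score in {**_EXTRA_SCORES, **SITE_SCORES}.items():
        scores[pos - FIRST] = score
    profile = DisorderProfile(
        positions=np.arange(FIRST, LAST + 1),
        scores=scores,
        source="synthetic-fixture",
        is_circular=True,
    )
    return record, ss, profile
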