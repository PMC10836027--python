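"""Per-residue intrinsic disorder profiles and their "circularization".

Per-residue disorder predictors (PONDR-family and kin) process linear chains
and systematically assign extra disorder to the N- and C-terminal regions of
any input — an artifact when the object of interest is a circularly permuted
protein, whose original termini are covalently joined.  The trick used here:
replicate the sequence three-fold, run the predictor on the tandem repeat,
and read back the central copy.  Every residue of the central copy sees a
full sequence context on both sides, so the resulting profile is that of the
*circular* chain, free of terminal edge effects.

Predictor output is an input to this package (TSV or PONDR-server text); a
self-contained windowed charge–hydropathy predictor is provided so the whole
pipeline can run without any external service.  It is a generic
order/disorder discriminant, not a reimplementation of any published neural
network, and carries its own documented constants.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .seq_records import SequenceRecord

# Kyte-Doolittle hydropathy, rescaled below to [0, 1] via (kd + 4.5) / 9.
_KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

# Net side-chain charge near neutral pH; His counted half-protonated.
_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0, "H": 0.5}


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder scores aligned to a record's author numbering.

    ``positions`` is a contiguous run of residue numbers (step 1); ``scores``
    holds one value in [0, 1] per position.  ``is_circular`` marks a profile
    read from the central copy of a triplicated sequence: window operations
    on such a profile wrap around instead of truncating.
    """

    positions: np.ndarray
    scores: np.ndarray
    source: str = "unknown"
    is_circular: bool = False

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=int)
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "scores", scores)
        if positions.ndim != 1 or positions.size == 0:
            raise ValueError("profile needs at least one position")
        if positions.size != scores.size:
            raise ValueError(
                f"{positions.size} positions but {scores.size} scores"
            )
        if positions.size > 1 and not np.all(np.diff(positions) == 1):
            raise ValueError("positions must be contiguous (step 1)")
        if np.any(scores < 0.0) or np.any(scores > 1.0):
            bad = scores[(scores < 0.0) | (scores > 1.0)][0]
            raise ValueError(f"disorder score {bad} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def first_number(self) -> int:
        return int(self.positions[0])

    @property
    def last_number(self) -> int:
        return int(self.positions[-1])

    def score_of(self, position: int) -> float:
        """Raw stored score at one residue number."""
        if not self.first_number <= position <= self.last_number:
            raise KeyError(
                f"position {position} not in profile "
                f"({self.first_number}..{self.last_number})"
            )
        return float(self.scores[position - self.first_number])


def read_disorder_profile(path: str | Path, dialect: str = "tsv") -> DisorderProfile:
    """Load a per-residue disorder profile from predictor output.

    ``dialect="tsv"``: tab-separated columns ``position [residue] score``
    (the residue-letter column is optional); no header required, lines
    starting with ``#`` ignored.  ``dialect="pondr"``: the PONDR server's
    whitespace-separated ``index residue score`` lines, ``#`` comments
    ignored.

    Scores outside [0, 1] and non-contiguous positions are errors, never
    silently clipped or reindexed.
    """
    path = Path(path)
    if dialect == "tsv":
        frame = pd.read_csv(path, sep="\t", comment="#", header=None)
    elif dialect == "pondr":
        frame = pd.read_csv(path, sep=r"\s+", comment="#", header=None)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'pondr')")
    if frame.shape[1] == 2:
        positions, scores = frame[0], frame[1]
    elif frame.shape[1] >= 3:
        positions, scores = frame[0], frame[2]
    else:
        raise ValueError(f"{path}: expected 2 or 3 columns, got {frame.shape[1]}")
    return DisorderProfile(
        positions=positions.to_numpy(dtype=int),
        scores=scores.to_numpy(dtype=float),
        source=f"{dialect}:{path.name}",
    )


def write_disorder_profile(
    profile: DisorderProfile, record: SequenceRecord | None, path: str | Path
) -> None:
    """Write a profile as ``position <tab> residue <tab> score`` lines."""
    with open(path, "w") as handle:
        handle.write(f"# source={profile.source} circular={profile.is_circular}\n")
        for pos, score in zip(profile.positions, profile.scores):
            letter = record.residue_at(int(pos)) if record is not None else "-"
            handle.write(f"{int(pos)}\t{letter}\t{score:.6f}\n")


def triplicate(record: SequenceRecord) -> SequenceRecord:
    """Tandem three-fold repeat of a sequence, renumbered from 1.

    Feed the result to a linear disorder predictor; the central copy of the
    output then carries the circular-chain profile (see
    :func:`circularize_profile`).
    """
    return SequenceRecord(
        id=f"{record.id}|x3", residues=record.residues * 3, first_number=1
    )


def circularize_profile(
    profile3: DisorderProfile, original: SequenceRecord
) -> DisorderProfile:
    """Extract the central-copy profile of a triplicated sequence.

    ``profile3`` must have been computed on ``triplicate(original)`` (length
    3L, positions 1..3L).  The returned profile covers the original record's
    numbering: the score of residue number ``n`` is the triplicated profile's
    value at (1-based) index ``L + (n - first_number) + 1``, i.e. the middle
    copy, where every residue is flanked by a full copy on each side.
    """
    length = len(original)
    if len(profile3) != 3 * length:
        raise ValueError(
            f"profile length {len(profile3)} does not match 3 x {length} "
            f"(triplicate of record {original.id!r})"
        )
    central = profile3.scores[length : 2 * length]
    return DisorderProfile(
        positions=np.arange(original.first_number, original.last_number + 1),
        scores=central.copy(),
        source=f"circularized({profile3.source})",
        is_circular=True,
    )


def score_at(profile: DisorderProfile, position: int, window: int = 1) -> float:
    """Mean disorder score over a centered window at one residue.

    With the default ``window=1`` this is the raw per-residue score — the
    quantity used to annotate candidate cleavage sites.  For circular
    profiles the window wraps around the join; for linear profiles it
    truncates at the chain ends.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if not profile.first_number <= position <= profile.last_number:
        raise KeyError(
            f"position {position} not in profile "
            f"({profile.first_number}..{profile.last_number})"
        )
    n = len(profile)
    center = position - profile.first_number
    half = window // 2
    idx = np.arange(center - half, center + half + 1)
    if profile.is_circular:
        idx = idx % n
    else:
        idx = idx[(idx >= 0) & (idx < n)]
    return float(profile.scores[idx].mean())


def _window_means(values: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean with truncation at the edges.

    Each window is summed independently (no prefix-sum differencing), so two
    windows holding the same values give bitwise-identical means regardless
    of where they sit in the array — the circularized fallback profile is
    then *exactly* rotation-equivariant, not just within rounding.
    """
    n = len(values)
    half = window // 2
    means = np.empty(n)
    if n >= window:
        full = np.lib.stride_tricks.sliding_window_view(values, window).mean(axis=1)
    for i in range(n):
        lo = max(i - half, 0)
        hi = min(i + half + 1, n)
        if hi - lo == window:
            means[i] = full[lo]
        else:
            means[i] = values[lo:hi].mean()
    return means


def fallback_disorder_profile(
    record: SequenceRecord, window: int = 51, steepness: float = 10.0
) -> DisorderProfile:
    """Self-contained windowed charge–hydropathy disorder score.

    For each residue, a folding index is computed over a centered window
    (truncated at the chain ends):

        FI = 2.785 * <H> - |<R>| - 1.151

    where ``<H>`` is the mean Kyte-Doolittle hydropathy rescaled to [0, 1]
    and ``<R>`` the mean net charge (K, R: +1; D, E: -1; H: +0.5).  Positive
    FI marks order-prone windows (hydrophobic, uncharged), negative FI
    disorder-prone ones; the score is the logistic squash
    ``1 / (1 + exp(steepness * FI))``, strictly inside (0, 1).

    This is pipeline plumbing so designs can be drafted with no external
    predictor; it shares no parameters with any published server, and
    site-level conclusions should be drawn from a real predictor's output.
    """
    hydro = np.array(
        [(_KYTE_DOOLITTLE[aa] + 4.5) / 9.0 for aa in record.residues]
    )
    charge = np.array([_CHARGE.get(aa, 0.0) for aa in record.residues])
    mean_h = _window_means(hydro, window)
    mean_r = _window_means(charge, window)
    folding_index = 2.785 * mean_h - np.abs(mean_r) - 1.151
    scores = expit(-steepness * folding_index)
    return DisorderProfile(
        positions=np.arange(record.first_number, record.last_number + 1),
        scores=scores,
        source="fallback-CH",
    )


def circular_fallback_profile(
    record: SequenceRecord, window: int = 51, steepness: float = 10.0
) -> DisorderProfile:
    """Fallback predictor run through the triplication trick.

    Convenience composition: predict on ``triplicate(record)``, read back the
    central copy.  The result is rotation-equivariant: rotating the input
    sequence rotates the profile.
    """
    profile3 = fallback_disorder_profile(triplicate(record), window, steepness)
    return circularize_profile(profile3, record)


def renumber(profile: DisorderProfile, first_number: int) -> DisorderProfile:
    """Shift a profile onto a new numbering origin (scores untouched)."""
    return replace(
        profile,
        positions=np.arange(first_number, first_number + len(profile)),
    )
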