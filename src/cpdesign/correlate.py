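"""Disorder-stability correlation analysis.

The design hypothesis is quantitative: across a set of circular permutants
of one protein, the experimentally measured stability (t_1/2 from CD melts,
t_m from DSC, or an unfolding free energy) should correlate *inversely* with
the intrinsic-disorder score at each permutant's cleavage site in the parent
chain.  This module packages the measured stability table for the GroEL
apical domain permutant series, a second fixture of published S6 ribosomal
protein permutant free energies, and the Pearson machinery to quantify the
relationship.

Conventions for the GroEL table: the wild type (cleavage-free, scored at the
joined termini) is included in every correlation; a variant missing a
measurement under one method is dropped from that method's correlation only.
One permutant (cp297) shows two DSC peaks — either can be designated the
melting temperature, and both choices are exposed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .permute import PermutantDesign
from .sites import CleavageSite

_STABILITY_COLUMNS = {
    "dsc": "tm_dsc",
    "cd210": "t_half_cd210",
    "cd220": "t_half_cd220",
}


@dataclass(frozen=True)
class StabilityRecord:
    """One variant's disorder score and measured stabilities (degC).

    Missing measurements are ``None``; ``tm_dsc_secondary`` carries the
    second DSC peak for variants whose thermogram is bimodal.
    """

    variant: str
    disorder_score: float
    tm_dsc: float | None = None
    tm_dsc_secondary: float | None = None
    t_half_cd210: float | None = None
    t_half_cd220: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.disorder_score <= 1.0:
            raise ValueError(f"disorder score {self.disorder_score} outside [0, 1]")
        if all(
            v is None
            for v in (self.tm_dsc, self.t_half_cd210, self.t_half_cd220)
        ):
            raise ValueError(f"variant {self.variant!r}: no stability measurement")


@dataclass(frozen=True)
class DGRecord:
    """A published permutant unfolding free energy (kcal/mol)."""

    variant: str
    source_study: str
    dG: float


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson correlation with its underlying points."""

    r: float
    n: int
    x_label: str
    y_label: str
    points: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"|r| > 1: {self.r}")
        if self.n != len(self.points):
            raise ValueError("n does not match number of points")


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("cpdesign").joinpath("data", name)))


def load_ad_groel_table(path: str | Path | None = None) -> list[StabilityRecord]:
    """The packaged GroEL apical-domain permutant stability table.

    Seven records (wild type + six permutants): per-site disorder score,
    DSC t_m (with cp297's second peak), and CD t_1/2 at 210 and 220 nm.
    """
    path = Path(path) if path is not None else _fixture_path("ad_groel_table1.tsv")
    frame = pd.read_csv(path, sep="\t")

    def _opt(value: object) -> float | None:
        return None if pd.isna(value) else float(value)

    return [
        StabilityRecord(
            variant=row["variant"],
            disorder_score=float(row["disorder"]),
            tm_dsc=_opt(row["tm_dsc"]),
            tm_dsc_secondary=_opt(row["tm_dsc_secondary"]),
            t_half_cd210=_opt(row["t_half_cd210"]),
            t_half_cd220=_opt(row["t_half_cd220"]),
        )
        for _, row in frame.iterrows()
    ]


def load_s6_table(path: str | Path | None = None) -> list[DGRecord]:
    """Published S6 ribosomal-protein permutant unfolding free energies.

    Thirteen values from two independent series (different linker designs,
    overlapping cleavage sites); replicate determinations of the same
    variant are kept as separate records, tagged by source.
    """
    path = Path(path) if path is not None else _fixture_path("s6_dg.tsv")
    frame = pd.read_csv(path, sep="\t")
    return [
        DGRecord(row["variant"], row["study"], float(row["dG_kcal_mol"]))
        for _, row in frame.iterrows()
    ]


def pearson(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Product-moment correlation coefficient.

    Requires equal-length inputs of at least 3 points with non-zero variance
    on both axes.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size != ys.size:
        raise ValueError(f"length mismatch: {xs.size} vs {ys.size}")
    if xs.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(_stats.pearsonr(xs, ys).statistic)


def correlate_stability(
    records: Sequence[StabilityRecord],
    stability: str,
    cp297_peak: str = "main",
) -> CorrelationResult:
    """Correlate cleavage-site disorder with one stability readout.

    ``stability`` is ``dsc``, ``cd210`` or ``cd220``; records missing that
    measurement are dropped.  For DSC, ``cp297_peak="secondary"`` substitutes
    a variant's second thermogram peak where one exists.
    """
    if stability not in _STABILITY_COLUMNS:
        raise ValueError(
            f"unknown stability {stability!r} (expected one of "
            f"{sorted(_STABILITY_COLUMNS)})"
        )
    if cp297_peak not in ("main", "secondary"):
        raise ValueError(f"cp297_peak must be 'main' or 'secondary', got {cp297_peak!r}")
    attr = _STABILITY_COLUMNS[stability]
    points: list[tuple[str, float, float]] = []
    for rec in records:
        value = getattr(rec, attr)
        if value is None:
            continue
        if (
            stability == "dsc"
            and cp297_peak == "secondary"
            and rec.tm_dsc_secondary is not None
        ):
            value = rec.tm_dsc_secondary
        points.append((rec.variant, rec.disorder_score, float(value)))
    if len(points) < 3:
        raise ValueError(
            f"only {len(points)} records carry a {stability} value; need >= 3"
        )
    r = pearson([p[1] for p in points], [p[2] for p in points])
    y_label = attr if not (stability == "dsc" and cp297_peak == "secondary") else (
        f"{attr} (second peak where present)"
    )
    return CorrelationResult(
        r=r,
        n=len(points),
        x_label="disorder_score",
        y_label=y_label,
        points=tuple(points),
    )


def design_report(
    sites: Sequence[CleavageSite] = (),
    designs: Sequence[PermutantDesign] = (),
    correlations: Sequence[CorrelationResult] = (),
    classification_threshold: float = 0.5,
) -> dict:
    """Machine-readable summary of a design run.

    Ranked selected sites, the predicted stable/unstable split, construct
    geometry, and any computed disorder-stability correlations (r to 2 dp in
    the report; callers keep full precision via :class:`CorrelationResult`).
    """
    selected = sorted(
        (s for s in sites if s.status == "selected"),
        key=lambda s: (s.disorder_score, s.position),
    )
    report = {
        "sites": {
            "ranked": [
                {"position": s.position, "disorder_score": round(s.disorder_score, 3)}
                for s in selected
            ],
            "predicted_stable": [
                s.position
                for s in selected
                if s.disorder_score < classification_threshold
            ],
            "predicted_unstable": [
                s.position
                for s in selected
                if s.disorder_score >= classification_threshold
            ],
            "rejected": [
                {"position": s.position, "reason": s.reject_reason}
                for s in sites
                if s.status == "rejected"
            ],
        },
        "designs": [
            {
                "name": d.name,
                "parent": d.parent_id,
                "new_start": d.new_start,
                "linker": d.linker,
                "length": len(d),
            }
            for d in designs
        ],
        "correlations": [
            {
                "x": c.x_label,
                "y": c.y_label,
                "r": round(c.r, 2),
                "n": c.n,
                "points": [list(p) for p in c.points],
            }
            for c in correlations
        ],
    }
    return report


def report_to_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def report_from_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
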