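"""Selection-coefficient estimation from competition count tables.

A competition mixes two strains i and j, grows (and possibly mates) them, and
counts both before and after (flow-cytometry style: a fixed number of events
is classified by marker).  The asexual estimator is the change in the log
frequency ratio,

    s_ij ≈ log(p_i,after / p_j,after) − log(p_i,before / p_j,before),

natural log, antisymmetric in i/j and invariant to rescaling all counts.
Divided by the number of mitotic generations t = transfers × log2(fold
growth per transfer) it becomes a per-generation coefficient.  For sexual
competitions the same log-ratio difference defines relative fitness
w = exp(Δ log-ratio) and s = 1 − w.

The fluorescent marker used to tell strains apart carries a fitness effect of
its own; assuming effects are additive (exact on the log scale), the strain
effect is recovered by subtracting the marker effect measured in isogenic
control competitions: s_corrected = s_total − s_marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional

import numpy as np
import pandas as pd

__all__ = [
    "CompetitionRecord",
    "SelectionEstimate",
    "ReplicateSummary",
    "log_ratio_selection",
    "generations",
    "per_generation",
    "marker_correct",
    "sexual_selection",
    "replicate_summary",
    "corrected_estimates",
]

REGIMES = ("asexual_exponential", "asexual_saturated", "sexual")

#: canonical column order for competition-record tables (CSV contract)
RECORD_COLUMNS = [
    "replicate",
    "kind",
    "regime",
    "marker_on",
    "transfers",
    "fold_growth",
    "count_i_before",
    "count_j_before",
    "count_i_after",
    "count_j_after",
]


@dataclass(frozen=True)
class CompetitionRecord:
    """Before/after counts of two competing strains.

    ``marker_on`` says which strain carries the fluorescent label; ``kind``
    distinguishes strain-vs-strain competitions from isogenic marker
    controls.  Counts may be floats (frequencies work as well as raw counts:
    every estimator is scale invariant).
    """

    count_i_before: float
    count_j_before: float
    count_i_after: float
    count_j_after: float
    transfers: int = 5
    fold_growth: float = 100.0
    regime: str = "asexual_saturated"
    marker_on: str = "i"
    kind: str = "competition"
    replicate: int = 0

    def __post_init__(self) -> None:
        for name in ("count_i_before", "count_j_before", "count_i_after", "count_j_after"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.marker_on not in ("i", "j"):
            raise ValueError(f"marker_on must be 'i' or 'j', got {self.marker_on!r}")


class SelectionEstimate(NamedTuple):
    """One corrected selection estimate with its bookkeeping."""

    s_total: float
    s_marker: float
    s_corrected: float
    generations: float
    per_generation: float
    regime: str
    replicate: int


class ReplicateSummary(NamedTuple):
    mean: float
    se: float
    n: int


def _counts(record: CompetitionRecord, pseudocount: bool) -> tuple:
    c = (
        record.count_i_before,
        record.count_j_before,
        record.count_i_after,
        record.count_j_after,
    )
    if any(x == 0 for x in c):
        if not pseudocount:
            raise ValueError(
                "zero count in competition record; pass pseudocount=True to apply a "
                "Haldane 0.5 correction"
            )
        c = tuple(x + 0.5 for x in c)
    return c


def log_ratio_selection(record: CompetitionRecord, pseudocount: bool = False) -> float:
    """Total (per-competition) selection coefficient of strain i over j:
    the change in the natural-log frequency ratio."""
    ib, jb, ia, ja = _counts(record, pseudocount)
    return math.log(ia / ja) - math.log(ib / jb)


def generations(transfers: int, fold_growth: float) -> float:
    """Mitotic generations over a competition: transfers × log2(fold growth).

    E.g. five transfers at 100-fold growth per transfer is ~33 generations;
    at 500-fold, ~45.
    """
    if transfers < 1:
        raise ValueError(f"transfers must be >= 1, got {transfers}")
    if fold_growth <= 1.0:
        raise ValueError(f"fold_growth must exceed 1, got {fold_growth}")
    return transfers * math.log2(fold_growth)


def per_generation(s: float, transfers: int, fold_growth: float) -> float:
    """Scale a per-competition coefficient to per mitotic generation."""
    return s / generations(transfers, fold_growth)


def marker_correct(
    s_total: float,
    s_marker: float,
    regime_total: Optional[str] = None,
    regime_marker: Optional[str] = None,
) -> float:
    """Subtract the marker effect under the additivity assumption.

    Both inputs must come from the same growth regime (and density); pass the
    regimes to enforce the check.
    """
    if regime_total is not None and regime_marker is not None and regime_total != regime_marker:
        raise ValueError(
            f"marker control measured under {regime_marker!r} cannot correct a "
            f"competition measured under {regime_total!r}"
        )
    return s_total - s_marker


def sexual_selection(record: CompetitionRecord, pseudocount: bool = False) -> float:
    """Selection coefficient over one sexual episode: w = exp(Δ log-ratio)
    for strain i relative to j, s = 1 − w.  Positive s means the focal
    strain i lost ground."""
    w = math.exp(log_ratio_selection(record, pseudocount=pseudocount))
    return 1.0 - w


def replicate_summary(estimates: Iterable[float]) -> ReplicateSummary:
    """Mean and standard error of the mean across replicates; SE is reported
    as NaN when fewer than two replicates exist."""
    x = np.asarray(list(estimates), dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("no estimates to summarize")
    mean = float(x.mean())
    se = float(x.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
    return ReplicateSummary(mean=mean, se=se, n=n)


def _record_from_row(row: pd.Series) -> CompetitionRecord:
    return CompetitionRecord(
        count_i_before=float(row["count_i_before"]),
        count_j_before=float(row["count_j_before"]),
        count_i_after=float(row["count_i_after"]),
        count_j_after=float(row["count_j_after"]),
        transfers=int(row["transfers"]),
        fold_growth=float(row["fold_growth"]),
        regime=str(row["regime"]),
        marker_on=str(row["marker_on"]),
        kind=str(row["kind"]),
        replicate=int(row["replicate"]),
    )


def corrected_estimates(records: pd.DataFrame, pseudocount: bool = False) -> pd.DataFrame:
    """Marker-corrected selection estimates from a long table of records.

    The table follows :data:`RECORD_COLUMNS`; each (replicate, marker_on)
    pair must contain one ``competition`` row and one ``marker_control`` row
    from the same regime.  Asexual regimes are corrected on the raw log-ratio
    scale and then divided by t (both measurements span the same t, so the
    order is immaterial; it is fixed for determinism).  The sexual regime
    reports s = 1 − w with the marker effect divided out of w.

    Returns one row per (replicate, marker_on) with columns ``s_total``,
    ``s_marker``, ``s_corrected``, ``generations``, ``s_per_generation``.
    """
    keys = ["replicate", "marker_on"]
    # sexual tables carry treatment columns; keep each treatment separate
    keys += [c for c in ("density", "initial_freq_i") if c in records.columns]
    rows = []
    for key_vals, group in records.groupby(keys):
        rep, marker_on = key_vals[0], key_vals[1]
        extra = dict(zip(keys[2:], key_vals[2:]))
        comp = group[group["kind"] == "competition"]
        ctrl = group[group["kind"] == "marker_control"]
        if len(comp) != 1 or len(ctrl) != 1:
            raise ValueError(
                f"replicate {rep!r} marker_on {marker_on!r}: need exactly one "
                f"competition and one marker_control row, got {len(comp)} and {len(ctrl)}"
            )
        comp_rec = _record_from_row(comp.iloc[0])
        ctrl_rec = _record_from_row(ctrl.iloc[0])
        if comp_rec.regime != ctrl_rec.regime:
            raise ValueError(
                f"replicate {rep!r}: regime mismatch between competition "
                f"({comp_rec.regime}) and marker control ({ctrl_rec.regime})"
            )
        s_total_raw = log_ratio_selection(comp_rec, pseudocount=pseudocount)
        s_marker_raw = log_ratio_selection(ctrl_rec, pseudocount=pseudocount)
        if comp_rec.regime == "sexual":
            w = math.exp(marker_correct(s_total_raw, s_marker_raw))
            rows.append(
                {
                    "replicate": rep,
                    "marker_on": marker_on,
                    "regime": comp_rec.regime,
                    "s_total": 1.0 - math.exp(s_total_raw),
                    "s_marker": 1.0 - math.exp(s_marker_raw),
                    "s_corrected": 1.0 - w,
                    "generations": float("nan"),
                    "s_per_generation": float("nan"),
                    **extra,
                }
            )
        else:
            t = generations(comp_rec.transfers, comp_rec.fold_growth)
            s_corr = marker_correct(s_total_raw, s_marker_raw)
            rows.append(
                {
                    "replicate": rep,
                    "marker_on": marker_on,
                    "regime": comp_rec.regime,
                    "s_total": s_total_raw,
                    "s_marker": s_marker_raw,
                    "s_corrected": s_corr,
                    "generations": t,
                    "s_per_generation": s_corr / t,
                    **extra,
                }
            )
    return pd.DataFrame(rows)
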