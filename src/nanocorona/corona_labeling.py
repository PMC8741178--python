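"""In/out-of-corona labeling from quantitative proteomics abundances.

A protein is placed in the corona by either of two criteria:

1. *Enrichment* — its abundance on the nanoparticle exceeds its abundance
   in the biofluid-only control (A_corona > A_biofluid).
2. *Abundance threshold* — among the remaining (non-enriched) proteins the
   corona-abundance distribution is modeled as an exponential decay
   n = n0·exp(−kA); the in-corona cutoff is placed where the decay has
   fallen by a factor exp(−p), i.e. A_threshold = p/k, and proteins with
   A_corona > A_threshold are in the corona.  The power p tunes how deep
   into the distribution the cutoff sits (default 2.25).

The rationale: a protein depleted relative to the biofluid can still be
present in the corona in large absolute quantity, so depletion alone must
not exclude it.

The default rate fit is the exponential maximum-likelihood estimate
k = 1/mean(A_corona), which is bin-free and deterministic; a histogram
least-squares mode (fitting log counts of equal-width bins, recovering n0
as well) is retained for fidelity experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import AbundanceRecord

DEFAULT_POWER = 2.25


@dataclass(frozen=True)
class ThresholdFit:
    """Fitted exponential rate and the resulting abundance threshold."""

    k: float
    p: float
    a_threshold: float
    n_fit: int
    method: str = "mle"
    n0: float | None = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"rate k must be positive, got {self.k}")
        if self.p < 0:
            raise ValueError(f"power p must be nonnegative, got {self.p}")
        if not np.isclose(self.a_threshold, self.p / self.k):
            raise ValueError("a_threshold must equal p/k")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "p": self.p,
            "a_threshold": self.a_threshold,
            "n_fit": self.n_fit,
            "method": self.method,
            "n0": self.n0,
        }


@dataclass(frozen=True)
class CoronaLabel:
    accession: str
    in_corona: bool
    reason: str  # enriched | above_threshold | below_threshold

    def __post_init__(self) -> None:
        if self.reason not in ("enriched", "above_threshold",
                               "below_threshold"):
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.reason == "enriched" and not self.in_corona:
            raise ValueError("enriched implies in_corona")
        if self.reason == "below_threshold" and self.in_corona:
            raise ValueError("below_threshold implies out of corona")


def _non_enriched_abundances(
    records: Sequence[AbundanceRecord],
) -> np.ndarray:
    return np.array(
        [r.a_corona for r in records if not r.enriched], dtype=float
    )


def fit_threshold(
    records: Sequence[AbundanceRecord],
    p: float = DEFAULT_POWER,
    method: str = "mle",
) -> ThresholdFit:
    """Fit the exponential rate to non-enriched corona abundances and set
    A_threshold = p/k.

    Enriched records (A_corona > A_biofluid) are excluded before fitting.
    ``method="mle"`` uses k = 1/mean (the exponential MLE); ``"histogram"``
    least-squares fits (n0, k) to log counts of equal-width bins.
    """
    if p < 0:
        raise ValueError(f"power p must be nonnegative, got {p}")
    abundances = _non_enriched_abundances(records)
    abundances = abundances[abundances > 0]
    if abundances.size == 0:
        raise ValueError(
            "no distribution to fit: every record is enriched (or has zero "
            "corona abundance)"
        )
    if method == "mle":
        if abundances.size < 2:
            raise ValueError("MLE fit requires ≥2 non-enriched records")
        mean = float(abundances.mean())
        if mean <= 0:
            raise ValueError("non-positive mean abundance")
        k = 1.0 / mean
        return ThresholdFit(
            k=k, p=p, a_threshold=p / k, n_fit=int(abundances.size),
            method="mle",
        )
    if method == "histogram":
        n_bins = max(5, int(np.sqrt(abundances.size)))
        counts, edges = np.histogram(abundances, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mask = counts > 0
        if mask.sum() < 2:
            raise ValueError("histogram fit requires ≥2 occupied bins")
        # log n = log n0 − k·A, ordinary least squares
        slope, intercept = np.polyfit(centers[mask], np.log(counts[mask]), 1)
        k = -float(slope)
        if k <= 0:
            raise ValueError(
                "histogram fit produced a non-decaying rate; distribution "
                "is not exponential-like"
            )
        return ThresholdFit(
            k=k, p=p, a_threshold=p / k, n_fit=int(abundances.size),
            method="histogram", n0=float(np.exp(intercept)),
        )
    raise ValueError(f"unknown fit method {method!r}")


def assign_labels(
    records: Sequence[AbundanceRecord], fit: ThresholdFit
) -> list[CoronaLabel]:
    """Label each protein in/out of the corona.

    In-corona ⇔ enriched OR A_corona > A_threshold; enrichment takes
    precedence in the recorded reason.  Comparisons are strict, so a tie at
    exactly A_threshold is out of the corona.
    """
    labels = []
    for rec in records:
        if rec.enriched:
            labels.append(CoronaLabel(rec.accession, True, "enriched"))
        elif rec.a_corona > fit.a_threshold:
            labels.append(CoronaLabel(rec.accession, True, "above_threshold"))
        else:
            labels.append(CoronaLabel(rec.accession, False, "below_threshold"))
    return labels


def threshold_sweep(
    records: Sequence[AbundanceRecord],
    p_grid: Sequence[float],
    method: str = "mle",
) -> list[tuple[float, int, ThresholdFit]]:
    """In-corona counts over a grid of threshold powers.

    The rate k is fitted once (it does not depend on p) and reused, so the
    sweep reflects only the moving cutoff.  Returns (p, n_in_corona, fit)
    rows; the count is monotone non-increasing in p and never drops below
    the number of enriched proteins.
    """
    if len(p_grid) == 0:
        raise ValueError("p_grid must be nonempty")
    if any(p < 0 for p in p_grid):
        raise ValueError("p_grid values must be nonnegative")
    base = fit_threshold(records, p=p_grid[0], method=method)
    rows = []
    for p in p_grid:
        fit = ThresholdFit(
            k=base.k, p=p, a_threshold=p / base.k, n_fit=base.n_fit,
            method=base.method, n0=base.n0,
        )
        n_in = sum(lab.in_corona for lab in assign_labels(records, fit))
        rows.append((float(p), int(n_in), fit))
    return rows
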